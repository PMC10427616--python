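"""Convert predicted contacts into docking distance restraints.

Each selected contact contributes a piecewise distance-dependent energy
to the docking score: a flat well of E0 (default -100 kcal/mol) inside
8 A, a linear ramp to zero between 8 and 12 A, and zero beyond 12 A.
Only the highest-probability predictions are used (default: top 10 with
probability > 0.65) to limit false-positive restraints.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .evaluation import ranked_pairs
from .net import ContactPrediction

__all__ = ["RestraintTerm", "restraint_energy", "select_restraints", "write_restraints"]

E0_DEFAULT = -100.0     # kcal/mol
R_PLATEAU = 8.0         # A
R_CUTOFF = 12.0         # A


@dataclasses.dataclass
class RestraintTerm:
    i: int                  # 1-based residue index
    j: int
    probability: float
    e0: float = E0_DEFAULT

    def energy(self, r: float) -> float:
        return restraint_energy(r, self.e0)


def restraint_energy(r: float, e0: float = E0_DEFAULT) -> float:
    """Piecewise restraint energy in kcal/mol for inter-residue distance r (A).

    e0 for r <= 8; e0 * (1 - (r - 8)/4) for 8 < r <= 12; 0 beyond.
    Continuous at both joints.
    """
    r = float(r)
    if r < 0:
        raise ValueError(f"negative distance: {r}")
    if r <= R_PLATEAU:
        return float(e0)
    if r <= R_CUTOFF:
        return float(e0 * (1.0 - (r - R_PLATEAU) / (R_CUTOFF - R_PLATEAU)))
    return 0.0


def select_restraints(pred: ContactPrediction | np.ndarray, top: int = 10,
                      pmin: float = 0.65, e0: float = E0_DEFAULT) -> list:
    """Top predicted contacts above the probability floor.

    Pairs are deduplicated over (i, j) <-> (j, i), ranked by descending
    probability with lexicographic (i, j) tie-break, and at most `top`
    with probability strictly above `pmin` are kept.  Indices are
    1-based in the returned terms.
    """
    prob = pred.probabilities if isinstance(pred, ContactPrediction) else np.asarray(pred)
    ii, jj, pp = ranked_pairs(prob)
    terms = []
    for i, j, p in zip(ii, jj, pp):
        if len(terms) >= top:
            break
        if p > pmin:
            terms.append(RestraintTerm(i=int(i) + 1, j=int(j) + 1,
                                       probability=float(p), e0=e0))
    return terms


def write_restraints(path, terms, chain_i: str = "A", chain_j: str = "B"):
    """TSV restraint file: chain_i, res_i, chain_j, res_j, probability, E0."""
    with open(path, "w") as f:
        f.write("chain_i\tres_i\tchain_j\tres_j\tprobability\tE0\n")
        for t in terms:
            f.write(f"{chain_i}\t{t.i}\t{chain_j}\t{t.j}\t{t.probability:.6f}\t{t.e0:.1f}\n")
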