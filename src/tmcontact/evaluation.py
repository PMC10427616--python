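"""Symmetry-aware evaluation: top-k precision, contact density, and
oligomeric-state calling.

Chains of a homo-oligomer are physically indistinguishable, so a
predicted pair (i, j) is scored against the union of the per-chain-pair
contact maps, deduplicated over (i, j) <-> (j, i).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .net import ContactPrediction
from .structures import ComplexStructure, interchain_contact_map

__all__ = [
    "PrecisionReport", "OligomerCall",
    "topk_precision", "contact_density", "classify_oligomeric_state",
    "success_rate_curve", "ranked_pairs",
    "THETA_MONOMER", "THETA_DIMER",
]

TOP_K_FIXED = (1, 10, 25, 50)
THETA_MONOMER = 0.77    # max contact probability at/below this -> monomer
THETA_DIMER = 0.97      # above this -> three or more subunits


@dataclasses.dataclass
class PrecisionReport:
    precisions: dict          # label -> precision in [0, 1] or None (no contacts)
    n_true_contacts: int


@dataclasses.dataclass
class OligomerCall:
    max_probability: float
    state: str                # 'monomer' | 'dimer' | 'higher-order'
    theta1: float = THETA_MONOMER
    theta2: float = THETA_DIMER


def ranked_pairs(prob: np.ndarray):
    """Deduplicated (upper triangle incl. diagonal) pairs, ranked by
    descending probability; ties broken by (i, j) lexicographic order."""
    L = prob.shape[0]
    iu, ju = np.triu_indices(L)
    p = prob[iu, ju]
    order = np.lexsort((ju, iu, -p))
    return iu[order], ju[order], p[order]


def topk_precision(pred: ContactPrediction | np.ndarray, truth: np.ndarray,
                   L: int | None = None) -> PrecisionReport:
    """Precision of the top k predicted pairs for k in
    {1, 10, 25, 50, L/10, L/5, L} (floored, minimum 1).

    `truth` is the union contact map over chain pairs.  A target with
    zero true contacts has undefined precision, reported as None.
    """
    prob = pred.probabilities if isinstance(pred, ContactPrediction) else np.asarray(pred)
    truth = np.asarray(truth, dtype=bool)
    if prob.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {prob.shape} vs truth {truth.shape}")
    if L is None:
        L = prob.shape[0]
    truth_sym = truth | truth.T
    n_true = int(np.triu(truth_sym).sum())
    ks = {f"top{k}": k for k in TOP_K_FIXED}
    ks["topL10"] = max(1, L // 10)
    ks["topL5"] = max(1, L // 5)
    ks["topL"] = L
    if n_true == 0:
        return PrecisionReport(precisions={k: None for k in ks}, n_true_contacts=0)
    ii, jj, _ = ranked_pairs(prob)
    hits = truth_sym[ii, jj].astype(float)
    cum = hits.cumsum()
    out = {}
    for label, k in ks.items():
        k = min(k, len(hits))
        out[label] = float(cum[k - 1] / k)
    return PrecisionReport(precisions=out, n_true_contacts=n_true)


def contact_density(c: ComplexStructure, L: int | None = None,
                    cutoff: float = 8.0) -> float:
    """Contacts at the maximum interface divided by 2L.

    The chain pair with the most contacts defines the interface; the
    count is the number of contacting (i, j) residue pairs in its L x L
    inter-chain map.
    """
    if c.n_chains < 2:
        raise ValueError("contact density requires >= 2 chains")
    cm = interchain_contact_map(c, cutoff=cutoff)
    if L is None:
        L = len(c.chains[0])
    best = max(int(m.sum()) for m in cm.pair_maps.values())
    return best / (2.0 * L)


def classify_oligomeric_state(maxp: float, theta1: float = THETA_MONOMER,
                              theta2: float = THETA_DIMER) -> OligomerCall:
    """Monomer / dimer / higher-order call from the max contact probability."""
    if not (0.0 <= maxp <= 1.0):
        raise ValueError(f"probability out of range: {maxp}")
    if not theta1 < theta2:
        raise ValueError("theta1 must be < theta2")
    if maxp <= theta1:
        state = "monomer"
    elif maxp <= theta2:
        state = "dimer"
    else:
        state = "higher-order"
    return OligomerCall(max_probability=maxp, state=state, theta1=theta1, theta2=theta2)


def success_rate_curve(calls, thresholds) -> list:
    """Success rates versus threshold.

    `calls` is a list of (max probability, true label) with labels in
    {'monomer', 'oligomer'}.  A monomer is a success when its maximum
    probability is below the threshold; an oligomer when at/above it.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("empty call list")
    labels = {lbl for _, lbl in calls}
    bad = labels - {"monomer", "oligomer"}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    mono = np.array([p for p, lbl in calls if lbl == "monomer"])
    olig = np.array([p for p, lbl in calls if lbl == "oligomer"])
    rows = []
    for t in thresholds:
        rows.append({
            "threshold": float(t),
            "monomer_success": float((mono < t).mean()) if mono.size else None,
            "oligomer_success": float((olig >= t).mean()) if olig.size else None,
        })
    return rows
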