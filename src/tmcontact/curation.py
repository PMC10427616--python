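"""Dataset curation: structural filters and greedy identity clustering.

The curation rules mirror standard homo-oligomer benchmark
construction: the assembly's chain count must equal its declared
symmetry order, chains must be near-identical in sequence, the monomer
must fit the feature extractor's length limit, and the complex must
have a real interface (minimum buried area and contact count).
Clustering is a deterministic greedy stand-in for an external
clustering tool, at a configurable identity threshold.
"""

from __future__ import annotations

import dataclasses

import edlib
import numpy as np

from .structures import ComplexStructure, interchain_contact_map, interface_area

__all__ = ["CurationRule", "CurationDecision", "apply_curation",
           "pairwise_identity", "greedy_cluster"]


@dataclasses.dataclass
class CurationRule:
    min_interface_area: float = 500.0    # A^2, max over chain pairs must reach this
    min_interface_contacts: int = 10     # contacts at the maximum interface
    max_monomer_length: int = 1024
    min_chain_identity: float = 0.99     # intra-complex pairwise identity
    cluster_identity: float = 0.30
    require_symmetry_match: bool = True  # chain count == declared symmetry order
    contact_cutoff: float = 8.0
    sasa_points: int = 120

    def __post_init__(self):
        if self.min_interface_area <= 0 or self.min_interface_contacts <= 0:
            raise ValueError("interface thresholds must be positive")
        for frac in (self.min_chain_identity, self.cluster_identity):
            if not (0.0 < frac <= 1.0):
                raise ValueError("identity fractions must be in (0, 1]")


@dataclasses.dataclass
class CurationDecision:
    accepted: bool
    reasons: list             # names of failed criteria, empty when accepted


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity (matches / alignment length)."""
    if not a or not b:
        raise ValueError("empty sequence")
    res = edlib.align(a, b, task="path", mode="NW")
    nice = edlib.getNiceAlignment(res, a, b)
    matched = sum(ch == "|" for ch in nice["matched_aligned"])
    return matched / len(nice["matched_aligned"])


def apply_curation(c: ComplexStructure, rule: CurationRule | None = None) -> CurationDecision:
    """Accept/reject one complex with the full list of failed criteria."""
    rule = rule or CurationRule()
    reasons = []
    if rule.require_symmetry_match:
        if c.symmetry_order is None:
            raise ValueError(f"{c.name}: symmetry order annotation required by the chain-count rule")
        if c.n_chains != c.symmetry_order:
            reasons.append("chain_count")
    L = max(len(ch) for ch in c.chains)
    if L > rule.max_monomer_length:
        reasons.append("monomer_length")
    seqs = [ch.sequence for ch in c.chains]
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if pairwise_identity(seqs[i], seqs[j]) < rule.min_chain_identity:
                reasons.append("chain_identity")
                break
        else:
            continue
        break
    if c.n_chains < 2:
        reasons.extend(["interface_area", "contact_count"])
    else:
        best_area = 0.0
        for i in range(c.n_chains):
            for j in range(i + 1, c.n_chains):
                best_area = max(best_area, interface_area(
                    c, c.chains[i].chain_id, c.chains[j].chain_id,
                    n_points=rule.sasa_points))
        if best_area < rule.min_interface_area:
            reasons.append("interface_area")
        cm = interchain_contact_map(c, cutoff=rule.contact_cutoff)
        max_contacts = max(int(m.sum()) for m in cm.pair_maps.values())
        if max_contacts < rule.min_interface_contacts:
            reasons.append("contact_count")
    return CurationDecision(accepted=not reasons, reasons=reasons)


def _kmer_set(seq: str, k: int = 3):
    return {seq[i:i + k] for i in range(max(0, len(seq) - k + 1))}


def greedy_cluster(seqs, identity: float = 0.30) -> np.ndarray:
    """Greedy incremental clustering by global identity.

    Sequences are processed in input order; each joins the first
    existing cluster whose representative it matches at >= `identity`
    (with a k-mer Jaccard prefilter to skip hopeless comparisons),
    otherwise it founds a new cluster.  The representative is the
    cluster's first member, so the caller controls representative choice
    by pre-sorting (e.g. by resolution).
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("no sequences to cluster")
    if any(not s for s in seqs):
        raise ValueError("empty sequence in input")
    reps, rep_kmers = [], []
    assignment = np.full(len(seqs), -1, dtype=int)
    for idx, s in enumerate(seqs):
        km = _kmer_set(s)
        placed = False
        for cid, (rseq, rkm) in enumerate(zip(reps, rep_kmers)):
            union = len(km | rkm)
            jac = len(km & rkm) / union if union else 0.0
            # a pair under the identity threshold cannot share most k-mers;
            # only skip the alignment when the k-mer overlap is hopeless
            if jac < 0.02 and identity > 0.5:
                continue
            if pairwise_identity(s, rseq) >= identity:
                assignment[idx] = cid
                placed = True
                break
        if not placed:
            assignment[idx] = len(reps)
            reps.append(s)
            rep_kmers.append(km)
    return assignment
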