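"""MSA handling and sequence-derived features.

Covers alignment I/O (A3M / aligned FASTA), greedy diversity filtering,
weighted PSSM profiles, effective-sequence counts (M_eff), per-target
average column entropy, and a mean-field direct coupling analysis (DCA)
with average product correction (APC).

DCA here is the mean-field approximation (shrinkage-regularised
inversion of the one-hot column covariance) rather than the
pseudo-likelihood solvers used by dedicated GPU tools; externally
computed score matrices can be ingested in its place through the HDF5
feature container (see :mod:`tmcontact.features`).
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "AMINO_ACIDS", "MSAProfile", "DCAResult",
    "read_msa", "write_msa", "diversity_filter", "sequence_weights",
    "compute_pssm", "compute_meff", "average_entropy", "mean_field_dca",
    "apc_correct",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_ALPHABET = AMINO_ACIDS + GAP          # 21 states; gap is the last
_AA_INDEX = {a: i for i, a in enumerate(_ALPHABET)}


@dataclasses.dataclass
class MSAProfile:
    """Aligned rows (match states only) with the query as row 0."""

    rows: np.ndarray          # (M, L) uint8 indices into AMINO_ACIDS + '-'
    names: list

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.uint8)
        if self.rows.ndim != 2 or self.rows.shape[0] == 0:
            raise ValueError("MSA must be a non-empty 2-D row matrix")

    @property
    def depth(self) -> int:
        return self.rows.shape[0]

    @property
    def length(self) -> int:
        return self.rows.shape[1]

    def sequences(self):
        for row in self.rows:
            yield "".join(_ALPHABET[i] for i in row)

    @property
    def query(self) -> str:
        return "".join(_ALPHABET[i] for i in self.rows[0])

    @classmethod
    def from_sequences(cls, seqs, names=None) -> "MSAProfile":
        seqs = list(seqs)
        if not seqs:
            raise ValueError("empty MSA")
        L = len(seqs[0])
        if any(len(s) != L for s in seqs):
            raise ValueError("ragged alignment: rows differ in length")
        rows = np.zeros((len(seqs), L), dtype=np.uint8)
        for i, s in enumerate(seqs):
            for j, ch in enumerate(s.upper()):
                rows[i, j] = _AA_INDEX.get(ch, _AA_INDEX[GAP])
        return cls(rows=rows, names=names or [f"seq{i}" for i in range(len(seqs))])


def read_msa(path, fmt: str = "a3m") -> MSAProfile:
    """Read an A3M or aligned-FASTA file; first record is the query.

    A3M lowercase letters are insertions relative to the query and are
    removed, leaving match-state columns only.
    """
    names, seqs = [], []
    name, buf = None, []
    with open(path) as f:
        for line in f:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs.append("".join(buf))
                name = line[1:].split()[0] or f"seq{len(names)}"
                names.append(name)
                buf = []
            elif line:
                buf.append(line)
    if name is not None:
        seqs.append("".join(buf))
    if not seqs:
        raise ValueError(f"empty MSA file: {path}")
    if fmt == "a3m":
        seqs = ["".join(ch for ch in s if not ch.islower()).replace(".", "") for s in seqs]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment in {path}: lengths {sorted(lengths)}")
    prof = MSAProfile.from_sequences(seqs, names)
    if GAP in prof.query:
        raise ValueError(f"query row contains gaps in {path}")
    return prof


def write_msa(msa: MSAProfile, path):
    with open(path, "w") as f:
        for nm, seq in zip(msa.names, msa.sequences()):
            f.write(f">{nm}\n{seq}\n")


def diversity_filter(msa: MSAProfile, cap: int = 512) -> MSAProfile:
    """Keep the `cap` most diverse rows (greedy max-min Hamming, query first).

    Deterministic: ties are broken by the lowest row index.  Mirrors the
    diversity-filtering step commonly applied before feeding an MSA to a
    language model.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if msa.depth <= cap:
        return msa
    rows = msa.rows
    selected = [0]
    mind = (rows != rows[0]).sum(axis=1)
    mind[0] = -1
    while len(selected) < cap:
        pick = int(np.argmax(mind))
        selected.append(pick)
        d = (rows != rows[pick]).sum(axis=1)
        mind = np.minimum(mind, d)
        mind[pick] = -1
    return MSAProfile(rows=rows[selected], names=[msa.names[i] for i in selected])


# ----------------------------------------------------------------------
# weights / depth / conservation

def _pairwise_identity_matrix(rows: np.ndarray) -> np.ndarray:
    """Fraction identical over positions where neither row is gapped."""
    M = rows.shape[0]
    gap = _AA_INDEX[GAP]
    ident = np.ones((M, M))
    nongap = rows != gap
    for i in range(M):
        both = nongap[i] & nongap
        eq = (rows == rows[i]) & both
        denom = both.sum(axis=1)
        ident[i] = np.where(denom > 0, eq.sum(axis=1) / np.maximum(denom, 1), 0.0)
    return ident


def sequence_weights(msa: MSAProfile, identity: float = 0.80) -> np.ndarray:
    """Inverse-neighbourhood weights: w_s = 1/#{t : id(s,t) >= identity}."""
    ident = _pairwise_identity_matrix(msa.rows)
    counts = (ident >= identity).sum(axis=1)
    return 1.0 / counts


def compute_meff(msa: MSAProfile, identity: float = 0.70) -> float:
    """Effective number of sequences at the given identity threshold."""
    return float(sequence_weights(msa, identity=identity).sum())


def compute_pssm(msa: MSAProfile, weights: np.ndarray | None = None,
                 pseudocount: float = 1.0) -> np.ndarray:
    """(L, 20) sequence-weighted amino-acid profile; rows sum to 1.

    Gaps are excluded from the per-column denominator; a pseudocount is
    added per symbol.  An all-gap column yields a uniform row.
    """
    if weights is None:
        weights = sequence_weights(msa)
    rows = msa.rows
    L = msa.length
    counts = np.zeros((L, 20))
    for a in range(20):
        counts[:, a] = (weights[:, None] * (rows == a)).sum(axis=0)
    counts += pseudocount
    denom = counts.sum(axis=1, keepdims=True)
    zero = denom[:, 0] == 0
    pssm = np.where(denom > 0, counts / np.maximum(denom, 1e-300), 1.0 / 20)
    if zero.any():
        import warnings
        warnings.warn(f"{int(zero.sum())} all-gap columns with zero pseudocount; uniform rows used")
        pssm[zero] = 1.0 / 20
    return pssm


def average_entropy(msa: MSAProfile) -> float:
    """Mean per-column Shannon entropy (natural log) over the 20 amino acids.

    H = -(1/N) sum_i sum_j p_i^j ln p_i^j with observed (unweighted)
    frequencies, gaps excluded from the denominator; 0 ln 0 := 0.
    """
    rows = msa.rows
    L = msa.length
    H = 0.0
    for i in range(L):
        col = rows[:, i]
        col = col[col != _AA_INDEX[GAP]]
        if col.size == 0:
            continue
        counts = np.bincount(col, minlength=20)[:20]
        p = counts / col.size
        nz = p > 0
        H -= float((p[nz] * np.log(p[nz])).sum())
    return H / L


# ----------------------------------------------------------------------
# direct coupling analysis

def apc_correct(S: np.ndarray) -> np.ndarray:
    """Average product correction: S_apc(i,j) = S_ij - S_i. * S_.j / S_..

    Row, column, and grand means are over the full matrix; an exactly
    rank-one score matrix is annihilated off the diagonal.
    """
    S = np.asarray(S, dtype=float)
    row_mean = S.mean(axis=1)
    col_mean = S.mean(axis=0)
    total = S.mean()
    if total == 0:
        corrected = S.copy()
    else:
        corrected = S - np.outer(row_mean, col_mean) / total
    np.fill_diagonal(corrected, 0.0)
    return corrected


@dataclasses.dataclass
class DCAResult:
    di: np.ndarray     # raw (Frobenius-norm) coupling scores, (L, L)
    apc: np.ndarray    # APC-corrected scores, (L, L)


def mean_field_dca(msa: MSAProfile, shrinkage: float = 0.5) -> DCAResult:
    """Mean-field DCA: invert the shrinkage-regularised column covariance.

    One-hot encodes 20 amino-acid states per column (gap as reference
    state), forms the sequence-weighted covariance, shrinks it towards a
    scaled identity, and scores couplings by the Frobenius norm of the
    inverse blocks.  Returns raw and APC-corrected (L, L) matrices.
    """
    if not (0.0 <= shrinkage < 1.0):
        raise ValueError("shrinkage must be in [0, 1)")
    w = sequence_weights(msa)
    if w.sum() < 2.0:
        raise ValueError("mean-field DCA needs at least 2 effective sequences")
    rows = msa.rows
    M, L = rows.shape
    q = 20                                # gap is the implicit reference state
    X = np.zeros((M, L * q))
    # layout: per-position blocks [i*q + a]
    for i in range(L):
        for a in range(q):
            X[:, i * q + a] = rows[:, i] == a
    wn = w / w.sum()
    mu = wn @ X
    Xc = X - mu
    C = (Xc * wn[:, None]).T @ Xc
    tr = np.trace(C)
    dim = C.shape[0]
    if tr <= 0:
        raise np.linalg.LinAlgError(
            "covariance has zero trace (fully conserved MSA); increase diversity or shrinkage")
    C_shrunk = (1.0 - shrinkage) * C + shrinkage * (tr / dim) * np.eye(dim)
    try:
        J = -np.linalg.inv(C_shrunk)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular covariance after shrinkage; try a higher shrinkage value") from None
    S = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            block = J[i * q:(i + 1) * q, j * q:(j + 1) * q]
            S[i, j] = S[j, i] = np.sqrt((block ** 2).sum())
    np.fill_diagonal(S, 0.0)
    return DCAResult(di=S, apc=apc_correct(S))
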