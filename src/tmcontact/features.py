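"""Feature assembly: pair tensors for receptor, ligand, and complex.

The pair tensor concatenates, channel-wise:

* tiled PSSM rows (query position i) and columns (position j), 20 + 20
* DCA raw and APC-corrected coupling scores, 1 + 1
* language-model pair attentions, 144
* row/column projections of the language-model embedding, 16 + 16
* (receptor/ligand only) the RBF-encoded intra-chain distance map, 64

A channel manifest records each block's span so downstream code can
locate or swap out individual feature families.  The complex tensor
omits the distance block: inter-chain geometry is what the network must
predict, so it never sees it as input.
"""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np

from .structures import DistanceEncoding

__all__ = [
    "LM_EMBED_DIM", "LM_ATTN_CHANNELS", "EMB_PROJ_DIM",
    "LMFeatures", "FeatureBundle",
    "ingest_lm_features", "assemble_features",
    "write_lm_features", "write_bundle", "read_bundle",
]

LM_EMBED_DIM = 768        # per-residue embedding width
LM_ATTN_CHANNELS = 144    # stacked row-attention maps (12 layers x 12 heads)
EMB_PROJ_DIM = 16         # fixed random projection of the embedding per side
_PROJ_SEED = 768144       # part of the feature definition, not a run seed


@dataclasses.dataclass
class LMFeatures:
    embedding: np.ndarray   # (L, 768)
    attentions: np.ndarray  # (L, L, 144)

    def __post_init__(self):
        e, a = np.asarray(self.embedding), np.asarray(self.attentions)
        L = e.shape[0]
        if e.ndim != 2 or e.shape[1] != LM_EMBED_DIM:
            raise ValueError(f"embedding must be (L, {LM_EMBED_DIM}); got {e.shape}")
        if a.ndim != 3 or a.shape[2] != LM_ATTN_CHANNELS:
            raise ValueError(f"attentions must be (L, L, {LM_ATTN_CHANNELS}); got {a.shape}")
        if a.shape[0] != L or a.shape[1] != L:
            raise ValueError(f"attention leading dims {a.shape[:2]} != embedding length {L}")
        for name, arr in (("embedding", e), ("attentions", a)):
            if not np.isfinite(arr).all():
                idx = tuple(int(k) for k in np.argwhere(~np.isfinite(arr))[0])
                raise ValueError(f"non-finite value in {name} at index {idx}")
        self.embedding, self.attentions = e, a

    @property
    def L(self) -> int:
        return self.embedding.shape[0]


def ingest_lm_features(embedding_path, attentions_path=None, L: int | None = None) -> LMFeatures:
    """Load externally computed language-model tensors from HDF5.

    One file holding datasets ``embedding`` and ``attentions``, or two
    files.  Shapes are validated against the stated dimensions and,
    when given, the expected sequence length L.
    """
    with h5py.File(embedding_path, "r") as f:
        emb = np.asarray(f["embedding"])
        if attentions_path is None:
            attn = np.asarray(f["attentions"])
    if attentions_path is not None:
        with h5py.File(attentions_path, "r") as f:
            attn = np.asarray(f["attentions"])
    lm = LMFeatures(embedding=emb, attentions=attn)
    if L is not None and lm.L != L:
        raise ValueError(f"language-model features have L={lm.L}, expected {L}")
    return lm


def write_lm_features(path, lm: LMFeatures):
    with h5py.File(path, "w") as f:
        f.create_dataset("embedding", data=lm.embedding)
        f.create_dataset("attentions", data=lm.attentions)


def _embedding_projection() -> np.ndarray:
    rng = np.random.default_rng(_PROJ_SEED)
    return rng.normal(0.0, 1.0 / np.sqrt(LM_EMBED_DIM), size=(LM_EMBED_DIM, EMB_PROJ_DIM))


@dataclasses.dataclass
class FeatureBundle:
    receptor: np.ndarray        # (L, L, C + 64)
    complex: np.ndarray         # (L, L, C)
    manifest: list              # [(name, start, stop)] for the receptor tensor

    @property
    def ligand(self) -> np.ndarray:
        # identical chains in a homo-oligomer share one monomer feature set
        return self.receptor

    @property
    def L(self) -> int:
        return self.complex.shape[0]

    def span(self, name: str) -> slice:
        for n, a, b in self.manifest:
            if n == name:
                return slice(a, b)
        raise KeyError(name)


def assemble_features(pssm: np.ndarray, dca, lm: LMFeatures,
                      enc: DistanceEncoding | np.ndarray | None) -> FeatureBundle:
    """Build receptor and complex pair tensors from per-family features.

    `enc` is the monomer distance encoding; it is appended to the
    receptor/ligand tensor only.  All inputs must share L.
    """
    pssm = np.asarray(pssm, dtype=np.float32)
    L = pssm.shape[0]
    if pssm.shape != (L, 20):
        raise ValueError(f"PSSM must be (L, 20); got {pssm.shape}")
    di, apc = np.asarray(dca.di), np.asarray(dca.apc)
    if di.shape != (L, L) or apc.shape != (L, L):
        raise ValueError("DCA matrices must be (L, L)")
    if lm.L != L:
        raise ValueError(f"language-model L={lm.L} != PSSM L={L}")
    proj = (lm.embedding @ _embedding_projection()).astype(np.float32)  # (L, 16)

    blocks = [
        ("pssm_i", np.broadcast_to(pssm[:, None, :], (L, L, 20))),
        ("pssm_j", np.broadcast_to(pssm[None, :, :], (L, L, 20))),
        ("dca_di", di[:, :, None]),
        ("dca_apc", apc[:, :, None]),
        ("lm_attn", lm.attentions),
        ("emb_i", np.broadcast_to(proj[:, None, :], (L, L, EMB_PROJ_DIM))),
        ("emb_j", np.broadcast_to(proj[None, :, :], (L, L, EMB_PROJ_DIM))),
    ]
    if enc is not None:
        vals = enc.values if isinstance(enc, DistanceEncoding) else np.asarray(enc)
        if vals.shape[:2] != (L, L):
            raise ValueError("distance encoding L mismatch")
        blocks.append(("dist_rbf", vals))

    manifest, arrays, off = [], [], 0
    for name, arr in blocks:
        arr = np.asarray(arr, dtype=np.float32)
        manifest.append((name, off, off + arr.shape[2]))
        arrays.append(arr)
        off += arr.shape[2]
    spans = [(a, b) for _, a, b in manifest]
    assert all(b0 <= a1 for (_, b0), (a1, _) in zip(spans, spans[1:])), "manifest overlap"
    receptor = np.concatenate(arrays, axis=2)
    n_complex = manifest[-1][1] if enc is not None else off  # complex drops the distance block
    return FeatureBundle(receptor=receptor, complex=receptor[:, :, :n_complex].copy(),
                         manifest=manifest)


def write_bundle(path, bundle: FeatureBundle, extra: dict | None = None):
    """Write the bundle (plus optional named feature matrices, e.g. the
    raw pssm / dca_di / dca_apc arrays) to one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("receptor", data=bundle.receptor)
        f.create_dataset("complex", data=bundle.complex)
        names = [n for n, _, _ in bundle.manifest]
        spans = np.array([[a, b] for _, a, b in bundle.manifest])
        f.create_dataset("manifest_spans", data=spans)
        f.attrs["manifest_names"] = ",".join(names)
        for name, arr in (extra or {}).items():
            f.create_dataset(name, data=np.asarray(arr))


def read_bundle(path) -> FeatureBundle:
    with h5py.File(path, "r") as f:
        receptor = np.asarray(f["receptor"])
        complex_ = np.asarray(f["complex"])
        spans = np.asarray(f["manifest_spans"])
        names = f.attrs["manifest_names"].split(",")
    manifest = [(n, int(a), int(b)) for n, (a, b) in zip(names, spans)]
    return FeatureBundle(receptor=receptor, complex=complex_, manifest=manifest)
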