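"""Synthetic Cn-symmetric benchmark generation.

Everything the predictor consumes can be generated here at desk scale:

* toy helical-bundle complexes with exact Cn rotational symmetry and a
  tunable inter-chain interface (ring radius sets helix-helix spacing);
* synthetic MSAs whose true interface column pairs covary;
* surrogate language-model tensors in which a fixed subset of the
  attention channels carries a noisy copy of the true inter-chain
  contact map (what a co-evolution-aware language model would expose);
* a train/valid/test benchmark with a "soluble-like" regime (abundant,
  cleaner signal, C2 dimers) and a "TMP-like" regime (scarce, noisier
  signal, higher symmetry orders, hydrophobic-biased sequences, tilted
  helix packing), the desk-scale analogue of transferring from soluble
  complexes to membrane complexes.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import features as feat
from . import msa as msamod
from .structures import (Chain, ComplexStructure, ContactMap, ONE_TO_THREE,
                         Residue, compute_sasa, encode_distance_rbf,
                         interchain_contact_map, intrachain_distance_map)
from .train import TrainingTarget

__all__ = [
    "BenchmarkConfig", "SyntheticBenchmark",
    "make_toy_complex", "make_synthetic_msa", "make_surrogate_lm_features",
    "build_target", "build_transfer_benchmark", "write_pdb",
]

HELIX_RISE = 1.5          # A per residue along the helix axis
HELIX_TWIST = 100.0       # degrees per residue
HELIX_RADIUS = 2.3        # Ca radius of an ideal alpha-helix

HYDROPHOBIC = "AVLIMFWC"
MIXED = msamod.AMINO_ACIDS

# Attention channels that carry the interface signal in surrogate features.
# The two regimes express the signal on half-overlapping channel sets: a
# model trained on one regime reads the other's features only partially,
# emulating the domain shift between soluble and membrane co-evolution
# statistics that motivates transfer learning.
SIGNAL_CHANNELS = tuple(range(8))            # default (soluble-like)
SIGNAL_CHANNELS_TMP = tuple(range(4, 12))    # shares 4-7 with the soluble set


# ----------------------------------------------------------------------
# structures

def _rotz(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _helix_chain(L: int, seq: str, tilt_deg: float) -> list:
    """Ideal alpha-helix (Ca + Cb pseudo side chain) along +z at the origin."""
    residues = []
    tilt = np.deg2rad(tilt_deg)
    tilt_mat = np.array([[1.0, 0.0, 0.0],
                         [0.0, np.cos(tilt), -np.sin(tilt)],
                         [0.0, np.sin(tilt), np.cos(tilt)]])
    for t in range(L):
        ang = np.deg2rad(HELIX_TWIST * t)
        ca = np.array([HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang),
                       HELIX_RISE * t])
        cb = np.array([(HELIX_RADIUS + 1.5) * np.cos(ang),
                       (HELIX_RADIUS + 1.5) * np.sin(ang), HELIX_RISE * t])
        ca, cb = tilt_mat @ ca, tilt_mat @ cb
        aa = seq[t]
        names = ["CA"] if aa == "G" else ["CA", "CB"]
        coords = np.array([ca] if aa == "G" else [ca, cb])
        residues.append(Residue(index=t, name=ONE_TO_THREE.get(aa, "ALA"), aa=aa,
                                author_seq_id=t + 1, atom_names=names,
                                coords=coords, elements=["C"] * len(names)))
    return residues


def make_toy_complex(n_chains: int, L: int, seed: int,
                     regime: str = "soluble",
                     axis_separation: float | None = None) -> ComplexStructure:
    """Cn-symmetric bundle of ideal helices about the z axis.

    `axis_separation` is the distance between adjacent helix axes; the
    ring radius follows from it.  The `tmp` regime uses tilted helix
    packing and a hydrophobic-biased sequence, making the two regimes
    statistically distinguishable.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if L < 20:
        raise ValueError("L must be >= 20")
    if regime not in ("soluble", "tmp"):
        raise ValueError("regime must be 'soluble' or 'tmp'")
    rng = np.random.default_rng(seed)
    if regime == "tmp":
        alphabet = HYDROPHOBIC * 2 + MIXED   # hydrophobic-biased draw
        tilt = 10.0
        sep = 9.5 if axis_separation is None else axis_separation
    else:
        alphabet = MIXED
        tilt = 0.0
        sep = 9.0 if axis_separation is None else axis_separation
    seq = "".join(rng.choice(list(alphabet), size=L))
    base = _helix_chain(L, seq, tilt)
    if n_chains == 1:
        ring_r = 0.0
    else:
        ring_r = sep / (2.0 * np.sin(np.pi / n_chains))
    chains = []
    for k in range(n_chains):
        theta = 2.0 * np.pi * k / max(n_chains, 1)
        rot = _rotz(theta)
        residues = []
        for r in base:
            coords = (rot @ (r.coords + np.array([ring_r, 0.0, 0.0])).T).T
            residues.append(Residue(index=r.index, name=r.name, aa=r.aa,
                                    author_seq_id=r.author_seq_id,
                                    atom_names=list(r.atom_names),
                                    coords=coords, elements=list(r.elements)))
        chains.append(Chain(chr(ord("A") + k), residues))
    return ComplexStructure(chains, name=f"toy_{regime}_c{n_chains}_L{L}_s{seed}",
                            symmetry_order=n_chains)


def write_pdb(c: ComplexStructure, path):
    """Minimal PDB writer for the synthetic complexes."""
    with open(path, "w") as f:
        serial = 1
        for ch in c.chains:
            for r in ch.residues:
                for name, el, xyz in zip(r.atom_names, r.elements, r.coords):
                    f.write(
                        f"ATOM  {serial:5d} {name:^4s}{r.name:>4s} {ch.chain_id}"
                        f"{r.author_seq_id:4d}    "
                        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                        f"{1.00:6.2f}{0.00:6.2f}          {el:>2s}\n")
                    serial += 1
            f.write("TER\n")
        f.write("END\n")


# ----------------------------------------------------------------------
# MSAs

def _interface_pairs(truth: np.ndarray, max_pairs: int = 40) -> list:
    """Disjoint upper-triangle interface pairs (a greedy matching).

    Each column joins at most one coupled pair, so the pairwise
    covariation written into the MSA is not overwritten by a later,
    overlapping pair.
    """
    iu, ju = np.triu_indices_from(truth, k=1)
    used, pairs = set(), []
    for i, j in zip(iu, ju):
        if truth[i, j] and i not in used and j not in used:
            pairs.append((int(i), int(j)))
            used.update((int(i), int(j)))
            if len(pairs) >= max_pairs:
                break
    return pairs


def make_synthetic_msa(c: ComplexStructure, depth: int = 200,
                       mutation_rate: float = 0.35,
                       coupling_strength: float = 0.85,
                       seed: int = 0,
                       truth: np.ndarray | None = None) -> msamod.MSAProfile:
    """Sample an MSA whose interface columns covary.

    Non-interface columns mutate i.i.d. at `mutation_rate`; interface
    pairs jointly adopt one of a few compatible residue-pair states with
    probability `coupling_strength`.  Row 0 is the native sequence.
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    rng = np.random.default_rng(seed)
    query = c.chains[0].sequence
    L = len(query)
    if truth is None:
        if c.n_chains >= 2:
            truth = interchain_contact_map(c).union
        else:
            truth = np.zeros((L, L), dtype=bool)
    pairs = _interface_pairs(truth)
    aa_idx = {a: i for i, a in enumerate(msamod.AMINO_ACIDS)}
    qrow = np.array([aa_idx[a] for a in query], dtype=np.uint8)
    rows = np.tile(qrow, (depth, 1))
    # i.i.d. column mutation
    mut = rng.random((depth, L)) < mutation_rate
    mut[0] = False
    repl = rng.integers(0, 20, size=(depth, L), dtype=np.uint8)
    rows = np.where(mut, repl, rows)
    # joint compatible states for interface pairs
    combos = {p: rng.integers(0, 20, size=(3, 2), dtype=np.uint8) for p in pairs}
    for (i, j), states in combos.items():
        couple = rng.random(depth) < coupling_strength
        couple[0] = False
        pick = rng.integers(0, len(states), size=depth)
        rows[couple, i] = states[pick[couple], 0]
        rows[couple, j] = states[pick[couple], 1]
    names = [c.name or "query"] + [f"synth{i}" for i in range(1, depth)]
    return msamod.MSAProfile(rows=rows, names=names)


# ----------------------------------------------------------------------
# surrogate language-model features

def make_surrogate_lm_features(c: ComplexStructure, truth: np.ndarray,
                               noise: float = 0.3, seed: int = 0,
                               signal_channels=SIGNAL_CHANNELS) -> feat.LMFeatures:
    """Surrogate for external language-model tensors.

    The embedding is seeded pseudo-random; the `signal_channels` subset
    of attention channels carries truth + Gaussian noise (sigma =
    `noise`), the rest are noise-only.
    """
    L = len(c.chains[0])
    truth = np.asarray(truth, dtype=float)
    if truth.shape != (L, L):
        raise ValueError(f"truth shape {truth.shape} != ({L}, {L})")
    rng = np.random.default_rng(seed)
    emb = rng.normal(0.0, 1.0, size=(L, feat.LM_EMBED_DIM))
    attn = rng.normal(0.0, 0.5, size=(L, L, feat.LM_ATTN_CHANNELS))
    for ch in signal_channels:
        attn[:, :, ch] = truth + (rng.normal(0.0, noise, size=(L, L)) if noise > 0 else 0.0)
    return feat.LMFeatures(embedding=emb, attentions=attn)


# ----------------------------------------------------------------------
# benchmark

@dataclasses.dataclass
class BenchmarkConfig:
    n_soluble_train: int = 60
    n_soluble_valid: int = 12
    n_tmp_train: int = 12
    n_tmp_valid: int = 4
    n_tmp_test: int = 8
    L_min: int = 48
    L_max: int = 64
    msa_depth: int = 200           # soluble-like MSAs are deep ...
    msa_depth_tmp: int = 80        # ... membrane-like MSAs are shallow
    mutation_rate: float = 0.35
    coupling_strength: float = 0.85
    coupling_strength_tmp: float = 0.6
    noise_soluble: float = 1.0     # per-channel sigma; signal must be pooled
    noise_tmp: float = 1.5         # across channels and corroborated by DCA
    tmp_chain_choices: tuple = (2, 3, 4)

    def __post_init__(self):
        for fld in ("n_soluble_train", "n_soluble_valid", "n_tmp_train",
                    "n_tmp_valid", "n_tmp_test"):
            if getattr(self, fld) < 1:
                raise ValueError(f"{fld} must be >= 1")


@dataclasses.dataclass
class SyntheticBenchmark:
    soluble_train: list
    soluble_valid: list
    tmp_train: list
    tmp_valid: list
    tmp_test: list
    seed: int = 0
    config: BenchmarkConfig | None = None

    def all_targets(self):
        return (self.soluble_train + self.soluble_valid + self.tmp_train
                + self.tmp_valid + self.tmp_test)


def build_target(regime: str, seed: int, cfg: BenchmarkConfig) -> TrainingTarget:
    """One fully featurised synthetic target."""
    rng = np.random.default_rng(seed)
    L = int(rng.integers(cfg.L_min, cfg.L_max + 1))
    if regime == "tmp":
        n_chains = int(rng.choice(cfg.tmp_chain_choices))
        noise = cfg.noise_tmp
        channels = SIGNAL_CHANNELS_TMP
        depth, coupling = cfg.msa_depth_tmp, cfg.coupling_strength_tmp
    else:
        n_chains = 2
        noise = cfg.noise_soluble
        channels = SIGNAL_CHANNELS
        depth, coupling = cfg.msa_depth, cfg.coupling_strength
    sub = rng.integers(0, 2 ** 31 - 1)
    c = make_toy_complex(n_chains, L, int(sub), regime=regime)
    truth = interchain_contact_map(c)
    mono = c.monomer()
    dmap = intrachain_distance_map(mono)
    surf = compute_sasa(mono)
    msa = make_synthetic_msa(c, depth=depth, mutation_rate=cfg.mutation_rate,
                             coupling_strength=coupling,
                             seed=int(rng.integers(0, 2 ** 31 - 1)), truth=truth.union)
    weights = msamod.sequence_weights(msa)
    pssm = msamod.compute_pssm(msa, weights=weights)
    dca = msamod.mean_field_dca(msa)
    lm = make_surrogate_lm_features(c, truth.union, noise=noise,
                                    seed=int(rng.integers(0, 2 ** 31 - 1)),
                                    signal_channels=channels)
    enc = encode_distance_rbf(dmap)
    bundle = feat.assemble_features(pssm, dca, lm, enc)
    return TrainingTarget(name=c.name, bundle=bundle, dmap=dmap, surface=surf,
                          truth=truth.union, L=L, structure=c)


def build_transfer_benchmark(cfg: BenchmarkConfig | None = None,
                             seed: int = 0) -> SyntheticBenchmark:
    """Disjoint soluble-like and TMP-like splits; reproducible per seed."""
    cfg = cfg or BenchmarkConfig()
    root = np.random.default_rng(seed)
    counts = [
        ("soluble", cfg.n_soluble_train), ("soluble", cfg.n_soluble_valid),
        ("tmp", cfg.n_tmp_train), ("tmp", cfg.n_tmp_valid), ("tmp", cfg.n_tmp_test),
    ]
    splits = []
    for regime, n in counts:
        targets = []
        for _ in range(n):
            targets.append(build_target(regime, int(root.integers(0, 2 ** 31 - 1)), cfg))
        splits.append(targets)
    return SyntheticBenchmark(*splits, seed=seed, config=cfg)
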