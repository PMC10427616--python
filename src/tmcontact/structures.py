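"""Structure handling: parsing, contact maps, distance maps, RBF encoding, SASA.

All geometry is computed on heavy atoms (hydrogens are dropped at parse
time).  The inter-chain contact definition is the field-standard one for
homo-oligomer interface prediction: two residues from different chains
are in contact when any two of their heavy atoms lie within 8 A
(inclusive).  The intra-chain distance map uses the Cb atom (Ca for
glycine), the community convention for contact/distance features.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import gemmi
import h5py
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

__all__ = [
    "Residue", "Chain", "ComplexStructure", "ContactMap", "DistanceMap",
    "DistanceEncoding", "SurfaceAnnotation",
    "parse_structure", "interchain_contact_map", "intrachain_distance_map",
    "encode_distance_rbf", "compute_sasa", "interface_area",
    "write_map_h5", "write_map_text",
    "RBF_N_BINS", "RBF_SIGMA", "RBF_MIN", "rbf_bin_centers",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# van der Waals radii (A) used by the SASA quadrature
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}
DEFAULT_VDW = 1.70
PROBE_RADIUS = 1.4

# Maximum (Gly-X-Gly extended tripeptide) per-residue SASA in A^2,
# theoretical values of Tien et al. 2013, used to normalise to relative SASA.
MAX_SASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}
SURFACE_REL_SASA = 0.05

RBF_N_BINS = 64
RBF_SIGMA = 0.3125
RBF_MIN = 2.0


def rbf_bin_centers() -> np.ndarray:
    """Bin centers d_k = 2 + 0.3125*k for k = 0..63, spanning 2-22 A."""
    return RBF_MIN + RBF_SIGMA * np.arange(RBF_N_BINS)


# ----------------------------------------------------------------------
# containers

@dataclasses.dataclass
class Residue:
    index: int                 # 0-based position within the chain
    name: str                  # three-letter code
    aa: str                    # one-letter code ('X' for non-standard)
    author_seq_id: int         # residue number as authored in the file
    atom_names: list
    coords: np.ndarray         # (n_atoms, 3) heavy-atom coordinates
    elements: list

    def atom(self, name: str) -> np.ndarray | None:
        try:
            return self.coords[self.atom_names.index(name)]
        except ValueError:
            return None

    def representative_atom(self) -> np.ndarray | None:
        """Cb, falling back to Ca for glycine (or when Cb is absent)."""
        if self.aa != "G":
            cb = self.atom("CB")
            if cb is not None:
                return cb
        return self.atom("CA")


@dataclasses.dataclass
class Chain:
    chain_id: str
    residues: list

    def __len__(self):
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def all_coords(self) -> np.ndarray:
        return np.concatenate([r.coords for r in self.residues], axis=0)

    def atom_residue_index(self) -> np.ndarray:
        return np.concatenate([np.full(len(r.atom_names), r.index) for r in self.residues])

    def all_elements(self) -> list:
        out = []
        for r in self.residues:
            out.extend(r.elements)
        return out


@dataclasses.dataclass
class ComplexStructure:
    chains: list
    name: str = ""
    symmetry_order: int | None = None   # declared Cn order, when known

    def __post_init__(self):
        for ch in self.chains:
            idx = [r.index for r in ch.residues]
            if idx != sorted(set(idx)):
                raise ValueError(f"chain {ch.chain_id}: residue indices not strictly increasing")
            for r in ch.residues:
                if len(r.atom_names) == 0:
                    raise ValueError(f"chain {ch.chain_id} residue {r.index}: no heavy atoms")

    @property
    def n_chains(self):
        return len(self.chains)

    def chain(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"chain {chain_id!r} not found")

    def monomer(self, chain_id: str | None = None) -> "ComplexStructure":
        ch = self.chains[0] if chain_id is None else self.chain(chain_id)
        return ComplexStructure([ch], name=f"{self.name}:{ch.chain_id}",
                                symmetry_order=1)


@dataclasses.dataclass
class ContactMap:
    union: np.ndarray                     # (L, L) bool, OR over chain pairs, symmetrized
    pair_maps: dict                       # (chain_i, chain_j) -> (L, L) bool
    cutoff: float

    @property
    def L(self):
        return self.union.shape[0]


@dataclasses.dataclass
class DistanceMap:
    values: np.ndarray                    # (L, L), +inf rows where rep atom missing
    missing: np.ndarray                   # (L,) bool flags

    @property
    def L(self):
        return self.values.shape[0]


@dataclasses.dataclass
class DistanceEncoding:
    values: np.ndarray                    # (L, L, 64) in [0, 1]
    bin_centers: np.ndarray
    sigma: float


@dataclasses.dataclass
class SurfaceAnnotation:
    sasa: np.ndarray                      # (L,) absolute per-residue SASA, A^2
    rel_sasa: np.ndarray                  # (L,) fraction of Gly-X-Gly reference
    surface: np.ndarray                   # (L,) bool, rel_sasa >= threshold


# ----------------------------------------------------------------------
# parsing

class StructureParseError(ValueError):
    pass


def parse_structure(path, fmt: str = "auto") -> ComplexStructure:
    """Read a PDB or mmCIF file into a :class:`ComplexStructure`.

    Hydrogens are dropped; alternate locations are resolved to the
    highest-occupancy conformer; only the first model is used.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise StructureParseError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as e:
        raise StructureParseError(f"failed to parse {path}: {e}") from None
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models")
    model = st[0]
    chains = []
    for gch in model:
        residues = []
        for ridx, gres in enumerate(gch):
            if gres.is_water():
                continue
            # resolve altlocs: keep highest occupancy per atom name
            best = {}
            for atom in gres:
                if atom.is_hydrogen():
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            if not best:
                continue
            names = sorted(best)
            coords = np.array([[best[n].pos.x, best[n].pos.y, best[n].pos.z] for n in names])
            elements = [best[n].element.name.upper() for n in names]
            rname = gres.name
            residues.append(Residue(
                index=len(residues), name=rname,
                aa=THREE_TO_ONE.get(rname, "X"),
                author_seq_id=gres.seqid.num,
                atom_names=names, coords=coords, elements=elements,
            ))
        if residues:
            chains.append(Chain(gch.name, residues))
    if not chains:
        raise StructureParseError(f"{path}: no chains with heavy atoms")
    return ComplexStructure(chains, name=path.stem)


# ----------------------------------------------------------------------
# contact & distance maps

def interchain_contact_map(c: ComplexStructure, cutoff: float = 8.0) -> ContactMap:
    """Inter-chain contacts: min heavy-atom distance <= cutoff (inclusive).

    All chains must have equal length (homo-oligomer); the union map is
    the OR over all ordered chain pairs, then symmetrized over (i,j).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if c.n_chains < 2:
        raise ValueError("inter-chain contacts require at least two chains")
    lengths = {len(ch) for ch in c.chains}
    if len(lengths) != 1:
        raise ValueError(f"chains differ in length ({sorted(lengths)}); homo-oligomer required")
    L = lengths.pop()
    per_chain = []
    for ch in c.chains:
        per_chain.append((ch.all_coords(), ch.atom_residue_index()))
    pair_maps = {}
    union = np.zeros((L, L), dtype=bool)
    for a in range(c.n_chains):
        for b in range(c.n_chains):
            if a == b:
                continue
            xa, ia = per_chain[a]
            xb, ib = per_chain[b]
            d = cdist(xa, xb)
            m = np.full((L, L), np.inf)
            rows = np.broadcast_to(ia[:, None], d.shape).ravel()
            cols = np.broadcast_to(ib[None, :], d.shape).ravel()
            np.minimum.at(m, (rows, cols), d.ravel())
            cm = m <= cutoff
            pair_maps[(c.chains[a].chain_id, c.chains[b].chain_id)] = cm
            union |= cm
    union |= union.T
    return ContactMap(union=union, pair_maps=pair_maps, cutoff=cutoff)


def intrachain_distance_map(monomer: ComplexStructure) -> DistanceMap:
    """Representative-atom (Cb; Ca for Gly) distances within one chain."""
    if monomer.n_chains != 1:
        raise ValueError("intrachain_distance_map expects a single-chain structure")
    ch = monomer.chains[0]
    L = len(ch)
    reps = np.full((L, 3), np.nan)
    missing = np.zeros(L, dtype=bool)
    for r in ch.residues:
        rep = r.representative_atom()
        if rep is None:
            missing[r.index] = True
        else:
            reps[r.index] = rep
    values = np.full((L, L), np.inf)
    ok = ~missing
    if ok.any():
        sub = cdist(reps[ok], reps[ok])
        values[np.ix_(ok, ok)] = sub
    np.fill_diagonal(values, np.where(missing, np.inf, 0.0))
    return DistanceMap(values=values, missing=missing)


def encode_distance_rbf(dm: DistanceMap | np.ndarray) -> DistanceEncoding:
    """Gaussian radial-basis encoding of distances into 64 bins over 2-22 A.

    f_k(d) = exp(-((d - d_k)/sigma)^2), sigma = 0.3125 A.  Rows/columns
    with a missing representative atom (+inf sentinel) encode to zeros.
    """
    d = dm.values if isinstance(dm, DistanceMap) else np.asarray(dm, dtype=float)
    centers = rbf_bin_centers()
    finite = np.isfinite(d)
    dsafe = np.where(finite, d, 0.0)
    enc = np.exp(-(((dsafe[..., None] - centers) / RBF_SIGMA) ** 2))
    enc = np.where(finite[..., None], enc, 0.0)
    return DistanceEncoding(values=enc, bin_centers=centers, sigma=RBF_SIGMA)


# ----------------------------------------------------------------------
# solvent accessibility

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def compute_sasa(c: ComplexStructure, chain_ids=None, n_points: int = 400) -> SurfaceAnnotation:
    """Shrake-Rupley solvent-accessible surface area, probe 1.4 A.

    A fixed Fibonacci lattice of `n_points` per atom makes the
    quadrature deterministic.  When `chain_ids` selects a subset, only
    those chains exist for the calculation (the rest are removed, not
    treated as occluders).  Per-residue sums are concatenated in chain
    order.
    """
    if chain_ids is None:
        chains = c.chains
    else:
        chains = [c.chain(cid) for cid in chain_ids]
    coords, radii, res_key = [], [], []
    offsets = []
    off = 0
    for ch in chains:
        offsets.append(off)
        for r in ch.residues:
            for name, el in zip(r.atom_names, r.elements):
                res_key.append(off + r.index)
            coords.append(r.coords)
            radii.extend(_atom_radius(e) for e in r.elements)
        off += len(ch)
    coords = np.concatenate(coords, axis=0)
    radii = np.asarray(radii) + PROBE_RADIUS
    res_key = np.asarray(res_key)
    n_res = off
    sphere = _fibonacci_sphere(n_points)

    tree = cKDTree(coords)
    max_r = radii.max()
    sasa_atom = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * sphere
        neigh = tree.query_ball_point(coords[i], radii[i] + max_r)
        neigh = [j for j in neigh if j != i]
        if neigh:
            d2 = ((pts[:, None, :] - coords[neigh][None, :, :]) ** 2).sum(-1)
            buried = (d2 <= (radii[neigh] ** 2)[None, :]).any(axis=1)
            exposed = int((~buried).sum())
        else:
            exposed = n_points
        sasa_atom[i] = 4.0 * math.pi * radii[i] ** 2 * exposed / n_points

    sasa = np.zeros(n_res)
    np.add.at(sasa, res_key, sasa_atom)
    aas = [r.aa for ch in chains for r in ch.residues]
    ref = np.array([MAX_SASA.get(a, 200.0) for a in aas])
    rel = sasa / ref
    return SurfaceAnnotation(sasa=sasa, rel_sasa=rel, surface=rel >= SURFACE_REL_SASA)


def interface_area(c: ComplexStructure, chain_a: str, chain_b: str,
                   n_points: int = 400) -> float:
    """Buried-surface interface area between two chains, in A^2.

    (SASA_A + SASA_B - SASA_AB) / 2, clamped at zero.
    """
    sa = compute_sasa(c, [chain_a], n_points=n_points).sasa.sum()
    sb = compute_sasa(c, [chain_b], n_points=n_points).sasa.sum()
    sab = compute_sasa(c, [chain_a, chain_b], n_points=n_points).sasa.sum()
    return max(0.0, (sa + sb - sab) / 2.0)


# ----------------------------------------------------------------------
# output

def write_map_h5(path, name: str, matrix: np.ndarray, attrs: dict | None = None):
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        ds = f.create_dataset(name, data=matrix)
        for k, v in (attrs or {}).items():
            ds.attrs[k] = v


def write_map_text(path, matrix: np.ndarray, threshold: float | None = None):
    """3-column text (i, j, value), 1-based indices, row-major order."""
    with open(path, "w") as f:
        for i in range(matrix.shape[0]):
            for j in range(matrix.shape[1]):
                v = matrix[i, j]
                if threshold is not None and not (v > threshold):
                    continue
                f.write(f"{i + 1}\t{j + 1}\t{v:g}\n")
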