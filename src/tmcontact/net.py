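"""The contact-prediction network.

Architecture: receptor, ligand, and complex pair tensors each pass
through a stack of ResNet-Inception blocks; the complex tensor is then
refined by geometric triangle-aware blocks (one triangle multiplicative
update, row and column triangle self-attention, and a transition layer
per block), using the receptor/ligand tensors as the monomer context.
A linear head with a logistic squashing produces the L x L inter-chain
contact probability map, symmetrized by transpose-averaging.

The triangle self-attention is distance-gated: attention weights are
multiplied by g(d) = exp(-d^2 / (2 lambda^2)) with lambda = 8 A, where d
is the intra-monomer distance between the attended residue and the
appropriate query residue, so that residue triples inconsistent with
the monomer geometry contribute little.  Buried (non-surface) residues
are excluded as attention keys and from the triangle-update sums.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import Conv2d, InstanceNorm2d, LayerNorm, Linear, Module

__all__ = [
    "ModelConfig", "ContactPrediction",
    "ResNetInceptionBlock", "TriangleUpdate", "TriangleAttention", "Transition",
    "TriangleBlock", "ContactNet", "distance_gate",
    "focal_loss", "save_checkpoint", "load_checkpoint",
]

GATE_LAMBDA = 8.0   # A; width of the geometric attention gate
FOCAL_EPS = 1e-7


@dataclasses.dataclass
class ModelConfig:
    n_res_blocks: int = 4       # ResNet-Inception blocks per tower
    n_tri_blocks: int = 4       # triangle-aware blocks
    d: int = 64                 # pair-representation width
    heads: int = 4              # attention heads (must divide d)
    dropout: float = 0.1
    gamma: float = 2.0          # focal-loss focusing exponent
    alpha: float = 0.25         # focal-loss scale
    mask_mode: str = "surface"  # 'surface' (buried residues excluded) or 'none'
    symmetrize: bool = True
    in_channels_monomer: int = 282
    in_channels_complex: int = 218

    def __post_init__(self):
        if self.n_res_blocks < 1 or self.n_tri_blocks < 1 or self.d < 1:
            raise ValueError("all block counts and d must be >= 1")
        if self.d % self.heads != 0:
            raise ValueError(f"heads ({self.heads}) must divide d ({self.d})")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.mask_mode not in ("surface", "none"):
            raise ValueError("mask_mode must be 'surface' or 'none'")


@dataclasses.dataclass
class ContactPrediction:
    probabilities: np.ndarray       # (L, L) in [0, 1]
    crop_offset: int = 0            # window start in the full sequence
    symmetrized: bool = True


def distance_gate(dmap_values: np.ndarray, lam: float = GATE_LAMBDA) -> np.ndarray:
    """g(d) = exp(-d^2 / (2 lambda^2)); infinite distances gate to 0."""
    d = np.asarray(dmap_values, dtype=np.float32)
    out = np.zeros_like(d)
    finite = np.isfinite(d)
    out[finite] = np.exp(-(d[finite] ** 2) / (2.0 * lam ** 2))
    return out


class ResNetInceptionBlock(Module):
    """Residual block with parallel 1x1 / 3x3 / 5x5-equivalent branches.

    Channel split d/4 + d/2 + d/4, each branch conv -> instance norm ->
    ELU, concatenated, fused by a 1x1 convolution, instance-normalised,
    and added to the input.
    """

    def __init__(self, d: int, rng: np.random.Generator):
        q = d // 4
        # biases omitted on convolutions feeding an instance norm (redundant)
        self.b1 = Conv2d(d, q, 1, rng, bias=False)
        self.n1 = InstanceNorm2d(q)
        self.b3 = Conv2d(d, d - 2 * q, 3, rng, bias=False)
        self.n3 = InstanceNorm2d(d - 2 * q)
        self.b5a = Conv2d(d, q, 3, rng, bias=False)
        self.n5a = InstanceNorm2d(q)
        self.b5b = Conv2d(q, q, 3, rng, bias=False)
        self.n5b = InstanceNorm2d(q)
        self.fuse = Conv2d(d, d, 1, rng, scale=0.5, bias=False)
        self.nf = InstanceNorm2d(d)

    def __call__(self, x: Tensor) -> Tensor:
        y1 = ad.elu(self.n1(self.b1(x)))
        y3 = ad.elu(self.n3(self.b3(x)))
        y5 = ad.elu(self.n5b(self.b5b(ad.elu(self.n5a(self.b5a(x))))))
        y = ad.concat([y1, y3, y5], axis=-1)
        return ad.add(x, self.nf(self.fuse(y)))


class _Gate(Module):
    """Bounded elementwise gate: sigmoid(linear(x))."""

    def __init__(self, d: int, rng):
        self.lin = Linear(d, d, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.sigmoid(self.lin(x))


class _NormLinear(Module):
    """Layer norm followed by a linear map (the phi output transform)."""

    def __init__(self, d_in: int, d_out: int, rng, scale: float = 0.5):
        self.norm = LayerNorm(d_in)
        self.lin = Linear(d_in, d_out, rng, scale=scale)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin(self.norm(x))


class TriangleUpdate(Module):
    """Inter-molecular triangle multiplicative update.

    z~_ij = z_ij + phi_out( sum_m r'_im * z'_mj + sum_n z''_in * l'_nj )
            (.) gate(z_ij)

    where primed tensors are gated linear projections of their sources
    and the products are elementwise over the channel dimension.  Buried
    residues of the summed-over monomer are excluded from the sums when
    masks are given.
    """

    def __init__(self, d: int, rng):
        self.gate_z1 = _Gate(d, rng)
        self.lin_z1 = Linear(d, d, rng)
        self.gate_z2 = _Gate(d, rng)
        self.lin_z2 = Linear(d, d, rng)
        self.gate_r = _Gate(d, rng)
        self.lin_r = Linear(d, d, rng)
        self.gate_l = _Gate(d, rng)
        self.lin_l = Linear(d, d, rng)
        self.gate_out = _Gate(d, rng)
        self.out = _NormLinear(d, d, rng)

    def __call__(self, z: Tensor, r: Tensor, l: Tensor,
                 mask_rec: np.ndarray | None = None,
                 mask_lig: np.ndarray | None = None) -> Tensor:
        zp = self.lin_z1(self.gate_z1(z))
        zpp = self.lin_z2(self.gate_z2(z))
        rp = self.lin_r(self.gate_r(r))
        lp = self.lin_l(self.gate_l(l))
        if mask_rec is not None:
            m = mask_rec.astype(zp.data.dtype)
            rp = ad.mul(rp, m[None, :, None])
            zp = ad.mul(zp, m[:, None, None])
        if mask_lig is not None:
            m = mask_lig.astype(zp.data.dtype)
            lp = ad.mul(lp, m[:, None, None])
            zpp = ad.mul(zpp, m[None, :, None])
        s = ad.add(ad.einsum("imd,mjd->ijd", rp, zp),
                   ad.einsum("ind,njd->ijd", zpp, lp))
        return ad.add(z, ad.mul(self.out(s), self.gate_out(z)))


class TriangleAttention(Module):
    """Distance-gated multi-head triangle self-attention (row or column).

    Row mode: for query (i, j) attend over ligand residues m with keys
    k_im; the gate uses the ligand intra-chain distance d(j, m).  Column
    mode transposes the roles (keys k_mj, receptor distances d(i, m)).
    The post-softmax weights are multiplied by g(d); buried residues are
    excluded as keys before the softmax.
    """

    def __init__(self, d: int, heads: int, axis: str, rng):
        if axis not in ("row", "column"):
            raise ValueError("axis must be 'row' or 'column'")
        if d % heads != 0:
            raise ValueError("heads must divide d")
        self.axis = axis
        self.heads = heads
        self.d = d
        self.norm_in = LayerNorm(d)
        self.q = Linear(d, d, rng)
        self.k = Linear(d, d, rng)
        self.v = Linear(d, d, rng)
        self.gate = _Gate(d, rng)
        self.out = _NormLinear(d, d, rng)

    def attention_weights(self, z: Tensor, gate_d: np.ndarray,
                          key_mask: np.ndarray | None):
        """Returns (softmax weights tensor, gated weights tensor)."""
        L1, L2, d = z.shape
        h, dh = self.heads, self.d // self.heads
        zn = self.norm_in(z)
        q = ad.reshape(self.q(zn), (L1, L2, h, dh))
        k = ad.reshape(self.k(zn), (L1, L2, h, dh))
        if self.axis == "row":
            logits = ad.einsum("ijhe,imhe->ijmh", q, k)       # m over ligand (L2)
            mask = None if key_mask is None else key_mask[None, None, :, None]
            gate = gate_d[None, :, :, None]                   # gate_d[j, m]
        else:
            logits = ad.einsum("ijhe,mjhe->ijmh", q, k)       # m over receptor (L1)
            mask = None if key_mask is None else key_mask[None, None, :, None]
            gate = gate_d[:, None, :, None]                   # gate_d[i, m]
        logits = ad.mul(logits, float(1.0 / np.sqrt(dh)))
        w_soft = ad.softmax(logits, axis=2, mask=mask)
        w = ad.mul(w_soft, gate)
        return w_soft, w

    def __call__(self, z: Tensor, dmap_values: np.ndarray,
                 key_mask: np.ndarray | None = None) -> Tensor:
        L1, L2, d = z.shape
        h, dh = self.heads, self.d // self.heads
        zn = self.norm_in(z)
        v = ad.reshape(self.v(zn), (L1, L2, h, dh))
        gate_d = distance_gate(dmap_values)
        _, w = self.attention_weights(z, gate_d, key_mask)
        if self.axis == "row":
            o = ad.einsum("ijmh,imhe->ijhe", w, v)
        else:
            o = ad.einsum("ijmh,mjhe->ijhe", w, v)
        o = ad.reshape(o, (L1, L2, d))
        return ad.add(z, self.out(ad.mul(o, self.gate(z))))


class Transition(Module):
    """Position-wise two-layer feed-forward with residual add."""

    def __init__(self, d: int, rng, expand: int = 2):
        self.norm = LayerNorm(d)
        self.lin1 = Linear(d, expand * d, rng)
        self.lin2 = Linear(expand * d, d, rng, scale=0.5)

    def __call__(self, z: Tensor) -> Tensor:
        return ad.add(z, self.lin2(ad.elu(self.lin1(self.norm(z)))))


class TriangleBlock(Module):
    """One triangle update, two triangle self-attentions, one transition."""

    def __init__(self, d: int, heads: int, rng):
        self.update = TriangleUpdate(d, rng)
        self.attn_row = TriangleAttention(d, heads, "row", rng)
        self.attn_col = TriangleAttention(d, heads, "column", rng)
        self.transition = Transition(d, rng)

    def __call__(self, z, r, l, dmap_rec, dmap_lig, mask_rec, mask_lig):
        z = self.update(z, r, l, mask_rec=mask_rec, mask_lig=mask_lig)
        z = self.attn_row(z, dmap_lig, key_mask=mask_lig)
        z = self.attn_col(z, dmap_rec, key_mask=mask_rec)
        return self.transition(z)


class ContactNet(Module):
    """Full network: monomer/complex towers + triangle blocks + head."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        d = cfg.d
        self.proj_mono = Conv2d(cfg.in_channels_monomer, d, 1, rng)
        self.proj_cplx = Conv2d(cfg.in_channels_complex, d, 1, rng)
        self.mono_blocks = [ResNetInceptionBlock(d, rng) for _ in range(cfg.n_res_blocks)]
        self.cplx_blocks = [ResNetInceptionBlock(d, rng) for _ in range(cfg.n_res_blocks)]
        self.tri_blocks = [TriangleBlock(d, cfg.heads, rng) for _ in range(cfg.n_tri_blocks)]
        self.head = Linear(d, 1, rng)

    def _tower(self, x: Tensor, blocks, train: bool, rng):
        for blk in blocks:
            x = blk(x)
            if train and self.cfg.dropout > 0:
                x = ad.dropout_mask(x, self.cfg.dropout, rng)
        return x

    def forward_tensor(self, receptor: np.ndarray, complex_: np.ndarray,
                       dmap_values: np.ndarray, surface: np.ndarray | None,
                       train: bool = False, rng: np.random.Generator | None = None) -> Tensor:
        """Symmetrized contact-probability map as an autodiff tensor."""
        if train and rng is None:
            rng = np.random.default_rng(0)
        mask = None
        if self.cfg.mask_mode == "surface" and surface is not None:
            mask = np.asarray(surface, dtype=bool)
        dtype = self.proj_mono.weight.data.dtype
        receptor = np.asarray(receptor, dtype=dtype)
        complex_ = np.asarray(complex_, dtype=dtype)
        r = self._tower(self.proj_mono(Tensor(receptor)), self.mono_blocks, train, rng)
        z = self._tower(self.proj_cplx(Tensor(complex_)), self.cplx_blocks, train, rng)
        l = r  # identical chains: ligand tensor == receptor tensor
        for blk in self.tri_blocks:
            z = blk(z, r, l, dmap_values, dmap_values, mask, mask)
            if train and self.cfg.dropout > 0:
                z = ad.dropout_mask(z, self.cfg.dropout, rng)
        logits = ad.reshape(self.head(z), z.shape[:2])
        p = ad.sigmoid(logits)
        if self.cfg.symmetrize:
            p = ad.mul(ad.add(p, ad.transpose2d(p)), 0.5)
        return p

    def predict(self, receptor, complex_, dmap_values, surface,
                crop_offset: int = 0) -> ContactPrediction:
        with ad.no_grad():
            p = self.forward_tensor(receptor, complex_, dmap_values, surface, train=False)
        return ContactPrediction(probabilities=p.data.copy(), crop_offset=crop_offset,
                                 symmetrized=self.cfg.symmetrize)


def focal_loss(pred: Tensor, truth: np.ndarray, gamma: float = 2.0,
               alpha: float = 0.25) -> Tensor:
    """Mean focal loss: -alpha * (1 - p_t)^gamma * log(p_t).

    `pred` holds probabilities in [0, 1]; `truth` is the boolean contact
    map.  Probabilities are clamped to [eps, 1 - eps], eps = 1e-7.  With
    gamma = 0, alpha = 1 this is exactly mean binary cross-entropy.
    """
    y = np.asarray(truth, dtype=float)
    if y.shape != tuple(pred.shape):
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {y.shape}")
    p = ad.clip(pred, FOCAL_EPS, 1.0 - FOCAL_EPS)
    pt = ad.add(ad.mul(p, y), ad.mul(ad.sub(1.0, p), 1.0 - y))
    term = ad.mul(ad.pow_const(ad.sub(1.0, pt), gamma), ad.log(pt))
    return ad.mul(ad.reduce_mean(term), -alpha)


# ----------------------------------------------------------------------
# checkpoints

def save_checkpoint(path, model: ContactNet):
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(dataclasses.asdict(model.cfg))
        grp = f.create_group("params")
        for name, p in model.named_parameters():
            grp.create_dataset(name, data=p.data)


def load_checkpoint(path) -> ContactNet:
    with h5py.File(path, "r") as f:
        cfg = ModelConfig(**json.loads(f.attrs["config"]))
        state = {k: np.asarray(v) for k, v in f["params"].items()}
    model = ContactNet(cfg)
    model.load_state_dict(state)
    return model
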