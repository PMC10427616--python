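"""Training: cropping, single-stage optimisation, and the transfer protocol.

The transfer protocol mirrors the two-stage recipe for scarce membrane
complexes: train an initial model (IT) on the abundant soluble-like
split, then fine-tune every parameter (no frozen layers) on the
TMP-like split.  A direct-training (DT) baseline trains the same
architecture from scratch on the TMP-like split alone.
"""

from __future__ import annotations

import copy
import dataclasses
import json

import numpy as np

from .net import ContactNet, ModelConfig, focal_loss
from .nn.optim import Adam

__all__ = [
    "TrainConfig", "TrainingTarget", "crop_to_window",
    "train_stage", "transfer_finetune", "run_protocol", "ProtocolResult",
]


@dataclasses.dataclass
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 20
    finetune_epochs: int = 20
    crop_window: int = 256
    dropout: float = 0.1
    patience: int = 5          # early stop on validation focal loss
    grad_clip: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.crop_window < 1:
            raise ValueError("crop window must be >= 1")
        if self.lr < 0:
            raise ValueError("learning rate must be >= 0")


@dataclasses.dataclass
class TrainingTarget:
    name: str
    bundle: object            # FeatureBundle
    dmap: object              # DistanceMap
    surface: object           # SurfaceAnnotation
    truth: np.ndarray         # (L, L) bool union inter-chain contact map
    L: int
    structure: object = None  # optional ComplexStructure provenance
    crop_offset: int = 0


def crop_to_window(t: TrainingTarget, window: int = 256, seed: int = 0) -> TrainingTarget:
    """Crop to the diagonal window with the most inter-chain contacts.

    All windows (stride 1) are scanned; those attaining the maximum
    contact count in the window x window diagonal block are collected
    and one is chosen uniformly at random with `seed`.  All tensors are
    sliced consistently.  Targets at or under the window are returned
    unchanged.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if t.L <= window:
        return t
    truth = t.truth.astype(np.int64)
    # contact count in [s, s+window)^2 for every start, via 2-D summed-area table
    sat = np.zeros((t.L + 1, t.L + 1), dtype=np.int64)
    sat[1:, 1:] = truth.cumsum(0).cumsum(1)
    n_starts = t.L - window + 1
    counts = np.empty(n_starts, dtype=np.int64)
    for s in range(n_starts):
        e = s + window
        counts[s] = sat[e, e] - sat[s, e] - sat[e, s] + sat[s, s]
    best = np.flatnonzero(counts == counts.max())
    rng = np.random.default_rng(seed)
    s = int(best[rng.integers(0, len(best))])
    sl = slice(s, s + window)
    bundle = copy.copy(t.bundle)
    bundle.receptor = t.bundle.receptor[sl, sl]
    bundle.complex = t.bundle.complex[sl, sl]
    dmap = copy.copy(t.dmap)
    dmap.values = t.dmap.values[sl, sl]
    dmap.missing = t.dmap.missing[sl]
    surf = copy.copy(t.surface)
    surf.sasa = t.surface.sasa[sl]
    surf.rel_sasa = t.surface.rel_sasa[sl]
    surf.surface = t.surface.surface[sl]
    return TrainingTarget(name=t.name, bundle=bundle, dmap=dmap, surface=surf,
                          truth=t.truth[sl, sl], L=window, structure=t.structure,
                          crop_offset=s)


def _target_loss(model: ContactNet, t: TrainingTarget, train: bool,
                 rng: np.random.Generator | None = None):
    pred = model.forward_tensor(t.bundle.receptor, t.bundle.complex,
                                t.dmap.values, t.surface.surface,
                                train=train, rng=rng)
    return pred, focal_loss(pred, t.truth, gamma=model.cfg.gamma, alpha=model.cfg.alpha)


def evaluate_loss(model: ContactNet, data) -> float:
    from .nn import autodiff as ad
    with ad.no_grad():
        losses = [_target_loss(model, t, train=False)[1].data.item() for t in data]
    return float(np.mean(losses))


def train_stage(model: ContactNet, data, cfg: TrainConfig,
                valid=None, epochs: int | None = None, log=None) -> ContactNet:
    """Per-target (batch 1) focal-loss optimisation with Adam.

    Keeps the best-validation parameters; stops early when validation
    loss has not improved for `cfg.patience` epochs.  Deterministic for
    a fixed seed.  Raises on a non-finite loss.
    """
    if not data:
        raise ValueError("empty training data")
    epochs = cfg.epochs if epochs is None else epochs
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    best_state, best_val, since_best = None, np.inf, 0
    for epoch in range(epochs):
        order = rng.permutation(len(data))
        ep_loss = 0.0
        for idx in order:
            t = data[idx]
            if t.L > cfg.crop_window:
                t = crop_to_window(t, cfg.crop_window, seed=int(rng.integers(0, 2 ** 31 - 1)))
            opt.zero_grad()
            _, loss = _target_loss(model, t, train=True, rng=rng)
            lv = loss.data.item()
            if not np.isfinite(lv):
                raise FloatingPointError(
                    f"non-finite loss on target {t.name} at epoch {epoch}")
            loss.backward()
            if cfg.grad_clip is not None:
                total = np.sqrt(sum((p.grad ** 2).sum() for p in model.parameters()
                                    if p.grad is not None))
                if total > cfg.grad_clip:
                    for p in model.parameters():
                        if p.grad is not None:
                            p.grad *= cfg.grad_clip / total
            opt.step()
            ep_loss += lv
        record = {"epoch": epoch, "train_loss": ep_loss / len(data)}
        if valid:
            vl = evaluate_loss(model, valid)
            record["valid_loss"] = vl
            if vl < best_val - 1e-9:
                best_val, best_state, since_best = vl, model.state_dict(), 0
            else:
                since_best += 1
        if log is not None:
            log.write(json.dumps(record) + "\n")
        if valid and since_best >= cfg.patience:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    return model


def transfer_finetune(pretrained: ContactNet, tmp_data, cfg: TrainConfig,
                      valid=None, log=None) -> ContactNet:
    """Fine-tune a copy of the pretrained model with no frozen layers.

    The pretrained model object is never mutated; all parameters of the
    copy remain trainable (frozen-parameter count is zero by
    construction, assertable via :func:`frozen_parameter_count`).
    """
    model = ContactNet(pretrained.cfg)
    model.load_state_dict(pretrained.state_dict())
    assert frozen_parameter_count(model) == 0
    if cfg.finetune_epochs == 0:
        return model
    return train_stage(model, tmp_data, cfg, valid=valid,
                       epochs=cfg.finetune_epochs, log=log)


def frozen_parameter_count(model: ContactNet) -> int:
    return sum(1 for p in model.parameters() if not p.requires_grad)


def toy_model_config(sample: TrainingTarget, dropout: float = 0.1) -> ModelConfig:
    """Desk-scale model: full architecture, narrow width.

    Keeps the four ResNet-Inception blocks and the complete
    triangle-aware block structure but runs at d = 8 with 2 heads and a
    single triangle block, the width at which the whole transfer
    protocol is practical on one CPU.
    """
    return ModelConfig(d=8, heads=2, n_tri_blocks=1, dropout=dropout,
                       in_channels_monomer=sample.bundle.receptor.shape[2],
                       in_channels_complex=sample.bundle.complex.shape[2])


@dataclasses.dataclass
class ProtocolResult:
    it_model: ContactNet
    dt_model: ContactNet
    transfer_model: ContactNet
    report: object            # pandas DataFrame of per-model test precisions


def run_protocol(benchmark, cfg: TrainConfig,
                 model_cfg: ModelConfig | None = None, log=None) -> ProtocolResult:
    """IT on soluble-like, DT from scratch on TMP-like, transfer = IT fine-tuned.

    All three models are evaluated on the TMP-like test split; the
    report lists per-target top-k precisions for each model.
    """
    from .evaluation import topk_precision  # local import to avoid cycle
    import pandas as pd

    for split_name in ("soluble_train", "tmp_train", "tmp_test"):
        if not getattr(benchmark, split_name):
            raise ValueError(f"empty split: {split_name}")
    if model_cfg is None:
        model_cfg = toy_model_config(benchmark.soluble_train[0], dropout=cfg.dropout)

    it = ContactNet(model_cfg, seed=cfg.seed)
    it = train_stage(it, benchmark.soluble_train, cfg,
                     valid=benchmark.soluble_valid, log=log)
    dt = ContactNet(model_cfg, seed=cfg.seed + 1)
    dt = train_stage(dt, benchmark.tmp_train, cfg,
                     valid=benchmark.tmp_valid,
                     epochs=cfg.finetune_epochs, log=log)
    tr = transfer_finetune(it, benchmark.tmp_train, cfg,
                           valid=benchmark.tmp_valid, log=log)

    rows = []
    for name, model in (("IT_Model", it), ("DT_Model", dt), ("Transfer", tr)):
        for t in benchmark.tmp_test:
            pred = model.predict(t.bundle.receptor, t.bundle.complex,
                                 t.dmap.values, t.surface.surface)
            rep = topk_precision(pred, t.truth, t.L)
            row = {"model": name, "target": t.name}
            row.update(rep.precisions)
            rows.append(row)
    report = pd.DataFrame(rows)
    return ProtocolResult(it_model=it, dt_model=dt, transfer_model=tr, report=report)
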