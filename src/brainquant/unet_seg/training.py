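"""Training loop (Adam, convergence-based early stopping), inference helpers
and checkpoint I/O for the desk-scale U-Net pair."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ..imaging_core import LabelMap3D, LabelScheme
from ._net import ModelConfig, UNet3D
from .losses import LossBreakdown, combined_loss

__all__ = ["TrainingConfig", "train_model", "predict_labels",
           "tissue_onehot", "save_model", "load_model"]


@dataclass(frozen=True)
class TrainingConfig:
    dice_weight: float = 1.0
    cce_weight: float = 1.0
    class_weights: tuple[float, ...] | None = None
    learning_rate: float = 1e-3
    max_epochs: int = 100
    #: epochs without validation-loss improvement before stopping
    patience: int = 10
    val_subjects: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dice_weight < 0 or self.cce_weight < 0:
            raise ValueError("loss weights must be non-negative")
        if self.dice_weight == 0 and self.cce_weight == 0:
            raise ValueError("at least one loss weight must be positive")
        if self.val_subjects < 1:
            raise ValueError("need at least one validation subject")


def _pad_to_multiple(x: np.ndarray, multiple: int) -> tuple[np.ndarray, tuple]:
    spatial = x.shape[1:]
    pads = [(0, 0)]
    for s in spatial:
        extra = (-s) % multiple
        pads.append((0, extra))
    return np.pad(x, pads), tuple(spatial)


def _one_hot(labels: np.ndarray, classes: int) -> np.ndarray:
    if labels.min() < 0 or labels.max() >= classes:
        raise ValueError("label values outside class range")
    return np.eye(classes)[labels.astype(int)].transpose(3, 0, 1, 2)


def tissue_onehot(labels: np.ndarray, tissue_ids: Sequence[Sequence[int]]) -> np.ndarray:
    """One-hot tissue channels for the lesion model input.

    ``tissue_ids`` lists, per output channel after the implicit background
    channel, the label ids belonging to that channel (e.g. CSF, GM, WM ids).
    Returns ``(1 + len(tissue_ids), D, H, W)``.
    """
    channels = [np.ones(labels.shape, dtype=np.float64)]
    for ids in tissue_ids:
        ch = np.isin(labels, list(ids)).astype(np.float64)
        channels.append(ch)
        channels[0] -= ch
    channels[0] = np.clip(channels[0], 0.0, 1.0)
    return np.stack(channels)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mh = self.m[k] / b1t
            vh = self.v[k] / b2t
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _evaluate(net: UNet3D, subjects: list[tuple[np.ndarray, np.ndarray]],
              cfg: TrainingConfig) -> LossBreakdown:
    dices, cces = [], []
    for inputs, onehot in subjects:
        logits, _ = net.forward(inputs)
        bd, _ = combined_loss(logits, onehot,
                              class_weights=cfg.class_weights,
                              dice_weight=cfg.dice_weight,
                              cce_weight=cfg.cce_weight, with_grad=False)
        dices.append(bd.soft_dice)
        cces.append(bd.weighted_cce)
    dice, cce = float(np.mean(dices)), float(np.mean(cces))
    return LossBreakdown(dice, cce, cfg.dice_weight * dice + cfg.cce_weight * cce)


def train_model(subjects: Sequence[tuple[np.ndarray, np.ndarray]],
                model_cfg: ModelConfig,
                train_cfg: TrainingConfig) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Train on ``subjects`` (list of ``(inputs (C,D,H,W), labels (D,H,W))``).

    After a seeded shuffle the last ``val_subjects`` subjects are held out for
    validation.  Training stops when the validation total loss has not
    improved for more than ``patience`` epochs, or at ``max_epochs``.
    Returns the trained parameters and a per-epoch history of
    ``{"train": LossBreakdown, "val": LossBreakdown}``.
    """
    if len(subjects) < train_cfg.val_subjects + 1:
        raise ValueError(
            f"need at least {train_cfg.val_subjects + 1} subjects, "
            f"got {len(subjects)}")
    rng = np.random.default_rng(train_cfg.seed)
    order = rng.permutation(len(subjects))
    shuffled = [subjects[i] for i in order]
    val_raw = shuffled[len(shuffled) - train_cfg.val_subjects:]
    train_raw = shuffled[:len(shuffled) - train_cfg.val_subjects]

    multiple = 2 ** model_cfg.levels

    def prep(pair: tuple[np.ndarray, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        inputs, labels = pair
        inputs = np.asarray(inputs, dtype=np.float64)
        if inputs.ndim == 3:
            inputs = inputs[None]
        padded, _ = _pad_to_multiple(inputs, multiple)
        lab_padded, _ = _pad_to_multiple(np.asarray(labels)[None], multiple)
        onehot = _one_hot(lab_padded[0], model_cfg.classes)
        return padded, onehot

    train_set = [prep(p) for p in train_raw]
    val_set = [prep(p) for p in val_raw]

    net = UNet3D(model_cfg, seed=train_cfg.seed)
    opt = _Adam(net.params, train_cfg.learning_rate)
    history: list[dict] = []
    best_val = np.inf
    since_best = 0
    for _epoch in range(train_cfg.max_epochs):
        epoch_order = rng.permutation(len(train_set))
        dices, cces = [], []
        for i in epoch_order:
            inputs, onehot = train_set[i]
            logits, cache = net.forward(inputs)
            bd, dlogits = combined_loss(
                logits, onehot, class_weights=train_cfg.class_weights,
                dice_weight=train_cfg.dice_weight,
                cce_weight=train_cfg.cce_weight)
            grads = net.backward(cache, dlogits)
            opt.step(net.params, grads)
            dices.append(bd.soft_dice)
            cces.append(bd.weighted_cce)
        dice, cce = float(np.mean(dices)), float(np.mean(cces))
        train_bd = LossBreakdown(
            dice, cce, train_cfg.dice_weight * dice + train_cfg.cce_weight * cce)
        val_bd = _evaluate(net, val_set, train_cfg)
        history.append({"train": train_bd, "val": val_bd})
        if val_bd.total < best_val:
            best_val = val_bd.total
            since_best = 0
        else:
            since_best += 1
            if since_best > train_cfg.patience:
                break
    return net.params, history


def predict_labels(params: dict[str, np.ndarray], inputs: np.ndarray,
                   model_cfg: ModelConfig,
                   affine: np.ndarray | None = None,
                   scheme: LabelScheme | None = None) -> np.ndarray | LabelMap3D:
    """Per-voxel argmax prediction.  Input grids are zero-padded up to the
    next multiple of ``2**levels`` and the output cropped back; argmax ties
    break to the lowest class id.  With ``affine`` and ``scheme`` supplied
    the result is wrapped as a :class:`LabelMap3D`."""
    inputs = np.asarray(inputs, dtype=np.float64)
    if inputs.ndim == 3:
        inputs = inputs[None]
    if inputs.shape[0] != model_cfg.in_channels:
        raise ValueError(
            f"model expects {model_cfg.in_channels} input channels, "
            f"got {inputs.shape[0]}")
    padded, orig = _pad_to_multiple(inputs, 2 ** model_cfg.levels)
    net = UNet3D(model_cfg, params=params)
    logits, _ = net.forward(padded)
    labels = np.argmax(logits, axis=0).astype(np.int16)
    labels = labels[:orig[0], :orig[1], :orig[2]]
    if affine is not None and scheme is not None:
        return LabelMap3D(labels=labels, affine=affine, scheme=scheme)
    return labels


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(params: dict[str, np.ndarray], model_cfg: ModelConfig,
               out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "weights.npz", **params)
    (out / "model.json").write_text(json.dumps(model_cfg.to_dict(), indent=2))
    return out


def load_model(model_dir: str | Path) -> tuple[dict[str, np.ndarray], ModelConfig]:
    model_dir = Path(model_dir)
    cfg = ModelConfig.from_dict(json.loads((model_dir / "model.json").read_text()))
    with np.load(model_dir / "weights.npz") as npz:
        params = {k: npz[k].copy() for k in npz.files}
    return params, cfg
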