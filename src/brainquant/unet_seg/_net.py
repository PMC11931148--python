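"""Minimal 3D U-Net in plain NumPy with hand-written backpropagation.

Deliberately desk-scale: full-volume forward passes, 3x3x3 convolutions
implemented as 27 shifted tensor contractions, 2x max pooling, nearest
neighbour upsampling and channel-concatenated skips.  Everything is
deterministic given the initialisation seed; there is no threading beyond
what BLAS does inside a single call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ModelConfig", "UNet3D"]


@dataclass(frozen=True)
class ModelConfig:
    classes: int
    in_channels: int = 1
    levels: int = 2
    base_channels: int = 8
    patch_size: int = 32

    def __post_init__(self) -> None:
        if self.classes < 2:
            raise ValueError("need at least 2 classes")
        if self.patch_size % (2 ** self.levels) != 0:
            raise ValueError(
                f"patch size {self.patch_size} not divisible by 2^{self.levels}")

    def channels_at(self, level: int) -> int:
        return self.base_channels * (2 ** level)

    def to_dict(self) -> dict:
        return {"classes": self.classes, "in_channels": self.in_channels,
                "levels": self.levels, "base_channels": self.base_channels,
                "patch_size": self.patch_size}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# primitive ops (forward + backward pairs)
# ---------------------------------------------------------------------------

def conv3d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """'Same' 3x3x3 convolution. x: (Cin,D,H,W), w: (Cout,Cin,3,3,3)."""
    d, h, wd = x.shape[1:]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    y = np.broadcast_to(b[:, None, None, None], (w.shape[0], d, h, wd)).copy()
    for dz in range(3):
        for dy in range(3):
            for dx in range(3):
                patch = xp[:, dz:dz + d, dy:dy + h, dx:dx + wd]
                y += np.tensordot(w[:, :, dz, dy, dx], patch, axes=(1, 0))
    return y


def conv3d_backward(gy: np.ndarray, x: np.ndarray,
                    w: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d, h, wd = x.shape[1:]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    gxp = np.zeros_like(xp)
    gw = np.zeros_like(w)
    for dz in range(3):
        for dy in range(3):
            for dx in range(3):
                patch = xp[:, dz:dz + d, dy:dy + h, dx:dx + wd]
                gw[:, :, dz, dy, dx] = np.tensordot(gy, patch,
                                                    axes=([1, 2, 3], [1, 2, 3]))
                gxp[:, dz:dz + d, dy:dy + h, dx:dx + wd] += np.tensordot(
                    w[:, :, dz, dy, dx].T, gy, axes=(1, 0))
    gb = gy.sum(axis=(1, 2, 3))
    return gxp[:, 1:-1, 1:-1, 1:-1], gw, gb


def maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c, d, h, w = x.shape
    blocks = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
    y = blocks.max(axis=(2, 4, 6))
    mask = blocks == y[:, :, None, :, None, :, None]
    return y, mask


def maxpool2_backward(gy: np.ndarray, mask: np.ndarray,
                      shape: tuple[int, ...]) -> np.ndarray:
    g = mask * gy[:, :, None, :, None, :, None]
    return g.reshape(shape)


def upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(gy: np.ndarray) -> np.ndarray:
    c, d, h, w = gy.shape
    return gy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class UNet3D:
    """Encoder-decoder with ``levels`` poolings and a two-conv block at each
    resolution; the head is a 1x1x1 convolution to class logits."""

    def __init__(self, config: ModelConfig, seed: int = 0,
                 params: dict[str, np.ndarray] | None = None) -> None:
        self.config = config
        self.params = params if params is not None else self._init_params(seed)

    # -- parameters ------------------------------------------------------
    def _init_params(self, seed: int) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(seed)
        cfg = self.config
        params: dict[str, np.ndarray] = {}

        def conv_pair(prefix: str, cin: int, cout: int) -> None:
            for i, (ci, co) in enumerate([(cin, cout), (cout, cout)], start=1):
                # He initialisation: std = sqrt(2 / fan_in)
                std = np.sqrt(2.0 / (ci * 27))
                params[f"{prefix}_conv{i}_w"] = rng.normal(
                    0.0, std, size=(co, ci, 3, 3, 3))
                params[f"{prefix}_conv{i}_b"] = np.zeros(co)

        prev = cfg.in_channels
        for lvl in range(cfg.levels):
            conv_pair(f"enc{lvl}", prev, cfg.channels_at(lvl))
            prev = cfg.channels_at(lvl)
        conv_pair("bott", prev, cfg.channels_at(cfg.levels))
        for lvl in reversed(range(cfg.levels)):
            conv_pair(f"dec{lvl}",
                      cfg.channels_at(lvl + 1) + cfg.channels_at(lvl),
                      cfg.channels_at(lvl))
        std = np.sqrt(2.0 / cfg.channels_at(0))
        params["out_w"] = rng.normal(0.0, std, size=(cfg.classes, cfg.channels_at(0)))
        params["out_b"] = np.zeros(cfg.classes)
        return params

    # -- forward ---------------------------------------------------------
    def _block_forward(self, prefix: str, x: np.ndarray,
                       cache: dict) -> np.ndarray:
        p = self.params
        for i in (1, 2):
            z = conv3d(x, p[f"{prefix}_conv{i}_w"], p[f"{prefix}_conv{i}_b"])
            cache[f"{prefix}_x{i}"] = x
            cache[f"{prefix}_z{i}"] = z
            x = np.maximum(z, 0.0)
        return x

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        cfg = self.config
        if x.ndim != 4 or x.shape[0] != cfg.in_channels:
            raise ValueError(
                f"expected input of shape ({cfg.in_channels}, D, H, W), got {x.shape}")
        for s in x.shape[1:]:
            if s % (2 ** cfg.levels) != 0:
                raise ValueError(
                    f"spatial size {x.shape[1:]} not divisible by 2^{cfg.levels}")
        cache: dict = {}
        skips = []
        h = np.asarray(x, dtype=np.float64)
        for lvl in range(cfg.levels):
            h = self._block_forward(f"enc{lvl}", h, cache)
            skips.append(h)
            cache[f"pool{lvl}_shape"] = h.shape
            h, mask = maxpool2(h)
            cache[f"pool{lvl}_mask"] = mask
        h = self._block_forward("bott", h, cache)
        for lvl in reversed(range(cfg.levels)):
            up = upsample2(h)
            cache[f"dec{lvl}_split"] = up.shape[0]
            h = np.concatenate([up, skips[lvl]], axis=0)
            h = self._block_forward(f"dec{lvl}", h, cache)
        cache["head_x"] = h
        logits = np.tensordot(self.params["out_w"], h, axes=(1, 0))
        logits += self.params["out_b"][:, None, None, None]
        return logits, cache

    # -- backward --------------------------------------------------------
    def _block_backward(self, prefix: str, g: np.ndarray, cache: dict,
                        grads: dict) -> np.ndarray:
        p = self.params
        for i in (2, 1):
            g = g * (cache[f"{prefix}_z{i}"] > 0.0)
            g, gw, gb = conv3d_backward(g, cache[f"{prefix}_x{i}"],
                                        p[f"{prefix}_conv{i}_w"])
            grads[f"{prefix}_conv{i}_w"] = gw
            grads[f"{prefix}_conv{i}_b"] = gb
        return g

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.config
        grads: dict[str, np.ndarray] = {}
        h = cache["head_x"]
        grads["out_w"] = np.tensordot(dlogits, h, axes=([1, 2, 3], [1, 2, 3]))
        grads["out_b"] = dlogits.sum(axis=(1, 2, 3))
        g = np.tensordot(self.params["out_w"].T, dlogits, axes=(1, 0))
        skip_grads: dict[int, np.ndarray] = {}
        for lvl in range(cfg.levels):
            g = self._block_backward(f"dec{lvl}", g, cache, grads)
            split = cache[f"dec{lvl}_split"]
            skip_grads[lvl] = g[split:]
            g = upsample2_backward(g[:split])
        g = self._block_backward("bott", g, cache, grads)
        for lvl in reversed(range(cfg.levels)):
            g = maxpool2_backward(g, cache[f"pool{lvl}_mask"],
                                  cache[f"pool{lvl}_shape"])
            g = g + skip_grads[lvl]
            g = self._block_backward(f"enc{lvl}", g, cache, grads)
        return grads
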