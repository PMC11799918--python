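"""Residual 3D U-Net with deep supervision.

Four encoder-decoder levels with two residual blocks per level, channel
doubling on descent, additive skip connections, and auxiliary 1x1x1
segmentation heads at the two intermediate decoder resolutions when deep
supervision is enabled.  Inputs are single-channel normalised-HU patches,
outputs are per-class logits at one or three resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Conv3d, Conv1x1, MaxPool2x, ReLU, ResidualBlock, Upsample2x


@dataclass(frozen=True)
class NetConfig:
    n_levels: int = 4
    residual_blocks_per_level: int = 2
    base_channels: int = 8
    deep_supervision: bool = True
    deep_supervision_weights: tuple = (1.0, 0.5, 0.25)
    n_classes: int = 3
    patch_size: tuple = (64, 64, 32)

    def __post_init__(self):
        if self.n_classes != 3:
            raise ValueError("this observer segments exactly 3 classes")
        if self.n_levels < 2:
            raise ValueError("need at least 2 levels")
        div = 2 ** (self.n_levels - 1)
        if any(s % div or s <= 0 for s in self.patch_size):
            raise ValueError(
                f"patch size {self.patch_size} must be positive and divisible by "
                f"2^(n_levels-1) = {div}"
            )
        if self.base_channels < 1 or self.residual_blocks_per_level < 1:
            raise ValueError("base_channels and residual_blocks_per_level must be >= 1")

    @property
    def n_heads(self) -> int:
        return min(3, self.n_levels - 1) if self.deep_supervision else 1

    def head_weights(self) -> np.ndarray:
        w = np.asarray(self.deep_supervision_weights[: self.n_heads], dtype=float)
        return w / w.sum()


class _BlockStack:
    def __init__(self, channels, n_blocks, rng, name):
        self.blocks = [ResidualBlock(channels, rng, f"{name}.b{i}") for i in range(n_blocks)]

    def params(self):
        return [p for b in self.blocks for p in b.params()]

    def forward(self, x):
        for b in self.blocks:
            x = b.forward(x)
        return x

    def backward(self, g):
        for b in reversed(self.blocks):
            g = b.backward(g)
        return g


class ResUNet3D:
    """See module docstring.  ``forward`` returns logits for each head,
    full resolution first; ``backward`` takes matching logit gradients."""

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        L = config.n_levels
        ch = [config.base_channels * 2**i for i in range(L)]
        nb = config.residual_blocks_per_level

        self.stem = Conv3d(1, ch[0], rng, "stem")
        self.enc = [_BlockStack(ch[i], nb, rng, f"enc{i}") for i in range(L)]
        self.pool = [MaxPool2x() for _ in range(L - 1)]
        self.down = [Conv3d(ch[i], ch[i + 1], rng, f"down{i}") for i in range(L - 1)]
        self.down_act = [ReLU() for _ in range(L - 1)]
        self.up = [Upsample2x() for _ in range(L - 1)]
        self.upconv = [Conv3d(ch[i + 1], ch[i], rng, f"up{i}") for i in range(L - 1)]
        self.up_act = [ReLU() for _ in range(L - 1)]
        self.dec = [_BlockStack(ch[i], nb, rng, f"dec{i}") for i in range(L - 1)]
        self.heads = [Conv1x1(ch[i], config.n_classes, rng, f"head{i}", zero_init=True)
                      for i in range(config.n_heads)]

    def params(self):
        out = self.stem.params()
        for m in (*self.enc, *self.down, *self.upconv, *self.dec, *self.heads):
            out += m.params()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        L = self.config.n_levels
        s = [None] * L
        h = self.stem.forward(x)
        s[0] = self.enc[0].forward(h)
        for i in range(L - 1):
            h = self.down_act[i].forward(self.down[i].forward(self.pool[i].forward(s[i])))
            s[i + 1] = self.enc[i + 1].forward(h)
        d = s[L - 1]
        self._dec_out = [None] * (L - 1)
        for i in range(L - 2, -1, -1):
            # channel reduction happens before upsampling (cheaper at coarse
            # resolution, same receptive field)
            u = self.up[i].forward(self.up_act[i].forward(self.upconv[i].forward(d)))
            d = self.dec[i].forward(u + s[i])
            self._dec_out[i] = d
        return [self.heads[i].forward(self._dec_out[i]) for i in range(len(self.heads))]

    def backward(self, g_logits: list[np.ndarray]) -> None:
        L = self.config.n_levels
        g_skip = [None] * L
        g_d = None
        # decoder in reverse (finest level first, mirroring the forward order)
        for i in range(L - 1):
            g = self.heads[i].backward(g_logits[i]) if i < len(self.heads) else None
            if g_d is not None:
                g = g_d if g is None else g + g_d
            g = self.dec[i].backward(g)
            g_skip[i] = g
            g_d = self.upconv[i].backward(self.up_act[i].backward(self.up[i].backward(g)))
        g_s = g_d  # gradient at the bottom encoder output
        for i in range(L - 1, 0, -1):
            g = self.enc[i].backward(g_s)
            g = self.pool[i - 1].backward(self.down[i - 1].backward(self.down_act[i - 1].backward(g)))
            g_s = g + g_skip[i - 1]
        self.stem.backward(self.enc[0].backward(g_s))

    # --- persistence ------------------------------------------------------

    def state_dict(self) -> dict:
        return {p.name: p.value for p in self.params()}

    def load_state_dict(self, state: dict) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
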