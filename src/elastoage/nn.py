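"""3D residual encoder and regression heads built on the autodiff core.

The encoder mirrors the small-ResNet design used for volumetric brain-age
work: a stack of stride-2 stages, each a downsampling convolution followed
by a two-convolution residual block with identity skip, ReLU throughout,
global average pooling and a linear latent head. Channel widths and the
embedding dimension are configurable so the same code runs at desk scale
(e.g. [4, 8, 16, 32], embedding 32) and at the full scale
([16, 32, 64, 128], embedding 256).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Adam, Tensor, conv3d

__all__ = ["EncoderConfig", "Encoder3D", "RegressionHead", "Adam"]


@dataclass
class EncoderConfig:
    input_channels: int = 2
    stage_channels: list = field(default_factory=lambda: [16, 32, 64, 128])
    embedding_dim: int = 256
    dropout: float = 0.0
    head_hidden: int = 64

    def __post_init__(self):
        if self.input_channels < 1 or any(c < 1 for c in self.stage_channels):
            raise ValueError("channel counts must be >= 1")
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")


def _he(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape), requires_grad=True)


class _Stage:
    """Stride-2 downsampling conv + residual block (2 convs, identity skip)."""

    def __init__(self, rng, cin, cout):
        k3 = 27
        self.wd = _he(rng, (cout, cin, 3, 3, 3), cin * k3)
        self.bd = Tensor(np.zeros(cout), requires_grad=True)
        self.w1 = _he(rng, (cout, cout, 3, 3, 3), cout * k3)
        self.b1 = Tensor(np.zeros(cout), requires_grad=True)
        self.w2 = _he(rng, (cout, cout, 3, 3, 3), cout * k3)
        self.b2 = Tensor(np.zeros(cout), requires_grad=True)

    def params(self):
        return [self.wd, self.bd, self.w1, self.b1, self.w2, self.b2]

    def __call__(self, x: Tensor) -> Tensor:
        h = conv3d(x, self.wd, self.bd, stride=2, padding=1).relu()
        r = conv3d(h, self.w1, self.b1, stride=1, padding=1).relu()
        r = conv3d(r, self.w2, self.b2, stride=1, padding=1)
        return (h + r).relu()


class Encoder3D:
    """Volumes (N, C, D, H, W) -> embeddings (N, embedding_dim)."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        chans = [config.input_channels] + list(config.stage_channels)
        self.stages = [_Stage(rng, cin, cout) for cin, cout in zip(chans[:-1], chans[1:])]
        self.w_emb = _he(rng, (chans[-1], config.embedding_dim), chans[-1])
        self.b_emb = Tensor(np.zeros(config.embedding_dim), requires_grad=True)
        self._rng = rng

    def params(self):
        ps = [p for s in self.stages for p in s.params()]
        return ps + [self.w_emb, self.b_emb]

    def check_shape(self, spatial) -> None:
        need = 2 ** len(self.stages)
        if min(spatial) < need:
            raise ValueError(
                f"spatial shape {tuple(spatial)} too small for {len(self.stages)} "
                f"stride-2 stages (each dim must be >= {need})"
            )

    def __call__(self, x: Tensor, train: bool = False) -> Tensor:
        self.check_shape(x.shape[2:])
        h = x
        for s in self.stages:
            h = s(h)
        h = h.mean(axis=(2, 3, 4))  # global average pool -> (N, C)
        if train and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            mask = (self._rng.random(h.shape) < keep) / keep
            h = h * Tensor(mask)
        return h @ self.w_emb + self.b_emb


class RegressionHead:
    """Two-layer MLP (embedding -> hidden -> 1) for supervised age regression."""

    def __init__(self, embedding_dim: int, hidden: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.w1 = _he(rng, (embedding_dim, hidden), embedding_dim)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.w2 = _he(rng, (hidden, 1), hidden)
        self.b2 = Tensor(np.zeros(1), requires_grad=True)

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def __call__(self, emb: Tensor) -> Tensor:
        return ((emb @ self.w1 + self.b1).relu() @ self.w2 + self.b2).reshape(-1)
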