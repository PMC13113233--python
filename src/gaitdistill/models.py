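"""Teacher and student architectures for per-cycle torque regression.

The *teacher* consumes a 2-D time-frequency representation of each IMU cycle:
every channel is expanded into a continuous-wavelet-transform (CWT) magnitude
scalogram on log-spaced scales, and a convolutional backbone (stride-2 in the
frequency axis, stride-1 in time) followed by multi-head self-attention over
time extracts features.  A linear projection W_T maps backbone features into a
``D_anchor``-dimensional anchor space from which a linear head reads out the
per-timestep torque.

The *student* consumes the raw 1-D IMU channels with a small stacked GRU and a
per-timestep linear torque head.  A linear *dimensional adapter* W_S maps the
final hidden state into the same anchor space, making the two heterogeneous
models comparable through the Gram images of W_T and W_S (see
:mod:`gaitdistill.anchor`).

Two scale presets are provided per model: ``paper`` reproduces the published
parameter budgets (teacher ~32 M, student ~0.45 M, a >=98 % reduction) and
``test`` is a miniature (<0.1 M) configuration for desk-scale experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pywt

from .autodiff import Tensor
from .nn import GRU, Conv2d, LayerNorm, Linear, Module, MultiheadSelfAttention

__all__ = [
    "TeacherConfig",
    "StudentConfig",
    "Scalogram",
    "cwt_scalogram",
    "TeacherNet",
    "StudentNet",
    "count_parameters",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TeacherConfig:
    n_scales: int = 32
    wavelet: str = "cmor1.5-1.0"
    conv_channels: tuple[int, ...] = (256, 512, 1024, 1024)
    attention_heads: int = 8
    ffn_mult: int = 6
    d_anchor: int = 64
    in_channels: int = 6
    out_axes: int = 1
    scale_preset: Literal["paper", "test"] = "paper"

    @classmethod
    def paper(cls, d_anchor: int = 64) -> "TeacherConfig":
        return cls(d_anchor=d_anchor)

    @classmethod
    def test(cls, d_anchor: int = 16) -> "TeacherConfig":
        return cls(
            n_scales=12,
            conv_channels=(8, 16, 24, 32),
            attention_heads=2,
            ffn_mult=2,
            d_anchor=d_anchor,
            scale_preset="test",
        )


@dataclass(frozen=True)
class StudentConfig:
    rnn_hidden: int = 224
    rnn_layers: int = 2
    d_anchor: int = 64
    in_channels: int = 6
    out_axes: int = 1
    scale_preset: Literal["paper", "test"] = "paper"

    @classmethod
    def paper(cls, d_anchor: int = 64) -> "StudentConfig":
        return cls(d_anchor=d_anchor)

    @classmethod
    def test(cls, d_anchor: int = 16) -> "StudentConfig":
        return cls(rnn_hidden=32, d_anchor=d_anchor, scale_preset="test")


@dataclass(frozen=True)
class Scalogram:
    """CWT magnitude per channel: values (C, n_scales, T), scales log-spaced."""

    values: np.ndarray
    scales: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError(f"scalogram must be (C, S, T), got shape {v.shape}")
        if np.any(v < 0):
            raise ValueError("scalogram magnitudes must be nonnegative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "scales", np.asarray(self.scales, dtype=np.float64))


# ---------------------------------------------------------------------------
# CWT front end
# ---------------------------------------------------------------------------


def cwt_scales(cfg: TeacherConfig, fs: float = 100.0) -> np.ndarray:
    """Log-spaced scales covering roughly 0.5 Hz .. fs/4 for the config wavelet."""
    fc = pywt.central_frequency(cfg.wavelet)
    f_hi = fs / 4.0
    f_lo = 0.5
    s_min = fc * fs / f_hi
    s_max = fc * fs / f_lo
    return np.geomspace(s_min, s_max, cfg.n_scales)


def cwt_scalogram(x: np.ndarray, cfg: TeacherConfig, fs: float = 100.0) -> Scalogram:
    """Per-channel CWT magnitude of an IMU cycle (C, T) on log-spaced scales."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"expected (C, T) input, got shape {x.shape}")
    T = x.shape[1]
    if T < 16:
        raise ValueError(f"cycle of {T} samples too short for CWT (need >= 16)")
    scales = cwt_scales(cfg, fs)
    if scales.max() > 4 * T:
        raise ValueError(
            f"largest scale {scales.max():.1f} too long for a {T}-sample cycle"
        )
    coefs, _ = pywt.cwt(x, scales, cfg.wavelet, sampling_period=1.0 / fs, axis=-1)
    # pywt returns (n_scales, C, T); magnitude, channel-major
    mag = np.abs(coefs).transpose(1, 0, 2)
    return Scalogram(mag, scales)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


class _AttentionBlock(Module):
    """Pre-LN transformer block: x + MHSA(LN(x)), then x + FFN(LN(x))."""

    def __init__(self, dim: int, heads: int, ffn_mult: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiheadSelfAttention(dim, heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ffn_mult * dim, rng)
        self.ff2 = Linear(ffn_mult * dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ff2(self.ff1(self.ln2(x)).tanh())


class TeacherNet(Module):
    """CWT-scalogram teacher: conv backbone + self-attention + anchor head."""

    def __init__(self, cfg: TeacherConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        chans = (cfg.in_channels,) + cfg.conv_channels
        self.convs = [
            Conv2d(chans[i], chans[i + 1], 3, rng, stride=(2, 1), padding=(1, 1))
            for i in range(len(cfg.conv_channels))
        ]
        width = cfg.conv_channels[-1]
        self.block = _AttentionBlock(width, cfg.attention_heads, cfg.ffn_mult, rng)
        self.project = Linear(width, cfg.d_anchor, rng)  # anchor projection W_T
        self.head = Linear(cfg.d_anchor, cfg.out_axes, rng)
        self.seed = seed

    def forward_with_anchor(self, x) -> tuple[Tensor, Tensor, Tensor]:
        """Map scalograms (B, C, S, T) -> (tau (B, T, A), z (B, D_anchor), W_T)."""
        if isinstance(x, Scalogram):
            x = x.values[None]
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} channels, got {x.shape[1]}"
            )
        for conv in self.convs:
            x = conv(x).tanh()
        feats = x.mean(axis=2)  # collapse frequency -> (B, width, T)
        feats = feats.transpose((0, 2, 1))  # (B, T, width)
        feats = self.block(feats)
        anchor_seq = (feats @ self.project.W + self.project.b).tanh()
        z = anchor_seq.mean(axis=1)  # pooled anchor activation (B, D_anchor)
        tau = anchor_seq @ self.head.W + self.head.b  # (B, T, A)
        # the per-timestep anchor activations carry the loss sensitivity used
        # by the diagonal Fisher estimate
        self._fisher_node = anchor_seq
        return tau, z, self.project.W

    def __call__(self, x) -> Tensor:
        return self.forward_with_anchor(x)[0]

    def anchor_weights(self) -> Tensor:
        """Live anchor projection weight W_T (backbone width x D_anchor)."""
        return self.project.W


class StudentNet(Module):
    """Lightweight recurrent student on raw 1-D IMU cycles."""

    def __init__(self, cfg: StudentConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.gru = GRU(cfg.in_channels, cfg.rnn_hidden, cfg.rnn_layers, rng)
        self.head = Linear(cfg.rnn_hidden, cfg.out_axes, rng)
        self.adapter = Linear(cfg.rnn_hidden, cfg.d_anchor, rng)  # W_S
        self.seed = seed

    def forward_with_anchor(self, x) -> tuple[Tensor, Tensor, Tensor]:
        """Map raw cycles (B, C, T) -> (tau (B, T, A), z (B, D_anchor), W_S)."""
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}"
            )
        seq = x.transpose((0, 2, 1))  # (B, T, C)
        h_seq, h_last = self.gru(seq)
        tau = h_seq @ self.head.W + self.head.b
        z = h_last @ self.adapter.W + self.adapter.b
        return tau, z, self.adapter.W

    def __call__(self, x) -> Tensor:
        return self.forward_with_anchor(x)[0]

    def anchor_weights(self) -> Tensor:
        """Live adapter weight W_S (rnn_hidden x D_anchor)."""
        return self.adapter.W


def count_parameters(model: Module) -> int:
    """Number of trainable scalar parameters."""
    return model.num_parameters()
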