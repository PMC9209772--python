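"""One-dimensional convolutional block attention (channel + temporal).

Given a feature map ``F ∈ ℝ^{T×C}`` (T time frames, C feature channels), the
block computes

* a feature-channel attention map ``M_C ∈ (0,1)^{1×C}``: average- and
  max-pool F over time, push both pooled vectors through a shared two-layer
  bottleneck perceptron (hidden width C/r, rectifier after the first layer),
  sum, sigmoid — ``M_C = σ(W₁ρ(W₀ F̄) + W₁ρ(W₀ F̂))``;
* a temporal attention map ``M_T ∈ (0,1)^{T×1}``: average- and max-pool F
  over feature channels, stack the two T-vectors as a 2-channel sequence,
  convolve with a length-3 kernel (zero same-padding), sigmoid;

and applies them sequentially: ``F′ = M_C ⊗ F`` then ``F″ = M_T ⊗ F′``
(broadcast elementwise products). Attention values lie strictly in (0,1),
so the block only re-weights — it never amplifies beyond the input.

Two equivalent surfaces are provided: pure-numpy functions on explicit
parameter bundles (used throughout the tests and for inspection), and the
trainable :class:`CBAM1d` layer operating on ``(N, C, L)`` activations
inside the network (time = L). Cross-agreement of the two is covered by the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from .nn import Module

__all__ = [
    "ChannelAttentionParams",
    "TemporalAttentionParams",
    "AttentionOutputs",
    "channel_attention",
    "temporal_attention",
    "apply_cbam",
    "CBAM1d",
    "cbam_parameter_count",
]


@dataclass(frozen=True)
class ChannelAttentionParams:
    """Shared-MLP weights: ``w0`` (C × C/r) bottleneck, ``w1`` (C/r × C)."""

    w0: np.ndarray
    w1: np.ndarray
    b0: np.ndarray | None = None
    b1: np.ndarray | None = None

    def validate(self, n_channels: int) -> None:
        c, cr = self.w0.shape
        if c != n_channels or self.w1.shape != (cr, c):
            raise ValueError(
                f"inconsistent MLP shapes {self.w0.shape}/{self.w1.shape} "
                f"for C={n_channels}"
            )


@dataclass(frozen=True)
class TemporalAttentionParams:
    """Length-3 conv kernel over the stacked [avg; max] pooled pair.

    ``kernel`` has shape (2, 3): one 3-tap filter per pooled input channel.
    """

    kernel: np.ndarray
    bias: float = 0.0

    def validate(self) -> None:
        if self.kernel.shape != (2, 3):
            raise ValueError(f"temporal kernel must be (2, 3); got {self.kernel.shape}")


@dataclass(frozen=True)
class AttentionOutputs:
    mc: np.ndarray  # (1, C)
    mt: np.ndarray  # (T, 1)
    f_prime: np.ndarray  # (T, C)
    f_doubleprime: np.ndarray  # (T, C)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _mlp(v: np.ndarray, p: ChannelAttentionParams) -> np.ndarray:
    h = v @ p.w0
    if p.b0 is not None:
        h = h + p.b0
    h = np.maximum(h, 0.0)
    out = h @ p.w1
    if p.b1 is not None:
        out = out + p.b1
    return out


def channel_attention(f: np.ndarray, params: ChannelAttentionParams) -> np.ndarray:
    """Feature-channel attention map ``M_C`` of shape (1, C), values in (0,1)."""
    f = np.asarray(f, dtype=float)
    params.validate(f.shape[1])
    f_avg = f.mean(axis=0)  # time-average per channel
    f_max = f.max(axis=0)  # time-max per channel
    return _sigmoid(_mlp(f_avg, params) + _mlp(f_max, params))[None, :]


def temporal_attention(f: np.ndarray, params: TemporalAttentionParams) -> np.ndarray:
    """Temporal attention map ``M_T`` of shape (T, 1), values in (0,1)."""
    f = np.asarray(f, dtype=float)
    params.validate()
    pooled = np.stack([f.mean(axis=1), f.max(axis=1)])  # (2, T), [avg; max]
    padded = np.pad(pooled, ((0, 0), (1, 1)))
    t = f.shape[0]
    conv = np.empty(t)
    for i in range(t):
        conv[i] = np.sum(padded[:, i : i + 3] * params.kernel) + params.bias
    return _sigmoid(conv)[:, None]


def apply_cbam(
    f: np.ndarray,
    channel_params: ChannelAttentionParams,
    temporal_params: TemporalAttentionParams,
) -> AttentionOutputs:
    """Sequential channel-then-temporal attention on a (T, C) feature map."""
    f = np.asarray(f, dtype=float)
    mc = channel_attention(f, channel_params)
    f_prime = mc * f
    mt = temporal_attention(f_prime, temporal_params)
    f_dp = mt * f_prime
    return AttentionOutputs(mc=mc, mt=mt, f_prime=f_prime, f_doubleprime=f_dp)


def cbam_parameter_count(n_channels: int, r: int, mlp_bias: bool = False) -> int:
    """Exact trainable-parameter count added by one block: 2C²/r for the
    shared MLP (+ C/r + C biases if enabled) + 2·3 + 1 for the temporal conv."""
    c, cr = n_channels, n_channels // r
    count = 2 * c * cr + 2 * 3 + 1
    if mlp_bias:
        count += cr + c
    return count


class CBAM1d(Module):
    """Trainable 1-D CBAM on ``(N, C, L)`` activations (time along L).

    ``r`` must divide the channel count. The shared MLP is bias-free by
    default; the temporal conv kernel is fixed at length 3 with zero
    same-padding so ``M_T`` has the input's temporal length.
    """

    def __init__(self, channels: int, r: int, rng: np.random.Generator,
                 mlp_bias: bool = False):
        super().__init__()
        if channels % r != 0:
            raise ValueError(f"compression rate r={r} must divide C={channels}")
        self.channels, self.r = channels, r
        cr = channels // r
        lim0 = np.sqrt(6.0 / (channels + cr))
        self.w0 = Tensor(rng.uniform(-lim0, lim0, (channels, cr)), requires_grad=True)
        self.w1 = Tensor(rng.uniform(-lim0, lim0, (cr, channels)), requires_grad=True)
        self.b0 = Tensor(np.zeros(cr), requires_grad=True) if mlp_bias else None
        self.b1 = Tensor(np.zeros(channels), requires_grad=True) if mlp_bias else None
        limk = np.sqrt(6.0 / (2 * 3 + 1))
        self.t_kernel = Tensor(rng.uniform(-limk, limk, (1, 2, 3)), requires_grad=True)
        self.t_bias = Tensor(np.zeros(1), requires_grad=True)

    def _shared_mlp(self, v: Tensor) -> Tensor:
        h = v @ self.w0
        if self.b0 is not None:
            h = h + self.b0
        h = h.relu()
        out = h @ self.w1
        if self.b1 is not None:
            out = out + self.b1
        return out

    def channel_map(self, x: Tensor) -> Tensor:
        """M_C for a batch: (N, C)."""
        f_avg = x.mean(axis=2)  # (N, C)
        f_max = x.max(axis=2)
        return (self._shared_mlp(f_avg) + self._shared_mlp(f_max)).sigmoid()

    def temporal_map(self, x: Tensor) -> Tensor:
        """M_T for a batch: (N, 1, L)."""
        pooled = Tensor.concat(
            [
                x.mean(axis=1, keepdims=True),  # (N, 1, L) channel-average
                x.max(axis=1, keepdims=True),  # (N, 1, L) channel-max
            ],
            axis=1,
        )  # (N, 2, L), order [avg; max]
        conv = pooled.conv1d(self.t_kernel, self.t_bias, stride=1, padding=1)
        return conv.sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        n, c, length = x.shape
        mc = self.channel_map(x).reshape(n, c, 1)
        f_prime = x * mc
        mt = self.temporal_map(f_prime)
        return f_prime * mt

    def export_params(self) -> tuple[ChannelAttentionParams, TemporalAttentionParams]:
        """Current weights as the functional parameter bundles."""
        return (
            ChannelAttentionParams(
                w0=self.w0.data.copy(),
                w1=self.w1.data.copy(),
                b0=None if self.b0 is None else self.b0.data.copy(),
                b1=None if self.b1 is None else self.b1.data.copy(),
            ),
            TemporalAttentionParams(
                kernel=self.t_kernel.data[0].copy(),
                bias=float(self.t_bias.data[0]),
            ),
        )
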