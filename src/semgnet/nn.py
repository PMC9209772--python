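"""Neural-network building blocks over the package's autodiff engine.

Layers follow the familiar Module convention: parameters are named tensors
discovered recursively, ``train()``/``eval()`` toggle stochastic behaviour
(dropout, batch-norm statistics), and state dicts are plain
name → numpy-array mappings for checkpointing. Weight initialization is
driven by an explicit seeded generator so whole-model construction is
reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "BatchNorm1d",
    "GRU",
    "Dropout",
    "Adam",
    "softmax",
    "cross_entropy",
]


class Module:
    """Base class: parameter discovery, mode switching, state dicts."""

    def __init__(self) -> None:
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, attr in vars(self).items():
            if isinstance(attr, Tensor) and attr.requires_grad:
                out.append((prefix + name, attr))
            elif isinstance(attr, Module):
                out.extend(attr.named_parameters(prefix + name + "."))
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{prefix}{name}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{prefix}{name}.{i}", item))
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def _set_mode(self, training: bool) -> None:
        self.training = training
        for attr in vars(self).values():
            if isinstance(attr, Module):
                attr._set_mode(training)
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        item._set_mode(training)

    def train(self) -> "Module":
        self._set_mode(True)
        return self

    def eval(self) -> "Module":
        self._set_mode(False)
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out: list[tuple[str, np.ndarray]] = []
        for name, attr in vars(self).items():
            if isinstance(attr, np.ndarray) and name.startswith("running_"):
                out.append((prefix + name, attr))
            elif isinstance(attr, Module):
                out.extend(attr.named_buffers(prefix + name + "."))
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        out.extend(item.named_buffers(f"{prefix}{name}.{i}."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data[...] = value
            elif name in bufs:
                bufs[name][...] = value
            else:
                raise KeyError(f"unknown parameter/buffer {name!r}")


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = _glorot(rng, (in_features, out_features), in_features, out_features)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv1d(Module):
    """1-D convolution (cross-correlation), same semantics as the engine op."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: int | None = None, bias: bool = True):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("odd kernel sizes only")
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_channels * kernel
        self.weight = _glorot(rng, (out_channels, in_channels, kernel),
                              fan_in, out_channels * kernel)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class BatchNorm1d(Module):
    """Per-feature-channel normalization over the batch and time axes.

    Input ``(N, C, L)``; training mode uses batch statistics and updates the
    exponential running estimates used in eval mode.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1))
        xhat = (x - mu) * (var + self.eps) ** (-0.5)
        return xhat * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


class GRU(Module):
    """Gated recurrent unit over a (N, T, C) sequence; returns (N, T, H).

    Update gate z, reset gate r, candidate state n:
    ``z = σ(x W_z + h U_z + b_z)``, ``r = σ(x W_r + h U_r + b_r)``,
    ``n = tanh(x W_n + r·(h U_n) + b_n)``, ``h ← (1−z)·n + z·h``.
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.hidden_size = hidden_size
        def mk(shape, fi, fo):
            return _glorot(rng, shape, fi, fo)
        i, h = input_size, hidden_size
        self.Wz, self.Uz = mk((i, h), i, h), mk((h, h), h, h)
        self.Wr, self.Ur = mk((i, h), i, h), mk((h, h), h, h)
        self.Wn, self.Un = mk((i, h), i, h), mk((h, h), h, h)
        self.bz = Tensor(np.zeros(h), requires_grad=True)
        self.br = Tensor(np.zeros(h), requires_grad=True)
        self.bn = Tensor(np.zeros(h), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n_batch, t_steps, _ = x.shape
        h = Tensor(np.zeros((n_batch, self.hidden_size)))
        outs = []
        for t in range(t_steps):
            xt = x[:, t, :]
            z = (xt @ self.Wz + h @ self.Uz + self.bz).sigmoid()
            r = (xt @ self.Wr + h @ self.Ur + self.br).sigmoid()
            n = (xt @ self.Wn + r * (h @ self.Un) + self.bn).tanh()
            h = (1.0 - z) * n + z * h
            outs.append(h.reshape(n_batch, 1, self.hidden_size))
        return Tensor.concat(outs, axis=1)

    def last_state(self, x: Tensor) -> Tensor:
        seq = self.forward(x)
        return seq[:, seq.shape[1] - 1, :]


class Dropout(Module):
    """Inverted dropout; a no-op in eval mode. Mask randomness comes from the
    generator handed in at construction (reseed per training run)."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not (0 <= p < 1):
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Adam:
    """Adam with bias-corrected first/second moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax ``p(m|g) = exp(g_m) / Σ_j exp(g_j)``."""
    g = np.asarray(logits, dtype=float)
    g = g - g.max(axis=axis, keepdims=True)
    e = np.exp(g)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy. ``logits`` (N, M), ``labels`` int (N,)."""
    n = logits.shape[0]
    shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    logsumexp = shifted.exp().sum(axis=1, keepdims=True).log()
    logp = shifted - logsumexp
    picked = logp[np.arange(n), np.asarray(labels, dtype=int)]
    return -picked.mean()
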