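"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the training backend for the package's neural networks: a tape of
:class:`Tensor` nodes, each holding a value, an accumulated gradient and a
closure that pushes gradients to its parents. The op set is exactly what
the multi-stream CNN/GRU/attention models need (broadcast arithmetic,
matmul, 1-D convolution and pooling, pointwise nonlinearities, axis
reductions, reshape/concat/indexing). Everything is float64 and CPU-only;
the models in this package are deliberately small.

Backward passes run in reverse topological order from the loss; gradients
accumulate, so call :meth:`Tensor.backward` once per graph (or zero grads
between calls).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ---- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # ---- arithmetic --------------------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor._wrap(other)
        out_data = a.data + b.data

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(out_data, (a, b), backward)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, Tensor._wrap(other)
        out_data = a.data * b.data

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * Tensor._wrap(other) ** (-1.0)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self ** (-1.0)

    def __pow__(self, p: float):
        a = self
        out_data = a.data**p

        def backward(g):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1.0))

        return Tensor._make(out_data, (a,), backward)

    def __matmul__(self, other):
        a, b = self, Tensor._wrap(other)
        out_data = a.data @ b.data

        def backward(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._make(out_data, (a, b), backward)

    # ---- pointwise nonlinearities ------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self
        out_data = np.log(a.data)

        def backward(g):
            a._accum(g / a.data)

        return Tensor._make(out_data, (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            a._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0
        out_data = a.data * mask

        def backward(g):
            a._accum(g * mask)

        return Tensor._make(out_data, (a,), backward)

    # ---- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                grad = np.broadcast_to(g, a.shape)
            elif keepdims:
                grad = np.broadcast_to(g, a.shape)
            else:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(ax % a.ndim for ax in axes)
                g_exp = np.expand_dims(g, axes)
                grad = np.broadcast_to(g_exp, a.shape)
            a._accum(grad.astype(float))

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; ties route the gradient to the first maximum."""
        a = self
        out_data = a.data.max(axis=axis, keepdims=keepdims)
        arg = a.data.argmax(axis=axis)
        onehot = np.zeros_like(a.data)
        np.put_along_axis(onehot, np.expand_dims(arg, axis), 1.0, axis=axis)

        def backward(g):
            g_exp = g if keepdims else np.expand_dims(g, axis)
            a._accum(onehot * g_exp)

        return Tensor._make(out_data, (a,), backward)

    # ---- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        a = self
        out_data = a.data.reshape(*shape)

        def backward(g):
            a._accum(g.reshape(a.shape))

        return Tensor._make(out_data, (a,), backward)

    def transpose(self, *axes):
        a = self
        out_data = a.data.transpose(*axes)
        inv = np.argsort(axes)

        def backward(g):
            a._accum(g.transpose(*inv))

        return Tensor._make(out_data, (a,), backward)

    def __getitem__(self, key):
        a = self
        out_data = a.data[key]

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            a._accum(full)

        return Tensor._make(out_data, (a,), backward)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = 0) -> "Tensor":
        tensors = [Tensor._wrap(t) for t in tensors]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])

        return Tensor._make(out_data, tuple(tensors), backward)

    # ---- convolution / pooling ---------------------------------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0) -> "Tensor":
        """1-D cross-correlation.

        ``self``: (N, C_in, L); ``weight``: (C_out, C_in, K);
        output (N, C_out, L_out) with L_out = (L + 2·padding − K)//stride + 1.
        """
        x, w = self, weight
        n, cin, length = x.shape
        cout, cin_w, k = w.shape
        if cin != cin_w:
            raise ValueError(f"conv1d channel mismatch: input {cin}, kernel {cin_w}")
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)))
        lout = (length + 2 * padding - k) // stride + 1
        # im2col: (N, L_out, C_in*K)
        idx = stride * np.arange(lout)[:, None] + np.arange(k)[None, :]
        cols = xp[:, :, idx]  # (N, C_in, L_out, K)
        cols2 = cols.transpose(0, 2, 1, 3).reshape(n, lout, cin * k)
        wmat = w.data.reshape(cout, cin * k)
        out_data = np.einsum("nlf,of->nol", cols2, wmat)
        if bias is not None:
            out_data = out_data + bias.data[None, :, None]

        parents = (x, w) if bias is None else (x, w, bias)

        def backward(g):
            # g: (N, C_out, L_out)
            if w.requires_grad:
                gw = np.einsum("nol,nlf->of", g, cols2).reshape(cout, cin, k)
                w._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2)))
            if x.requires_grad:
                gcols2 = np.einsum("nol,of->nlf", g, wmat)
                gcols = gcols2.reshape(n, lout, cin, k).transpose(0, 2, 1, 3)
                gxp = np.zeros_like(xp)
                np.add.at(gxp, (slice(None), slice(None), idx), gcols)
                gx = gxp[:, :, padding : padding + length] if padding else gxp
                x._accum(gx)

        return Tensor._make(out_data, parents, backward)

    def maxpool1d(self, kernel: int) -> "Tensor":
        """Non-overlapping max pooling along the last axis (stride = kernel).

        A trailing remainder shorter than the kernel is dropped.
        """
        x = self
        n, c, length = x.shape
        lout = length // kernel
        trimmed = x.data[:, :, : lout * kernel].reshape(n, c, lout, kernel)
        out_data = trimmed.max(axis=3)
        arg = trimmed.argmax(axis=3)

        def backward(g):
            gx = np.zeros((n, c, lout, kernel))
            np.put_along_axis(gx, arg[..., None], g[..., None], axis=3)
            full = np.zeros_like(x.data)
            full[:, :, : lout * kernel] = gx.reshape(n, c, lout * kernel)
            x._accum(full)

        return Tensor._make(out_data, (x,), backward)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"
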