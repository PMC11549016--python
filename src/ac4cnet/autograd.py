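"""A compact reverse-mode automatic-differentiation core on NumPy arrays.

The network in this package is a differentiable computation graph built from
a handful of primitives (matmul, elementwise nonlinearities, softmax,
embedding lookup, 1-D convolution, max-pooling, reductions).  Each primitive
records its parents and a closure that accumulates gradients; calling
:meth:`Tensor.backward` on a scalar loss runs the chain rule over a
topological sort of the graph.

Besides training, input gradients from this core drive the fast-gradient
(FGM) robustness attack, which perturbs feature tensors along the sign of
``dJ/dx``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An n-d array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...],
              backward: Callable[["Tensor"], None]) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = lambda: backward(out)
        return out

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)

        def backward(out: Tensor) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(out: Tensor) -> None:
            if self.requires_grad:
                self._accumulate(-out.grad)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)

        def backward(out: Tensor) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            raise NotImplementedError("division only by constants")
        return self * (1.0 / other)

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._lift(other)

        def backward(out: Tensor) -> None:
            g = out.grad
            if self.requires_grad:
                gs = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(gs, self.shape))
            if other.requires_grad:
                go = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(go, other.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    # -- shaping -------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        old = self.shape

        def backward(out: Tensor) -> None:
            if self.requires_grad:
                self._accumulate(out.grad.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        def backward(out: Tensor) -> None:
            if self.requires_grad:
                self._accumulate(np.swapaxes(out.grad, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), backward)

    def __getitem__(self, key) -> "Tensor":
        def backward(out: Tensor) -> None:
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, key, out.grad)
                self._accumulate(g)

        return self._make(self.data[key], (self,), backward)

    # -- nonlinearities ------------------------------------------------------

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))

        def backward(out: Tensor) -> None:
            if self.requires_grad:
                self._accumulate(out.grad * y * (1.0 - y))

        return self._make(y, (self,), backward)

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)

        def backward(out: Tensor) -> None:
            if self.requires_grad:
                self._accumulate(out.grad * (1.0 - y * y))

        return self._make(y, (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(out: Tensor) -> None:
            if self.requires_grad:
                self._accumulate(out.grad * mask)

        return self._make(self.data * mask, (self,), backward)

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(out: Tensor) -> None:
            if self.requires_grad:
                g = out.grad
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accumulate((g - dot) * y)

        return self._make(y, (self,), backward)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(out: Tensor) -> None:
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def amax(self, axis: int) -> "Tensor":
        arg = self.data.argmax(axis=axis)
        y = np.take_along_axis(self.data, np.expand_dims(arg, axis), axis=axis)

        def backward(out: Tensor) -> None:
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.put_along_axis(
                    g, np.expand_dims(arg, axis), np.expand_dims(out.grad, axis), axis=axis
                )
                self._accumulate(g)

        return self._make(np.squeeze(y, axis=axis), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- graph traversal -----------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from a scalar output."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()


# ---------------------------------------------------------------------------
# Structured primitives
# ---------------------------------------------------------------------------

def concatenate(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(data, requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)

        def backward() -> None:
            pieces = np.split(out.grad, splits, axis=axis)
            for t, g in zip(tensors, pieces):
                if t.requires_grad:
                    t._accumulate(g)

        out._backward = backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(data, requires_grad=any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)

        def backward() -> None:
            pieces = np.moveaxis(out.grad, axis, 0)
            for t, g in zip(tensors, pieces):
                if t.requires_grad:
                    t._accumulate(g)

        out._backward = backward
    return out


def embedding(table: Tensor, codes: np.ndarray) -> Tensor:
    """Row lookup ``table[codes]`` with scatter-add backward."""
    codes = np.asarray(codes, dtype=np.int64)
    if codes.size and (codes.min() < 0 or codes.max() >= table.shape[0]):
        raise ValueError("embedding code outside table range")

    def backward(out: Tensor) -> None:
        if table.requires_grad:
            g = np.zeros_like(table.data)
            np.add.at(g, codes, out.grad)
            table._accumulate(g)

    return table._make(table.data[codes], (table,), backward)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor, padding: int = 0) -> Tensor:
    """1-D convolution, stride 1, symmetric zero padding.

    ``x``: (B, C_in, L); ``weight``: (C_out, C_in, K); ``bias``: (C_out,).
    """
    B, C_in, L = x.shape
    C_out, C_in_w, K = weight.shape
    if C_in != C_in_w:
        raise ValueError(f"channel mismatch: input {C_in}, kernel {C_in_w}")
    if L + 2 * padding < K:
        raise ValueError(f"kernel {K} exceeds padded length {L + 2 * padding}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)))
    L_out = L + 2 * padding - K + 1
    # im2col: (B, C_in, K, L_out)
    cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (B,C_in,L_out,K)
    cols = cols.transpose(0, 1, 3, 2).reshape(B, C_in * K, L_out)
    W2 = weight.data.reshape(C_out, C_in * K)
    y = np.einsum("ok,bkl->bol", W2, cols) + bias.data[None, :, None]

    def backward(out: Tensor) -> None:
        g = out.grad  # (B, C_out, L_out)
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2)))
        if weight.requires_grad:
            gw = np.einsum("bol,bkl->ok", g, cols).reshape(C_out, C_in, K)
            weight._accumulate(gw)
        if x.requires_grad:
            gcols = np.einsum("ok,bol->bkl", W2, g).reshape(B, C_in, K, L_out)
            gxp = np.zeros_like(xp)
            for j in range(K):
                gxp[:, :, j : j + L_out] += gcols[:, :, j, :]
            gx = gxp[:, :, padding : padding + L] if padding else gxp
            x._accumulate(gx)

    return x._make(y, (x, weight, bias), backward)


def maxpool1d(x: Tensor, width: int) -> Tensor:
    """Non-overlapping max-pool over the last axis; remainder positions drop."""
    B, C, L = x.shape
    L_out = L // width
    if L_out < 1:
        raise ValueError(f"pool width {width} exceeds length {L}")
    trimmed = x.data[:, :, : L_out * width].reshape(B, C, L_out, width)
    arg = trimmed.argmax(axis=-1)
    y = np.take_along_axis(trimmed, arg[..., None], axis=-1)[..., 0]

    def backward(out: Tensor) -> None:
        if x.requires_grad:
            g4 = np.zeros((B, C, L_out, width))
            np.put_along_axis(g4, arg[..., None], out.grad[..., None], axis=-1)
            g = np.zeros_like(x.data)
            g[:, :, : L_out * width] = g4.reshape(B, C, L_out * width)
            x._accumulate(g)

    return x._make(y, (x,), backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels against softmax(logits)."""
    labels = np.asarray(labels, dtype=np.int64)
    B = logits.shape[0]
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    loss = -logp[np.arange(B), labels].mean()
    p = np.exp(logp)

    def backward(out: Tensor) -> None:
        if logits.requires_grad:
            g = p.copy()
            g[np.arange(B), labels] -= 1.0
            logits._accumulate(out.grad * g / B)

    return logits._make(np.array(loss), (logits,), backward)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(self, params: Iterable[Tensor], lr: float = 0.001,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
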