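"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine provides exactly the primitives the pose-to-load network needs:
broadcast-aware arithmetic, batched matmul, reductions, shape ops, the
activation functions of the model (LeakyReLU, ReLU, GELU, sigmoid, softmax),
a causal time-shift for dilated convolutions, column gathering for feature
masks, and dropout.  Gradients are accumulated by a topological-order sweep
over the recorded graph, and an AdamW optimizer drives training.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import ndtr  # standard normal CDF


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def _in_graph(self) -> bool:
        return self.requires_grad or bool(self._parents)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for long sequences
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- op construction helper -------------------------------------------

    @staticmethod
    def _make(data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p._in_graph() for p in parents):
            out._parents = parents
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self._in_graph():
                self._accum(_unbroadcast(g, self.data.shape))
            if other._in_graph():
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self._in_graph():
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self._in_graph():
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other._in_graph():
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (as_tensor(other) ** -1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * (self ** -1.0)

    def __pow__(self, exponent: float):
        exponent = float(exponent)
        out_data = self.data ** exponent

        def backward(g):
            if self._in_graph():
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self._in_graph():
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other._in_graph():
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- reductions & shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self._in_graph():
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self._in_graph():
                self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out_data = self.data.transpose(axes)

        def backward(g):
            if self._in_graph():
                self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), backward)

    # -- pointwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self._in_graph():
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            if self._in_graph():
                self._accum(g * (self.data > 0.0))

        return Tensor._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.1):
        out_data = np.where(self.data >= 0.0, self.data, slope * self.data)

        def backward(g):
            if self._in_graph():
                self._accum(g * np.where(self.data >= 0.0, 1.0, slope))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self._in_graph():
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def gelu(self):
        # x * Phi(x); d/dx = Phi(x) + x * phi(x)
        phi_cdf = ndtr(self.data)
        out_data = self.data * phi_cdf

        def backward(g):
            if self._in_graph():
                pdf = np.exp(-0.5 * self.data ** 2) / np.sqrt(2.0 * np.pi)
                self._accum(g * (phi_cdf + self.data * pdf))

        return Tensor._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self._in_graph():
                inner = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - inner))

        return Tensor._make(out_data, (self,), backward)

    # -- structured ops -----------------------------------------------------

    def time_shift(self, k: int):
        """Shift along axis -2 (time) by k steps into the past, zero-padded.

        y[..., t, :] = x[..., t-k, :] for t >= k, else 0 -- the x_{t-d*k}
        lookup of a causal dilated convolution tap.
        """
        if k == 0:
            return self * 1.0
        out_data = np.zeros_like(self.data)
        out_data[..., k:, :] = self.data[..., :-k, :]

        def backward(g):
            if self._in_graph():
                gg = np.zeros_like(g)
                gg[..., :-k, :] = g[..., k:, :]
                self._accum(gg)

        return Tensor._make(out_data, (self,), backward)

    def take_last(self, indices: np.ndarray):
        """Gather columns of the last axis (feature-mask selection)."""
        idx = np.asarray(indices, dtype=int)
        out_data = self.data[..., idx]

        def backward(g):
            if self._in_graph():
                gg = np.zeros_like(self.data)
                np.add.at(gg, (..., idx), g)
                self._accum(gg)

        return Tensor._make(out_data, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t._in_graph():
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


# -- modules ---------------------------------------------------------------


class Module:
    """Parameter container with recursive traversal and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)

        walk(self)
        return params

    def _submodules(self):
        for v in vars(self).values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                yield from (m for m in v if isinstance(m, Module))

    def train(self):
        self.training = True
        for m in self._submodules():
            m.train()
        return self

    def eval(self):
        self.training = False
        for m in self._submodules():
            m.eval()
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(state[f"p{i}"], dtype=np.float64).reshape(p.data.shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((in_dim, out_dim))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / (in_dim + out_dim)),
                           size=(in_dim, out_dim))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class AdamW:
    """Decoupled weight-decay Adam (the training regimen's optimizer)."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
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
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                                 + self.weight_decay * p.data)
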