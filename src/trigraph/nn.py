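"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package's message-passing networks are small (a few hundred tensor
operations per forward pass, arrays of at most a few thousand rows), so a
compact numpy autodiff core is sufficient and keeps the whole stack
single-threaded and bit-reproducible.  The design is the usual tape-based
one: every operation records its parents and a closure that scatters the
output gradient back to them; ``Tensor.backward`` walks the tape in reverse
topological order.

Only the primitives the networks need are provided: elementwise arithmetic
with broadcasting, matmul, relu/tanh, reductions, row gather / segment-sum
(the two graph primitives), layer normalisation and a fused softmax
cross-entropy.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Linear",
    "MLP",
    "LayerNorm",
    "Adam",
    "gather",
    "segment_sum",
    "layer_norm",
    "relu",
    "tanh",
    "cross_entropy",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._prev for p in parents):
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise NotImplementedError("divide by a scalar only")
        return self * (1.0 / other)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g, out):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    def __pow__(self, p: float):
        def backward(g, out):
            return (g * p * self.data ** (p - 1),)

        return self._make(self.data**p, (self,), backward)

    # -- reductions / reshapes ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, out):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def backward(g, out):
            return (g.reshape(self.shape),)

        return self._make(self.data.reshape(*shape), (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad, node)
            for parent, g in zip(node._prev, grads):
                if g is None or not (parent.requires_grad or parent._prev):
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


# -- functional primitives ----------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g, out):
        return (g * mask,)

    return x._make(np.where(mask, x.data, 0.0), (x,), backward)


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)

    def backward(g, out):
        return (g * (1.0 - y**2),)

    return x._make(y, (x,), backward)


def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """Rows of x at idx (graph 'source node' lookup)."""
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g, out):
        gx = np.zeros_like(x.data)
        np.add.at(gx, idx, g)
        return (gx,)

    return x._make(x.data[idx], (x,), backward)


def segment_sum(x: Tensor, idx: np.ndarray, n: int) -> Tensor:
    """Scatter-add rows of x into n buckets (graph message aggregation)."""
    idx = np.asarray(idx, dtype=np.intp)
    out_data = np.zeros((n,) + x.data.shape[1:])
    np.add.at(out_data, idx, x.data)

    def backward(g, out):
        return (g[idx],)

    return x._make(out_data, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise each row to zero mean / unit variance, then scale + shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv

    def backward(g, out):
        d = x.data.shape[-1]
        gxhat = g * gamma.data
        gx = inv / d * (
            d * gxhat
            - gxhat.sum(axis=-1, keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=-1, keepdims=True)
        )
        ggamma = _unbroadcast(g * xhat, gamma.shape)
        gbeta = _unbroadcast(g, beta.shape)
        return (gx, ggamma, gbeta)

    return x._make(xhat * gamma.data + beta.data, (x, gamma, beta), backward)


def cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; target is an int class-index vector."""
    target = np.asarray(target, dtype=np.intp)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    n = logits.data.shape[0]
    loss = -logp[np.arange(n), target].mean()

    def backward(g, out):
        grad = np.exp(logp)
        grad[np.arange(n), target] -= 1.0
        return (g * grad / n,)

    return logits._make(np.array(loss), (logits,), backward)


def bce_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw scores (numerically stable)."""
    t = np.asarray(target, dtype=float)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def backward(g, out):
        sig = 1.0 / (1.0 + np.exp(-z))
        return (g * (sig - t) / n,)

    return logits._make(np.array(loss.mean()), (logits,), backward)


# -- modules ------------------------------------------------------------------

class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, identity: bool = False):
        if identity:
            if n_in != n_out:
                raise ValueError("identity init requires square weight")
            w = np.eye(n_in)
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.W = Parameter(w)
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class MLP(Module):
    """Two-layer perceptron with ReLU, the GIN combine / prediction head."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int, rng: np.random.Generator):
        self.fc1 = Linear(n_in, n_hidden, rng)
        self.fc2 = Linear(n_hidden, n_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(relu(self.fc1(x)))


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def clip_grad_norm(self, max_norm: float) -> float:
        total = np.sqrt(sum(float((p.grad**2).sum())
                            for p in self.params if p.grad is not None))
        if total > max_norm:
            scale = max_norm / (total + 1e-12)
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale
        return total

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
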