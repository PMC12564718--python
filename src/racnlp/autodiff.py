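"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical core that the transformer encoder and the
classification heads are built on: a tape-based ``Tensor`` holding a
float64 array, a gradient slot and a backward closure, plus the small
set of fused operations a masked-language-model / sequence-classifier
stack actually needs (matmul, layer norm, softmax, GELU, embedding
lookup, cross-entropy and weighted binary cross-entropy with logits).

The engine is deliberately small: every op has an analytic gradient,
there is no graph optimisation, and all arithmetic is float64 so that
pooling identities in the test-suite hold to tight tolerances.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "reshape",
    "transpose",
    "tsum",
    "concat",
    "gather",
    "take_rows",
    "layer_norm",
    "softmax",
    "gelu",
    "dropout",
    "softmax_cross_entropy",
    "bce_with_logits",
    "AdamW",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # remove leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Node in the computation graph.

    Parameters are created with ``requires_grad=True``; constants wrap
    plain arrays. Gradients accumulate into ``.grad`` during
    :meth:`backward`.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = tuple(_parents)
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph traversal ------------------------------------------------
    def backward(self):
        """Run reverse-mode accumulation from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return Tensor(out_data, _parents=(a, b), _backward=bwd)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, _parents=(a, b), _backward=bwd)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            if a.data.ndim == 1:
                ga = ga.reshape(a.data.shape) if ga.shape == a.data.shape else ga.sum(axis=0)
            _accum(a, _unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            if a.data.ndim == 1:
                gb = np.outer(a.data, g)
            else:
                gb = np.swapaxes(a.data, -1, -2) @ g
            _accum(b, _unbroadcast(gb, b.data.shape))

    return Tensor(out_data, _parents=(a, b), _backward=bwd)


def reshape(x, shape) -> Tensor:
    x = _as_tensor(x)
    out_data = x.data.reshape(shape)

    def bwd(g):
        _accum(x, g.reshape(x.data.shape))

    return Tensor(out_data, _parents=(x,), _backward=bwd)


def transpose(x, axes) -> Tensor:
    x = _as_tensor(x)
    out_data = np.transpose(x.data, axes)
    inv = np.argsort(axes)

    def bwd(g):
        _accum(x, np.transpose(g, inv))

    return Tensor(out_data, _parents=(x,), _backward=bwd)


def tsum(x, axis, keepdims: bool = False) -> Tensor:
    x = _as_tensor(x)
    out_data = x.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        gg = g
        if not keepdims:
            gg = np.expand_dims(g, axis)
        _accum(x, np.broadcast_to(gg, x.data.shape).copy())

    return Tensor(out_data, _parents=(x,), _backward=bwd)


def concat(tensors, axis: int = -1) -> Tensor:
    ts = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return Tensor(out_data, _parents=tuple(ts), _backward=bwd)


def gather(table: Tensor, idx: np.ndarray) -> Tensor:
    """Embedding lookup ``table[idx]`` with scatter-add backward."""
    idx = np.asarray(idx)
    out_data = table.data[idx]

    def bwd(g):
        if not table.requires_grad:
            return
        if table.grad is None:
            table.grad = np.zeros_like(table.data)
        np.add.at(table.grad, idx.ravel(), g.reshape(-1, table.data.shape[-1]))

    return Tensor(out_data, _parents=(table,), _backward=bwd)


def take_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows of a 2-D tensor (used to score only masked positions)."""
    idx = np.asarray(idx)
    out_data = x.data[idx]

    def bwd(g):
        if not x.requires_grad:
            return
        if x.grad is None:
            x.grad = np.zeros_like(x.data)
        np.add.at(x.grad, idx, g)

    return Tensor(out_data, _parents=(x,), _backward=bwd)


def layer_norm(x, gain, bias, eps: float = 1e-5) -> Tensor:
    """Fused layer normalisation over the last axis."""
    x, gain, bias = _as_tensor(x), _as_tensor(gain), _as_tensor(bias)
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = xhat * gain.data + bias.data
    d = x.data.shape[-1]

    def bwd(g):
        if gain.requires_grad:
            _accum(gain, (g * xhat).reshape(-1, d).sum(axis=0))
        if bias.requires_grad:
            _accum(bias, g.reshape(-1, d).sum(axis=0))
        if x.requires_grad:
            gx = g * gain.data
            term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            _accum(x, term * inv)

    return Tensor(out_data, _parents=(x, gain, bias), _backward=bwd)


def softmax(x, bias: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis; ``bias`` is an additive constant
    (e.g. the −1e9 attention mask) applied before normalisation."""
    x = _as_tensor(x)
    z = x.data if bias is None else x.data + bias
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=-1, keepdims=True)

    def bwd(g):
        dot = (g * out_data).sum(axis=-1, keepdims=True)
        _accum(x, (g - dot) * out_data)

    return Tensor(out_data, _parents=(x,), _backward=bwd)


_GELU_C = np.sqrt(2.0 / np.pi)


def gelu(x) -> Tensor:
    """GELU activation (tanh approximation)."""
    x = _as_tensor(x)
    u = _GELU_C * (x.data + 0.044715 * x.data**3)
    t = np.tanh(u)
    out_data = 0.5 * x.data * (1.0 + t)

    def bwd(g):
        du = _GELU_C * (1.0 + 3 * 0.044715 * x.data**2)
        dgelu = 0.5 * (1.0 + t) + 0.5 * x.data * (1.0 - t**2) * du
        _accum(x, g * dgelu)

    return Tensor(out_data, _parents=(x,), _backward=bwd)


def dropout(x, p: float, rng: np.random.Generator | None, train: bool) -> Tensor:
    """Inverted dropout; identity when not training or ``p == 0``."""
    x = _as_tensor(x)
    if not train or p <= 0.0:
        return x
    if rng is None:
        raise ValueError("dropout in training mode needs an rng")
    keep = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return mul(x, Tensor(keep))


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of ``logits`` [N, V] against integer targets [N]."""
    targets = np.asarray(targets)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1))
    loss_val = (lse - z[np.arange(n), targets]).mean()
    probs = np.exp(z - lse[:, None])

    def bwd(g):
        grad = probs.copy()
        grad[np.arange(n), targets] -= 1.0
        _accum(logits, g * grad / n)

    return Tensor(loss_val, _parents=(logits,), _backward=bwd)


def bce_with_logits(logits: Tensor, targets: np.ndarray, pos_weight: float = 1.0) -> Tensor:
    """Mean weighted binary cross-entropy computed on logits.

    ``pos_weight`` multiplies the positive-class term, countering class
    imbalance exactly as the classifier heads require.
    """
    y = np.asarray(targets, dtype=np.float64)
    z = logits.data
    n = z.size
    # softplus(z) = log(1 + e^z), computed stably
    loss_val = (pos_weight * y * np.logaddexp(0.0, -z) + (1.0 - y) * np.logaddexp(0.0, z)).mean()
    sig = 1.0 / (1.0 + np.exp(-z))

    def bwd(g):
        dz = (pos_weight * y * (sig - 1.0) + (1.0 - y) * sig) / n
        _accum(logits, g * dz)

    return Tensor(loss_val, _parents=(logits,), _backward=bwd)


class AdamW:
    """Adam with decoupled weight decay.

    Decay is applied to matrix-shaped parameters only (weights), never
    to biases or layer-norm gains, following common transformer
    practice.
    """

    def __init__(self, params: dict[str, Tensor], lr: float, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for name, p in self.params.items():
            if p.grad is None:
                continue
            m = self._m[name]
            v = self._v[name]
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and p.data.ndim >= 2:
                update = update + self.weight_decay * p.data
            p.data -= self.lr * update
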