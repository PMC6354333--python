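"""A minimal reverse-mode automatic-differentiation engine on numpy.

Just enough machinery for the recurrent relation-extraction network:
float64 tensors, the ops the model needs (matmul, elementwise arithmetic,
sigmoid/tanh, concatenation, row gathering for embeddings, elementwise
max for pooling, column slicing for LSTM gates, fused
softmax-cross-entropy) and an Adam optimizer.  Gradients are exact, which
the finite-difference checks in the test-suite verify directly.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

Array = np.ndarray


class Tensor:
    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, value: Array | float, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[Array], None] | None = None,
                 name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward
        self.name = name

    @property
    def shape(self) -> tuple[int, ...]:
        return self.value.shape

    def accumulate(self, g: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" {self.name}" if self.name else ""
        return f"Tensor{tag}(shape={self.value.shape}, grad={self.requires_grad})"


def parameter(value: Array, name: str = "") -> Tensor:
    return Tensor(np.array(value, dtype=np.float64), requires_grad=True, name=name)


def _wrap(x: Tensor | Array | float) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(value: Array, parents: Sequence[Tensor],
          backward: Callable[[Array], None]) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(value, requires_grad=req, parents=tuple(parents),
                  backward=backward if req else None)


def _unbroadcast(g: Array, shape: tuple[int, ...]) -> Array:
    """Reduce a gradient back to the shape of a broadcast operand."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


def add(a: Tensor | Array, b: Tensor | Array) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_val = a.value + b.value

    def backward(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.value.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.value.shape))

    return _node(out_val, (a, b), backward)


def mul(a: Tensor | Array, b: Tensor | Array) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_val = a.value * b.value

    def backward(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.value, a.value.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.value, b.value.shape))

    return _node(out_val, (a, b), backward)


def matmul(a: Tensor | Array, b: Tensor | Array) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_val = a.value @ b.value

    def backward(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(g @ b.value.T)
        if b.requires_grad:
            b.accumulate(a.value.T @ g)

    return _node(out_val, (a, b), backward)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.value))

    def backward(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(g * s * (1.0 - s))

    return _node(s, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.value)

    def backward(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(g * (1.0 - t * t))

    return _node(t, (a,), backward)


def concat(parts: Sequence[Tensor], axis: int = 1) -> Tensor:
    parts = [_wrap(p) for p in parts]
    out_val = np.concatenate([p.value for p in parts], axis=axis)
    sizes = [p.value.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def backward(g: Array) -> None:
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                p.accumulate(g[tuple(idx)])

    return _node(out_val, tuple(parts), backward)


def slice_cols(a: Tensor, start: int, stop: int) -> Tensor:
    out_val = a.value[:, start:stop]

    def backward(g: Array) -> None:
        if a.requires_grad:
            full = np.zeros_like(a.value)
            full[:, start:stop] = g
            a.accumulate(full)

    return _node(out_val, (a,), backward)


def gather_rows(table: Tensor, indices: Array) -> Tensor:
    """Embedding lookup: rows of ``table`` selected by an integer array."""
    indices = np.asarray(indices)
    out_val = table.value[indices]

    def backward(g: Array) -> None:
        if table.requires_grad:
            if table.grad is None:
                table.grad = np.zeros_like(table.value)
            np.add.at(table.grad, indices, g)

    return _node(out_val, (table,), backward)


def maximum(a: Tensor | Array, b: Tensor | Array) -> Tensor:
    """Elementwise max; on ties the gradient flows to the first operand."""
    a, b = _wrap(a), _wrap(b)
    take_a = a.value >= b.value
    out_val = np.where(take_a, a.value, b.value)

    def backward(g: Array) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * take_a, a.value.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * ~take_a, b.value.shape))

    return _node(out_val, (a, b), backward)


def dropout(a: Tensor, rate: float, rng: np.random.Generator,
            train: bool) -> Tensor:
    """Inverted dropout: active units are rescaled by 1/(1-rate)."""
    if not train or rate <= 0.0:
        return a
    keep = (rng.random(a.value.shape) >= rate) / (1.0 - rate)
    return mul(a, keep)


def softmax(logits: Array) -> Array:
    """Plain numpy softmax over the last axis (inference path)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: Array,
                          sample_weights: Array | None = None) -> Tensor:
    """Cross-entropy of integer ``labels`` under softmax of ``logits``.

    Unweighted: the plain mean over the batch.  With ``sample_weights``
    the per-sample losses are averaged with those weights
    (sum(w·ce)/sum(w)).
    """
    labels = np.asarray(labels)
    n = logits.value.shape[0]
    if sample_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(sample_weights, dtype=np.float64)
    w_norm = w / w.sum()
    z = logits.value - logits.value.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    per_sample = lse - z[np.arange(n), labels]
    loss = float(per_sample @ w_norm)
    probs = softmax(logits.value)

    def backward(g: Array) -> None:
        if logits.requires_grad:
            d = probs.copy()
            d[np.arange(n), labels] -= 1.0
            logits.accumulate(float(g) * d * w_norm[:, None])

    return _node(np.float64(loss), (logits,), backward)


def backward(loss: Tensor) -> None:
    """Reverse sweep from a scalar loss, filling ``.grad`` on every
    reachable tensor with ``requires_grad``."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(loss, False)]
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

    loss.grad = np.ones_like(loss.value)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


class Adam:
    """Adaptive moment estimation with the standard bias correction."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = self.m[i] / (1 - self.beta1 ** self.t)
            v_hat = self.v[i] / (1 - self.beta2 ** self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
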