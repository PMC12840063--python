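"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model is trained by stochastic gradient ascent on an evidence lower
bound assembled from small dense networks and mixture densities.  All of
those pieces are compositions of elementwise primitives, matrix products
and reductions, so a compact tape-based engine suffices.  Gradients are
accumulated by a reverse topological sweep over the recorded graph.

Broadcasting follows numpy semantics; gradients of broadcast operands are
summed back to the operand's shape (`_unbroadcast`).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "logsumexp", "softmax", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were broadcast from size 1
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # beat np.ndarray in mixed arithmetic

    def __init__(self, value, requires_grad: bool = False, _parents=(), _backward=None):
        self.value = np.asarray(value, dtype=np.float64 if np.asarray(value).dtype.kind != "f" else None)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    @property
    def size(self):
        return self.value.size

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.value)

    # -- autodiff driver -----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar output")
            grad = np.ones_like(self.value)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.value.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if not parent.requires_grad or pg is None:
                        continue
                    acc = grads.get(id(parent))
                    grads[id(parent)] = pg if acc is None else acc + pg
            else:  # leaf
                t.grad = g if t.grad is None else t.grad + g

    # -- arithmetic ----------------------------------------------------------
    # binary backwards return None for operands that do not require grad,
    # skipping the corresponding products/reductions entirely.  Python
    # scalars stay scalars (weak numpy promotion: float32 graphs are not
    # silently upcast) and never enter the tape.
    def __add__(self, other):
        if isinstance(other, (int, float)):
            return Tensor(self.value + other, _parents=(self,),
                          _backward=lambda g: (g,))
        other = as_tensor(other)

        def back(g):
            return (_unbroadcast(g, self.shape) if self.requires_grad else None,
                    _unbroadcast(g, other.shape) if other.requires_grad else None)

        return Tensor(self.value + other.value, _parents=(self, other), _backward=back)

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, _parents=(self,), _backward=lambda g: (-g,))

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return (-self) + other if isinstance(other, (int, float)) \
            else as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return Tensor(self.value * other, _parents=(self,),
                          _backward=lambda g: (g * other,))
        other = as_tensor(other)

        def back(g):
            return (_unbroadcast(g * other.value, self.shape) if self.requires_grad else None,
                    _unbroadcast(g * self.value, other.shape) if other.requires_grad else None)

        return Tensor(self.value * other.value, _parents=(self, other), _backward=back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = as_tensor(other)

        def back(g):
            return (_unbroadcast(g / other.value, self.shape) if self.requires_grad else None,
                    _unbroadcast(-g * self.value / other.value ** 2, other.shape)
                    if other.requires_grad else None)

        return Tensor(self.value / other.value, _parents=(self, other), _backward=back)

    def __rtruediv__(self, other):
        if isinstance(other, (int, float)):
            return Tensor(other / self.value, _parents=(self,),
                          _backward=lambda g: (-g * other / self.value ** 2,))
        return as_tensor(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        return Tensor(self.value ** p, _parents=(self,),
                      _backward=lambda g: (g * p * self.value ** (p - 1),))

    def __matmul__(self, other):
        other = as_tensor(other)

        def back(g):
            a, b = self.value, other.value
            ga = gb = None
            if self.requires_grad:
                ga = _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)
            if other.requires_grad:
                gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)
            return ga, gb

        return Tensor(self.value @ other.value, _parents=(self, other), _backward=back)

    # -- elementwise ----------------------------------------------------------
    def exp(self):
        out_val = np.exp(self.value)
        return Tensor(out_val, _parents=(self,), _backward=lambda g: (g * out_val,))

    def log(self):
        return Tensor(np.log(self.value), _parents=(self,),
                      _backward=lambda g: (g / self.value,))

    def tanh(self):
        out_val = np.tanh(self.value)
        return Tensor(out_val, _parents=(self,),
                      _backward=lambda g: (g * (1.0 - out_val ** 2),))

    def sqrt(self):
        out_val = np.sqrt(self.value)
        return Tensor(out_val, _parents=(self,),
                      _backward=lambda g: (g * 0.5 / out_val,))

    def clamp_min(self, lo: float):
        """Lower clamp; gradient is zero where the clamp is active."""
        mask = self.value >= lo
        return Tensor(np.where(mask, self.value, lo), _parents=(self,),
                      _backward=lambda g: (g * mask,))

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def back(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return Tensor(self.value.sum(axis=axis, keepdims=keepdims),
                      _parents=(self,), _backward=back)

    def mean(self, axis=None, keepdims=False):
        n = self.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor(self.value.reshape(shape), _parents=(self,),
                      _backward=lambda g: (g.reshape(self.shape),))

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        return Tensor(self.value.transpose(axes), _parents=(self,),
                      _backward=lambda g: (g.transpose(inv),))

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        plain = not any(isinstance(i, (np.ndarray, list))
                        for i in (idx if isinstance(idx, tuple) else (idx,)))

        def back(g):
            full = np.zeros_like(self.value)
            if plain:       # slices/ints cannot alias; fast in-place add
                full[idx] += g
            else:           # fancy indexing may repeat entries
                np.add.at(full, idx, g)
            return (full,)

        return Tensor(self.value[idx], _parents=(self,), _backward=back)


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    a = np.asarray(x)
    return Tensor(a if a.dtype.kind == "f" else a.astype(float))


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.value for t in tensors], axis=axis),
                  _parents=tuple(tensors), _backward=back)


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def back(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor(np.stack([t.value for t in tensors], axis=axis),
                  _parents=tuple(tensors), _backward=back)


def logsumexp(t: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp; max subtraction uses a detached max."""
    m = np.max(t.value, axis=axis, keepdims=True)
    s = (t - Tensor(m)).exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    return s if keepdims else s.reshape(tuple(d for i, d in enumerate(t.shape) if i != axis))


def gaussian_logpdf(x, mean, var) -> Tensor:
    """Elementwise log N(x; mean, var) with analytic gradients.

    ``x`` is observed data (constant); ``mean`` and ``var`` may carry
    gradients.  Fused into one tape node because it sits on the largest
    arrays of the objective.
    """
    x = np.asarray(x.value if isinstance(x, Tensor) else x)
    mean = as_tensor(mean)
    var = as_tensor(var)
    r = x - mean.value
    v = var.value
    out = -0.5 * (np.log(2.0 * np.pi) + np.log(v) + r * r / v)

    def back(g):
        gm = _unbroadcast(g * r / v, mean.shape) if mean.requires_grad else None
        gv = (_unbroadcast(g * 0.5 * (r * r / (v * v) - 1.0 / v), var.shape)
              if var.requires_grad else None)
        return gm, gv

    return Tensor(out, _parents=(mean, var), _backward=back)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    ax = axis if axis >= 0 else t.ndim + axis
    e = (t - Tensor(np.max(t.value, axis=ax, keepdims=True))).exp()
    return e / e.sum(axis=ax, keepdims=True)


class Adam:
    """Adam optimizer over a list of leaf Tensors (maximization via -loss outside)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def reset_state(self, params):
        """Clear the moment estimates of a subset of parameters (after an
        external re-initialization of their values)."""
        ids = {id(p) for p in params}
        for i, p in enumerate(self.params):
            if id(p) in ids:
                self.m[i][...] = 0.0
                self.v[i][...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
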