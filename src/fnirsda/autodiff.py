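"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine in the micrograd style, tensorised: every
:class:`Tensor` wraps an ``ndarray``, records its parents and a closure that
scatters the upstream gradient back to them.  Broadcasting follows numpy
semantics; gradients of broadcast operands are summed back to the operand's
shape.  The engine is dtype-agnostic — whatever dtype the data carries is the
dtype the gradients carry.

Only the operations the network and its losses need are implemented: +, -, *,
/, ** (constant exponent), matmul (batched), exp, log, sigmoid, sum, mean,
reshape, transpose, fancy/basic indexing, and a gradient-reversal primitive
used for adversarial training.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "grad_reverse"]


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
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _node(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- introspection -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._wrap(other)
        out = Tensor._node(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        return Tensor._node(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        return Tensor._node(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):  # pragma: no cover - unsupported path
            raise TypeError("only constant exponents are supported")
        return Tensor._node(
            self.data**exponent,
            (self,),
            lambda g: (g * exponent * self.data ** (exponent - 1),),
        )

    def __matmul__(self, other):
        other = Tensor._wrap(other)

        def backward(g):
            ga = _unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)), self.shape)
            gb = _unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g), other.shape)
            return ga, gb

        return Tensor._node(np.matmul(self.data, other.data), (self, other), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._node(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._node(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sigmoid(self):
        from scipy.special import expit  # numerically stable logistic

        out_data = expit(self.data)
        return Tensor._node(out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gx = g
            if not keepdims:
                gx = np.expand_dims(gx, axis)
            return (np.broadcast_to(gx, self.shape).copy(),)

        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.shape[a] for a in axis]))
        else:
            n = self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._node(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(self.shape),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._node(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, key):
        key_parts = key if isinstance(key, tuple) else (key,)
        basic = all(isinstance(k, (slice, int, type(None), type(Ellipsis)))
                    for k in key_parts)

        def backward(g):
            gx = np.zeros_like(self.data)
            if basic:  # basic indexing never aliases: direct accumulation
                gx[key] += g
            else:
                np.add.at(gx, key, g)
            return (gx,)

        return Tensor._node(self.data[key], (self,), backward)

    # -- autodiff driver -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (by default with a gradient of ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
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

        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            assigned: set[int] = set()
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    # copy only when the array is (a view of) the node's own
                    # grad or was already handed to a sibling parent — a
                    # later in-place accumulation must not alias them
                    if g.dtype != parent.data.dtype:
                        g = g.astype(parent.data.dtype)
                    elif id(g) in assigned or np.may_share_memory(g, node.grad):
                        g = g.copy()
                    assigned.add(id(g))
                    parent.grad = g
                else:
                    parent.grad += g


def grad_reverse(x: Tensor, coefficient: float = 1.0) -> Tensor:
    """Identity in the forward pass; scales the gradient by ``-coefficient``.

    The standard gradient-reversal operator used to fold a domain
    discriminator's adversarial objective into a single backward pass: the
    discriminator minimises its loss on its own parameters while the upstream
    feature extractor receives the negated gradient and is pushed towards
    domain-indistinguishable features.
    """
    if coefficient < 0:
        raise ValueError(f"coefficient must be >= 0, got {coefficient}")
    x = Tensor._wrap(x)
    return Tensor._node(x.data, (x,), lambda g: (-coefficient * g,))
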