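"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A tape-based engine in the micrograd style: every operation builds a node
holding its inputs and a closure that accumulates gradients into them.
``backward()`` topologically sorts the tape and runs the closures once.

Only the operations the equivariant network and its losses need are
provided: broadcast arithmetic, matmul, row gather / segment scatter-add,
reductions, and a handful of elementwise nonlinearities. Arrays are kept
in whatever dtype they arrive in (the model defaults to float64).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concatenate", "segment_sum"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- plumbing -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = np.array(grad, dtype=float, copy=True)
        else:
            self.grad += grad

    def backward(self, seed: np.ndarray | None = None):
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self._accumulate(np.ones_like(self.data, dtype=float) if seed is None else seed)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other):
        other = tensor(other)

        def bwd(g):
            self._accum_bcast(g)
            other._accum_bcast(g)

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    def _accum_bcast(self, g):
        if self.requires_grad:
            self._accumulate(_unbroadcast(g, self.data.shape))

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum_bcast(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)

        def bwd(g):
            self._accum_bcast(g * other.data)
            other._accum_bcast(g * self.data)

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = tensor(other)

        def bwd(g):
            self._accum_bcast(g / other.data)
            other._accum_bcast(-g * self.data / other.data**2)

        return Tensor(self.data / other.data, parents=(self, other), backward=bwd)

    def __rtruediv__(self, other):
        return tensor(other) / self

    def __matmul__(self, other):
        other = tensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)

    def __pow__(self, p: float):
        def bwd(g):
            self._accum_bcast(g * p * self.data ** (p - 1))

        return Tensor(self.data**p, parents=(self,), backward=bwd)

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        def bwd(g):
            self._accumulate(g.reshape(self.data.shape))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data, dtype=float)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor(self.data[idx], parents=(self,), backward=bwd)

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bwd
        )

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- elementwise nonlinearities -----------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum_bcast(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self):
        def bwd(g):
            self._accum_bcast(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accum_bcast(g * 0.5 / out_data)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def relu(self):
        keep = self.data > 0

        def bwd(g):
            self._accum_bcast(g * keep)

        return Tensor(np.where(keep, self.data, 0.0), parents=(self,), backward=bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum_bcast(g * out_data * (1.0 - out_data))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum_bcast(g * (sig + self.data * sig * (1.0 - sig)))

        return Tensor(self.data * sig, parents=(self,), backward=bwd)

    def abs(self):
        sign = np.sign(self.data)

        def bwd(g):
            self._accum_bcast(g * sign)

        return Tensor(np.abs(self.data), parents=(self,), backward=bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accum_bcast(g * (1.0 - out_data**2))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log_softmax(self, axis=-1):
        # max-shift is a constant w.r.t. the gradient (it cancels exactly)
        shifted = self - self.data.max(axis=axis, keepdims=True)
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def tensor(x) -> Tensor:
    """Wrap ``x`` as a constant Tensor (no-op on Tensors)."""
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(parts: list, axis: int = 0) -> Tensor:
    parts = [tensor(p) for p in parts]
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            p._accum_bcast(g[tuple(sl)])

    return Tensor(
        np.concatenate([p.data for p in parts], axis=axis),
        parents=tuple(parts),
        backward=bwd,
    )


def segment_sum(values: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``values`` into ``num_segments`` buckets by ``segment_ids``."""
    values = tensor(values)
    out = np.zeros((num_segments,) + values.data.shape[1:], dtype=values.data.dtype)
    np.add.at(out, segment_ids, values.data)

    def bwd(g):
        values._accum_bcast(g[segment_ids])

    return Tensor(out, parents=(values,), backward=bwd)
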