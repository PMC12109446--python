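"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the sequence models in this package: broadcasting
elementwise arithmetic, batched matmul, slicing/reshape/transpose/concat,
the sigmoid/tanh/relu/softmax nonlinearities, reductions, and |x|.
Gradients are accumulated by a topological backward sweep, micrograd-style.
Every gradient rule here is checked against central finite differences in
the test suite.
"""

from __future__ import annotations

import contextlib

import numpy as np

#: Compute dtype for all tensors.  float32 is the working default (training
#: is memory-bandwidth bound); the finite-difference gradient tests switch
#: to float64 via :func:`default_dtype`.
DTYPE = np.float32


@contextlib.contextmanager
def default_dtype(dtype):
    """Temporarily set the tensor compute dtype (e.g. np.float64)."""
    global DTYPE
    previous = DTYPE
    DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        DTYPE = previous


GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global GRAD_ENABLED
    previous = GRAD_ENABLED
    GRAD_ENABLED = False
    try:
        yield
    finally:
        GRAD_ENABLED = previous


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        if GRAD_ENABLED:
            self.requires_grad = requires_grad or any(
                p.requires_grad for p in _parents
            )
            self._parents = _parents if self.requires_grad else ()
        else:
            self.requires_grad = requires_grad
            self._parents = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------
    def _register(self, fn) -> None:
        """Attach a backward rule only when a gradient will ever be needed."""
        if self.requires_grad:
            self._backward = fn

    def _accum(self, parent: "Tensor", grad: np.ndarray) -> None:
        if not parent.requires_grad:
            return
        if parent.grad is None:
            parent.grad = np.array(grad)  # copy: grad may alias another buffer
        else:
            parent.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
        # the graph is consumed: break closure cycles so buffers free promptly
        # (leaf .grad values survive for the optimizer)
        for t in topo:
            t._backward = None
            t._parents = ()

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        if isinstance(other, (int, float)):  # constant: no second parent
            out = Tensor(self.data + other, _parents=(self,))

            def backward():
                out._accum(self, out.grad)

            out._register(backward)
            return out
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def backward():
            out._accum(self, _unbroadcast(out.grad, self.shape))
            out._accum(other, _unbroadcast(out.grad, other.shape))

        out._register(backward)
        return out

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = Tensor(self.data * other, _parents=(self,))

            def backward():
                out._accum(self, out.grad * other)

            out._register(backward)
            return out
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def backward():
            out._accum(self, _unbroadcast(out.grad * other.data, self.shape))
            out._accum(other, _unbroadcast(out.grad * self.data, other.shape))

        out._register(backward)
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, scalar: float):
        return self * (1.0 / scalar)

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def backward():
            a, b, g = self.data, other.data, out.grad
            if b.ndim == 1:
                ga = np.expand_dims(g, -1) * b
                gb = np.tensordot(g, a, axes=(range(g.ndim), range(g.ndim)))
            elif a.ndim == 1:
                ga = (np.expand_dims(g, -2) @ np.swapaxes(b, -1, -2)).squeeze(-2)
                gb = np.expand_dims(a, -1) * np.expand_dims(g, -2)
            elif b.ndim == 2 and a.ndim > 2:
                # batched input x shared weight: contract batch dims directly
                ga = g @ b.T
                axes = tuple(range(a.ndim - 1))
                gb = np.tensordot(a, g, axes=(axes, axes))
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            out._accum(self, _unbroadcast(ga, self.shape))
            out._accum(other, _unbroadcast(gb, other.shape))

        out._register(backward)
        return out

    # -- shape ops ---------------------------------------------------------
    def __getitem__(self, key):
        out = Tensor(self.data[key], _parents=(self,))

        def backward():
            grad = np.zeros_like(self.data)
            grad[key] += out.grad
            out._accum(self, grad)

        out._register(backward)
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def backward():
            out._accum(self, out.grad.reshape(self.shape))

        out._register(backward)
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), _parents=(self,))
        inverse = np.argsort(axes)

        def backward():
            out._accum(self, out.grad.transpose(*inverse))

        out._register(backward)
        return out

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = -1) -> "Tensor":
        out = Tensor(
            np.concatenate([t.data for t in tensors], axis=axis),
            _parents=tuple(tensors),
        )
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.concatenate([[0], np.cumsum(sizes)])

        def backward():
            for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(int(start), int(stop))
                out._accum(t, out.grad[tuple(sl)])

        out._register(backward)
        return out

    def pad_axis(self, axis: int, before: int, after: int = 0) -> "Tensor":
        width = [(0, 0)] * self.data.ndim
        width[axis] = (before, after)
        out = Tensor(np.pad(self.data, width), _parents=(self,))

        def backward():
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(before, out.grad.shape[axis] - after)
            out._accum(self, out.grad[tuple(sl)])

        out._register(backward)
        return out

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))

        def backward():
            out._accum(self, out.grad * (self.data > 0))

        out._register(backward)
        return out

    def sigmoid(self):
        from scipy.special import expit  # overflow-safe logistic

        s = expit(self.data)
        out = Tensor(s, _parents=(self,))

        def backward():
            out._accum(self, out.grad * s * (1.0 - s))

        out._register(backward)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _parents=(self,))

        def backward():
            out._accum(self, out.grad * (1.0 - y * y))

        out._register(backward)
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _parents=(self,))

        def backward():
            g = out.grad
            inner = (g * s).sum(axis=axis, keepdims=True)
            out._accum(self, s * (g - inner))

        out._register(backward)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), _parents=(self,))

        def backward():
            out._accum(self, out.grad * np.sign(self.data))

        out._register(backward)
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def backward():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            out._accum(self, np.broadcast_to(g, self.shape).copy())

        out._register(backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n


def parameter(rng: np.random.Generator, *shape, scale: float | None = None) -> Tensor:
    """Glorot-style initialized trainable tensor."""
    if scale is None:
        fan_in = shape[0] if len(shape) > 1 else max(shape[0], 1)
        scale = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-scale, scale, size=shape), requires_grad=True)


def zeros(*shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)
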