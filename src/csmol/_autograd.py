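"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the package's lightweight neural-network core: a Tensor type with a
taped backward pass, the handful of ops the encoder and heads need (matmul,
broadcasting arithmetic, LeakyReLU, sigmoid, concatenation, row gather,
segment sum/mean for graph aggregation, batch normalization), Kaiming
initialization, and an AdamW optimizer. Everything runs in float64 on one
CPU; determinism follows from seeding the NumPy generators that touch it.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "Parameter", "Linear", "BatchNorm1d", "AdamW",
    "leaky_relu", "sigmoid", "concat", "gather_rows", "segment_sum",
    "segment_mean", "mse",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph bookkeeping --------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accumulate(self, grad):
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- ops ----------------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __pow__(self, exponent: float):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return self._make(self.data**exponent, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        return self._make(self.data.reshape(*shape), (self,), backward)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def leaky_relu(x: Tensor, negative_slope: float = 0.01) -> Tensor:
    mask = np.where(x.data > 0, 1.0, negative_slope)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return x._make(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out_data * (1.0 - out_data))

    return x._make(out_data, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out = tensors[0]._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward
    )
    return out


def gather_rows(x: Tensor, indices: np.ndarray) -> Tensor:
    indices = np.asarray(indices, dtype=np.int64)

    def backward(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            np.add.at(acc, indices, g)
            x._accumulate(acc)

    return x._make(x.data[indices], (x,), backward)


def segment_sum(x: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets given per-row ids."""
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    out_data = np.zeros((n_segments,) + x.data.shape[1:])
    np.add.at(out_data, segment_ids, x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g[segment_ids])

    return x._make(out_data, (x,), backward)


def segment_mean(x: Tensor, segment_ids: np.ndarray, n_segments: int) -> Tensor:
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    counts = np.bincount(segment_ids, minlength=n_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0)[:, None]
    total = segment_sum(x, segment_ids, n_segments)
    return total * Tensor(1.0 / counts)


def mse(pred: Tensor, target: np.ndarray, weights: np.ndarray | None = None) -> Tensor:
    diff = pred - Tensor(target)
    sq = diff * diff
    if weights is not None:
        sq = sq * Tensor(weights)
    return sq.mean()


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    def parameters(self) -> list[Parameter]:
        params = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name → array mapping of parameters and buffers (for checkpoints)."""
        out = {}

        def walk(obj, prefix):
            for name, value in obj.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(value, Parameter):
                    out[key] = value.data
                elif isinstance(value, Module):
                    walk(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")
                elif isinstance(value, np.ndarray):
                    out[key] = value
        walk(self, "")
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        def walk(obj, prefix):
            for name, value in obj.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(value, Parameter):
                    value.data = np.array(state[key], dtype=np.float64)
                elif isinstance(value, Module):
                    walk(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")
                elif isinstance(value, np.ndarray):
                    obj.__dict__[name] = np.array(state[key])
        walk(self, "")

    def train(self):
        self._set_mode(True)

    def eval(self):
        self._set_mode(False)

    def _set_mode(self, training: bool):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value._set_mode(training)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item._set_mode(training)
        if hasattr(self, "training"):
            self.training = training


class Linear(Module):
    """Fully connected layer, Kaiming-uniform init suited to LeakyReLU."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        gain = np.sqrt(2.0 / (1 + 0.01**2))
        bound = gain * np.sqrt(3.0 / in_dim)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Batch normalization over axis 0 with running statistics for inference."""

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training and x.data.shape[0] > 1:
            self.running_mean = (1 - self.momentum) * self.running_mean \
                + self.momentum * x.data.mean(axis=0)
            self.running_var = (1 - self.momentum) * self.running_var \
                + self.momentum * x.data.var(axis=0)
            mu = x.mean(axis=0, keepdims=True)
            xm = x - mu
            var = (xm * xm).mean(axis=0, keepdims=True)
            xhat = xm * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) * Tensor(
                1.0 / np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta


class AdamW(Module):
    """AdamW with decoupled weight decay."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= lr * (m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
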