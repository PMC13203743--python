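"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module is the deep-learning runtime for the package: a small Tensor
class with a dynamically built computation graph, the handful of
differentiable operations the EEG pipeline needs (dense and 2-D grouped
convolutions, pooling, normalisation statistics, softmax building blocks),
a Module/Parameter system, and an Adam optimizer.

Design constraints
------------------
* CPU-only, single process; all heavy lifting is delegated to BLAS through
  ``np.matmul`` (convolutions go through im2col).
* dtype follows the input arrays (float32 for training, float64 in
  gradient-check tests).
* Determinism: every source of randomness is an explicit
  ``numpy.random.Generator`` owned by the caller.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "LayerNorm",
    "Dropout",
    "Adam",
    "concat",
    "conv2d",
    "avg_pool2d",
    "softmax",
    "log_softmax",
    "cross_entropy",
    "as_tensor",
]


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _attach(out: "Tensor", fn) -> "Tensor":
    if out.requires_grad:
        out._backward = fn
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = _GRAD_ENABLED and (
            bool(requires_grad) or any(p.requires_grad for p in _parents)
        )
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- introspection ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        # take ownership without copying; accumulation allocates a fresh
        # array instead of mutating, so aliased incoming grads stay safe
        if grad.dtype != self.data.dtype:
            grad = grad.astype(self.data.dtype)
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    # -- autograd ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            interior = node._backward is not None
            if interior and node.grad is not None:
                node._backward(node.grad)
            # free interior grads (and graph closures) eagerly; leaves
            # (parameters, inputs) keep their gradient for the caller
            if interior:
                node.grad = None
                node._backward = None
                node._parents = ()

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        _attach(out, bwd)
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _parents=(self,))
        _attach(out, lambda g: self._accumulate(-g))
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        _attach(out, bwd)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        _attach(out, bwd)
        return out

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, _parents=(self,))
        _attach(out, lambda g: self._accumulate(
            g * exponent * self.data ** (exponent - 1)
        ))
        return out

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.shape))

        _attach(out, bwd)
        return out

    # -- elementwise functions --------------------------------------------
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _parents=(self,))
        _attach(out, lambda g: self._accumulate(g * out.data))
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _parents=(self,))
        _attach(out, lambda g: self._accumulate(g / self.data))
        return out

    def sqrt(self) -> "Tensor":
        out = Tensor(np.sqrt(self.data), _parents=(self,))
        _attach(out, lambda g: self._accumulate(g * 0.5 / out.data))
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0), _parents=(self,))
        _attach(out, lambda g: self._accumulate(g * mask))
        return out

    # -- shape manipulation ------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        _attach(out, lambda g: self._accumulate(g.reshape(self.shape)))
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        _attach(out, lambda g: self._accumulate(g.transpose(inv)))
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accumulate(full)

        _attach(out, bwd)
        return out

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).astype(self.dtype))

        _attach(out, bwd)
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / float(count)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
    )
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    _attach(out, bwd)
    return out


# ---------------------------------------------------------------------------
# convolution / pooling
# ---------------------------------------------------------------------------


def _pad_hw(x: np.ndarray, padding: int) -> np.ndarray:
    """Zero-pad the two trailing axes (faster than np.pad for this case)."""
    if not padding:
        return x
    b, c, h, w = x.shape
    out = np.zeros((b, c, h + 2 * padding, w + 2 * padding), dtype=x.dtype)
    out[:, :, padding : padding + h, padding : padding + w] = x
    return out


def _im2col(x: np.ndarray, k: int, stride: int, padding: int):
    """Return (cols, (Ho, Wo)) with cols of shape (B, C, k, k, Ho, Wo).

    Built with k*k strided slice copies, which beats materialising the
    6-D as_strided view in one go.
    """
    b, c, h, w = x.shape
    xp = _pad_hw(x, padding)
    hp, wp = xp.shape[2:]
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    cols = np.empty((b, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols, (ho, wo)


def _col2im(
    dcols: np.ndarray, in_shape: tuple[int, ...], k: int, stride: int, padding: int
) -> np.ndarray:
    """Inverse scatter of :func:`_im2col`; dcols is (B, C, k, k, Ho, Wo)."""
    b, c, h, w = in_shape
    ho, wo = dcols.shape[-2:]
    dx = np.zeros((b, c, h + 2 * padding, w + 2 * padding), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                dcols[:, :, i, j]
            )
    if padding:
        dx = dx[:, :, padding : padding + h, padding : padding + w]
    return dx


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """Grouped 2-D convolution (cross-correlation, as in every DL runtime)."""
    x = as_tensor(x)
    bsz, cin, _, _ = x.shape
    cout, cing, k, _ = weight.shape
    if cin != cing * groups:
        raise ValueError(
            f"conv2d: input has {cin} channels, weight expects {cing * groups}"
        )
    coutg = cout // groups
    pointwise = k == 1 and stride == 1 and padding == 0
    if pointwise:
        ho, wo = x.shape[2], x.shape[3]
        # plain channel mixing: reshape is a view, no im2col copy
        cols_g = x.data.reshape(bsz, groups, cing, ho * wo)
    else:
        cols, (ho, wo) = _im2col(x.data, k, stride, padding)
        cols_g = cols.reshape(bsz, groups, cing * k * k, ho * wo)
    w_g = weight.data.reshape(groups, coutg, cing * k * k)
    out_data = np.matmul(w_g[None], cols_g).reshape(bsz, cout, ho, wo)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(out_data, _parents=parents)
    del cols_g  # recomputed in backward; x.data stays alive via the graph

    def bwd(g):
        gg = g.reshape(bsz, groups, coutg, ho * wo)
        if pointwise:
            cols_b = x.data.reshape(bsz, groups, cing, ho * wo)
        else:
            cols_b, _ = _im2col(x.data, k, stride, padding)
            cols_b = cols_b.reshape(bsz, groups, cing * k * k, ho * wo)
        if weight.requires_grad:
            dw = np.matmul(gg, np.swapaxes(cols_b, -1, -2)).sum(axis=0)
            weight._accumulate(dw.reshape(weight.shape))
        del cols_b
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(np.swapaxes(w_g[None], -1, -2), gg)
            if pointwise:
                x._accumulate(dcols.reshape(x.shape))
            else:
                dcols = dcols.reshape(bsz, cin, k, k, ho, wo)
                x._accumulate(_col2im(dcols, x.shape, k, stride, padding))

    _attach(out, bwd)
    return out


def avg_pool2d(x: Tensor, k: int, stride: int | None = None, padding: int = 0) -> Tensor:
    x = as_tensor(x)
    stride = stride or k
    xp = _pad_hw(x.data, padding)
    hp, wp = xp.shape[2:]
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    acc = np.zeros(x.shape[:2] + (ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            acc += xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    out = Tensor(acc / (k * k), _parents=(x,))

    def bwd(g):
        b, c, h, w = x.shape
        gp = g / (k * k)
        dx = np.zeros((b, c, h + 2 * padding, w + 2 * padding), dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += gp
        if padding:
            dx = dx[:, :, padding : padding + h, padding : padding + w]
        x._accumulate(dx)

    _attach(out, bwd)
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C)."""
    return x.mean(axis=(2, 3))


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float):
    """Fused batch normalisation over (B, H, W) per channel (training mode).

    Returns (out, batch_mean, batch_var) with the standard O(1)-buffer
    backward; only the normalised activations are retained for it.
    """
    axes = (0, 2, 3)
    count = x.shape[0] * x.shape[2] * x.shape[3]
    mean = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv_std
    gshape = (1, x.shape[1], 1, 1)
    out_data = xhat * gamma.data.reshape(gshape) + beta.data.reshape(gshape)
    out = Tensor(out_data, _parents=(x, gamma, beta))

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            sum_g = g.sum(axis=axes, keepdims=True)
            sum_gx = (g * xhat).sum(axis=axes, keepdims=True)
            dx = (
                gamma.data.reshape(gshape)
                * inv_std
                * (g - sum_g / count - xhat * (sum_gx / count))
            )
            x._accumulate(dx.astype(x.dtype))

    _attach(out, bwd)
    return out, mean.reshape(-1), var.reshape(-1)


# ---------------------------------------------------------------------------
# softmax family
# ---------------------------------------------------------------------------


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``logits``."""
    labels = np.asarray(labels)
    n, c = logits.shape
    if labels.shape != (n,):
        raise ValueError("labels must be a vector matching the batch size")
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError("label outside the class range")
    onehot = np.zeros((n, c), dtype=logits.dtype)
    onehot[np.arange(n), labels] = 1.0
    logp = log_softmax(logits, axis=-1)
    return -(logp * Tensor(onehot)).sum() / float(n)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Tiny nn.Module analogue: parameter discovery + train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterable["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for mod in self.modules():
            for v in mod.__dict__.values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
        return params

    def named_state(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}

        def visit(mod: Module, prefix: str):
            for name, v in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(v, Parameter):
                    state[key] = v.data
                elif isinstance(v, np.ndarray):
                    state[key] = v
                elif isinstance(v, Module):
                    visit(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")

        visit(self, "")
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        own = self.named_state()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing keys in state: {sorted(missing)[:5]} ...")

        def visit(mod: Module, prefix: str):
            for name, v in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(v, Parameter):
                    v.data = np.asarray(state[key], dtype=v.data.dtype).reshape(v.shape)
                elif isinstance(v, np.ndarray):
                    mod.__dict__[name] = np.asarray(state[key], dtype=v.dtype).reshape(
                        v.shape
                    )
                elif isinstance(v, Module):
                    visit(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")

        visit(self, "")

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("channel counts must be divisible by groups")
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        self.weight = Parameter(
            _kaiming(
                rng,
                (out_channels, in_channels // groups, kernel_size, kernel_size),
                fan_in,
            )
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(
            x,
            self.weight,
            self.bias,
            stride=self.stride,
            padding=self.padding,
            groups=self.groups,
        )


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(num_features, dtype=np.float32))
        self.beta = Parameter(np.zeros(num_features, dtype=np.float32))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            out, mean, var = batch_norm_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                np.float32
            )
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
            return out
        scale = (self.gamma.data / np.sqrt(self.running_var + self.eps)).reshape(
            1, c, 1, 1
        )
        shift = (self.beta.data - self.running_mean * scale.reshape(c)).reshape(
            1, c, 1, 1
        )
        # eval mode: affine transform with the running statistics; gradients
        # (if any) flow to x only, matching frozen-statistics fine-tuning
        return x * Tensor(scale) + Tensor(shift)


class LayerNorm(Module):
    """Normalisation over the last axis (token features)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        var = ((x - mean) ** 2).mean(axis=-1, keepdims=True)
        return (x - mean) / (var + self.eps).sqrt() * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)


class Adam:
    """Adam (Kingma & Ba) with the standard bias correction."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
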