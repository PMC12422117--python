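"""Minimal reverse-mode tensor autodiff on numpy arrays.

Supports exactly the operations the breath classifier needs: broadcasting
arithmetic, matmul, 1-D convolution, ReLU/sigmoid/exp/log/pow/sqrt,
reductions, reshape/transpose and softmax — each with an analytic backward
pass.  Float64 throughout; correctness is pinned by central-difference
gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "conv1d", "softmax", "concatenate", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum grad over axes that were broadcast to reach ``grad.shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, _parents=(), name: str = ""):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents
        self._backward = None
        self.name = name

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                if exponent == 0:
                    grad = np.zeros_like(self.data)
                else:
                    grad = exponent * self.data ** (exponent - 1.0) * g
                self._accumulate(grad)

        out._backward = backward
        return out

    def sqrt(self):
        return self.pow(0.5)

    def matmul(self, other: "Tensor"):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def backward(g):
            if self.requires_grad:
                grad = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(grad, self.data.shape))
            if other.requires_grad:
                grad = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(grad, other.data.shape))

        out._backward = backward
        return out

    __matmul__ = matmul

    # -- elementwise nonlinearities ---------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward = backward
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._backward = backward
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * e)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = backward
        return out

    def clip(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                mask = (self.data >= lo) & (self.data <= hi)
                self._accumulate(g * mask)

        out._backward = backward
        return out

    # -- reductions & shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                grad = np.asarray(g)
                if axis is not None and not keepdims:
                    grad = np.expand_dims(grad, axis)
                self._accumulate(np.broadcast_to(grad, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = backward
        return out

    def transpose(self, axes):
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        inverse = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inverse))

        out._backward = backward
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _parents=(self,))

        def backward(g):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, key, g)
                self._accumulate(grad)

        out._backward = backward
        return out


def tensor(data, requires_grad: bool = False, name: str = "") -> Tensor:
    return Tensor(data, requires_grad=requires_grad, name=name)


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]

    def backward(g):
        start = 0
        for t, size in zip(tensors, sizes):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(start, start + size)
                t._accumulate(g[tuple(idx)])
            start += size

    out._backward = backward
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: str = "same") -> Tensor:
    """Cross-correlation of x (B, C_in, L) with kernels w (C_out, C_in, K).

    'same' pads symmetrically so the output length equals L; 'valid' gives
    L - K + 1 (K must fit).
    """
    B, C_in, L = x.data.shape
    C_out, C_in_w, K = w.data.shape
    if C_in != C_in_w:
        raise ValueError(f"conv1d: input has {C_in} channels, kernel expects {C_in_w}")
    if padding == "same":
        pad_left = (K - 1) // 2
        pad_right = K - 1 - pad_left
    elif padding == "valid":
        if K > L:
            raise ValueError(f"conv1d: kernel size {K} exceeds input length {L}")
        pad_left = pad_right = 0
    else:
        raise ValueError(f"unknown padding {padding!r}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad_left, pad_right)))
    L_out = xp.shape[2] - K + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # B,Cin,Lout,K
    y = np.einsum("bclk,ock->bol", windows, w.data, optimize=True)
    if b is not None:
        y = y + b.data[None, :, None]
    parents = (x, w) + ((b,) if b is not None else ())
    out = Tensor(y, _parents=parents)

    def backward(g):
        if w.requires_grad:
            gw = np.einsum("bclk,bol->ock", windows, g, optimize=True)
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, :, k : k + L_out] += np.einsum(
                    "bol,oc->bcl", g, w.data[:, :, k], optimize=True
                )
            gx = gxp[:, :, pad_left : pad_left + L] if pad_left or pad_right else gxp
            x._accumulate(gx)

    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax composed from primitive ops."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, no grad path
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adaptive moment estimation over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
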