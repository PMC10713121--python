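"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the primitives the correlation encoder needs: broadcasted
arithmetic, matmul (including stacked/batched), reshape/transpose, slicing,
padding, reductions, elementwise nonlinearities and a fused softmax. Gradients
are accumulated by a topological backward sweep; correctness is guarded by
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    """A numpy array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = as_tensor(other)
        out_data = self.data - other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)

        return Tensor._make(out_data, (self, other), backward)

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._make(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data
        a, b = self.data, other.data

        def backward(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor._make(out_data, (self, other), backward)

    def square(self):
        return self * self

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            return (g * 0.5 / out_data,)

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def abs(self):
        sign = np.sign(self.data)
        return Tensor._make(np.abs(self.data), (self,), lambda g: (g * sign,))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(
            np.where(mask, self.data, 0.0), (self,), lambda g: (g * mask,)
        )

    def prelu(self, slope: "Tensor"):
        """Parametric ReLU: x if x > 0 else slope * x (slope is learned)."""
        x = self.data
        neg = np.minimum(x, 0.0)
        out_data = np.maximum(x, 0.0) + slope.data * neg
        pos_mask = x > 0

        def backward(g):
            gx = g * np.where(pos_mask, 1.0, slope.data)
            gs = _unbroadcast(g * neg, slope.shape)
            return gx, gs

        return Tensor._make(out_data, (self, slope), backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalize the last axis to zero mean / unit variance, then affine."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out_data = xhat * gamma.data + beta.data
        d = x.shape[-1]

        def backward(g):
            ggamma = _unbroadcast(g * xhat, gamma.shape)
            gbeta = _unbroadcast(g, beta.shape)
            gh = g * gamma.data
            # standard layer-norm input gradient
            gx = inv / d * (d * gh - gh.sum(axis=-1, keepdims=True)
                            - xhat * (gh * xhat).sum(axis=-1, keepdims=True))
            return gx, ggamma, gbeta

        return Tensor._make(out_data, (self, gamma, beta), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            gk = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gk, shape).copy(),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def swapaxes(self, a, b):
        return Tensor._make(
            np.swapaxes(self.data, a, b), (self,), lambda g: (np.swapaxes(g, a, b),)
        )

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.shape
        # basic slicing yields disjoint cells: direct accumulation is enough
        basic = isinstance(idx, (int, slice)) or (
            isinstance(idx, tuple) and all(isinstance(i, (int, slice)) for i in idx)
        )

        def backward(g):
            gx = np.zeros(shape)
            if basic:
                gx[idx] += g
            else:
                np.add.at(gx, idx, g)
            return (gx,)

        return Tensor._make(out_data, (self,), backward)

    def pad_last(self, before: int, after: int):
        """Zero-pad the last axis (used for 'same' convolutions)."""
        width = [(0, 0)] * (self.ndim - 1) + [(before, after)]
        out_data = np.pad(self.data, width)
        n = self.shape[-1]

        def backward(g):
            return (g[..., before : before + n],)

        return Tensor._make(out_data, (self,), backward)

    # -- fused ops -----------------------------------------------------------
    def softmax(self):
        """Softmax over the last axis, numerically stabilised."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            return (s * (g - (g * s).sum(axis=-1, keepdims=True)),)

        return Tensor._make(s, (self,), backward)

    # -- autodiff driver -----------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed recursion depth
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.array(g, dtype=np.float64)  # defensive copy
                else:
                    parent.grad += g

    def zero_grad(self):
        self.grad = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def conv1d_same(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """'Same'-padded 1-D convolution in channels-last layout.

    ``x`` is (n, l, C), ``W`` is (kw, C, Co), ``b`` is (Co,); returns
    (n, l, Co). Fused primitive: im2col + one GEMM forward, GEMM +
    shift-accumulate backward — far cheaper than composing the convolution
    node by node.
    """
    n, l, C = x.data.shape
    kw, _, Co = W.data.shape
    left = (kw - 1) // 2
    xp = np.pad(x.data, ((0, 0), (left, kw - 1 - left), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, kw, axis=1)  # (n,l,C,kw)
    col = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(n * l, kw * C)
    Wm = W.data.reshape(kw * C, Co)
    out_data = (col @ Wm + b.data).reshape(n, l, Co)

    def backward(g):
        gm = g.reshape(n * l, Co)
        gW = (col.T @ gm).reshape(kw, C, Co)
        gb = gm.sum(axis=0)
        gcol = (gm @ Wm.T).reshape(n, l, kw, C)
        gxp = np.zeros_like(xp)
        for j in range(kw):
            gxp[:, j : j + l, :] += gcol[:, :, j, :]
        return gxp[:, left : left + l, :], gW, gb

    return Tensor._make(out_data, (x, W, b), backward)


class Adam:
    """Adaptive-moment gradient optimizer with the standard defaults.

    Moments are kept in one flat vector so the update is a handful of
    vectorised operations regardless of how many parameter tensors exist.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        sizes = [p.data.size for p in self.params]
        self._offsets = np.concatenate([[0], np.cumsum(sizes)])
        total = int(self._offsets[-1])
        self.m = np.zeros(total)
        self.v = np.zeros(total)

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        g = np.concatenate([
            (p.grad if p.grad is not None else np.zeros_like(p.data)).ravel()
            for p in self.params
        ])
        self.m = b1 * self.m + (1 - b1) * g
        self.v = b2 * self.v + (1 - b2) * g * g
        upd = (self.lr / (1 - b1**self.t)) * self.m / (
            np.sqrt(self.v / (1 - b2**self.t)) + self.eps)
        for i, p in enumerate(self.params):
            sl = slice(self._offsets[i], self._offsets[i + 1])
            p.data -= upd[sl].reshape(p.data.shape)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
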