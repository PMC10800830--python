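"""A small reverse-mode automatic differentiation engine on numpy arrays.

Implements exactly the operations the segmentation network needs: broadcast
arithmetic, matmul, reshape/transpose/concat, activations (ReLU, GELU,
sigmoid), softmax, stride-1 2-D convolution and 2x2/stride-2 transposed
convolution. Gradients are accumulated into ``Tensor.grad`` by
:meth:`Tensor.backward`; every op is verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True

# Engine dtype: float32 keeps CPU training fast; tests that verify gradients
# against finite differences switch to float64 for headroom.
DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global DTYPE
    if np.dtype(dtype) not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    DTYPE = np.dtype(dtype).type


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar output")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(
            p.requires_grad or p._parents for p in parents
        ):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g):
            self._accumulate(g * e * self.data ** (e - 1.0))

        return self._make(self.data**e, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, self.shape))
            other._accumulate(_unbroadcast(gb, other.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    # -- reductions & shaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            self._accumulate(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def concat(self, others: list["Tensor"], axis: int = -1):
        parts = [self] + [self._lift(o) for o in others]
        sizes = [p.shape[axis] for p in parts]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            for p, gp in zip(parts, np.split(g, splits, axis=axis)):
                p._accumulate(gp)

        return self._make(
            np.concatenate([p.data for p in parts], axis=axis), tuple(parts), backward
        )

    # -- activations -------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._accumulate(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def gelu(self):
        """Exact GELU: x * Phi(x) with the Gaussian CDF."""
        from scipy.special import erf

        x = self.data
        phi = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))

        def backward(g):
            self._accumulate(g * (cdf + x * phi))

        return self._make(x * cdf, (self,), backward)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            inner = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - inner))

        return self._make(s, (self,), backward)

    # -- convolutions ------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None, padding: int = 0):
        """Stride-1 2-D convolution (cross-correlation), NCHW layout.

        ``weight`` has shape (O, C, kh, kw); ``padding`` is symmetric zero
        padding on both spatial axes.
        """
        weight = self._lift(weight)
        x = self.data
        n, c, h, w = x.shape
        o, c2, kh, kw = weight.shape
        if c != c2:
            raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
        if padding:
            xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        else:
            xp = x
        ho, wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # n,c,ho,wo,kh,kw
        # single im2col copy, then one BLAS GEMM
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * kh * kw
        )
        wmat = weight.data.reshape(o, c * kh * kw)
        out = (cols @ wmat.T).reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
        if bias is not None:
            bias = self._lift(bias)
            out = out + bias.data.reshape(1, o, 1, 1)

        parents = (self, weight) if bias is None else (self, weight, bias)

        def backward(g):
            gout = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, o)
            weight._accumulate((gout.T @ cols).reshape(weight.shape))
            if bias is not None:
                bias._accumulate(gout.sum(axis=0))
            gcols = (gout @ wmat).reshape(n, ho, wo, c, kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + ho, j : j + wo] += gcols[:, :, :, :, i, j].transpose(
                        0, 3, 1, 2
                    )
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            self._accumulate(gxp)

        return self._make(out, parents, backward)

    def conv_transpose2d_2x2(self, weight: "Tensor", bias: "Tensor | None" = None):
        """2x2, stride-2 transposed convolution (exact 2x upsampling).

        ``weight`` has shape (C, O, 2, 2): ``out[n,o,2h+k,2w+l] =
        sum_c x[n,c,h,w] * W[c,o,k,l]``.
        """
        weight = self._lift(weight)
        x = self.data
        n, c, h, w = x.shape
        c2, o, kh, kw = weight.shape
        if c != c2 or kh != 2 or kw != 2:
            raise ValueError("conv_transpose2d_2x2 needs weight of shape (C, O, 2, 2)")
        xmat = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(n * h * w, c)
        wmat = weight.data.reshape(c, o * 4)
        t = (xmat @ wmat).reshape(n, h, w, o, 2, 2)  # n,h,w,o,k,l
        out = np.ascontiguousarray(t.transpose(0, 3, 1, 4, 2, 5)).reshape(
            n, o, 2 * h, 2 * w
        )
        if bias is not None:
            bias = self._lift(bias)
            out = out + bias.data.reshape(1, o, 1, 1)
        parents = (self, weight) if bias is None else (self, weight, bias)

        def backward(g):
            gt = np.ascontiguousarray(
                g.reshape(n, o, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
            ).reshape(n * h * w, o * 4)  # rows align with xmat
            gx = (gt @ wmat.T).reshape(n, h, w, c).transpose(0, 3, 1, 2)
            weight._accumulate((xmat.T @ gt).reshape(weight.shape))
            self._accumulate(gx)
            if bias is not None:
                bias._accumulate(g.sum(axis=(0, 2, 3)))

        return self._make(out, parents, backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    return tensors[0].concat(tensors[1:], axis=axis)
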