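"""A minimal reverse-mode automatic differentiation engine on numpy arrays.

This is the computational substrate for the transformer segmenter: a
:class:`Tensor` wraps a float32 ``numpy`` array and records the operations
applied to it; :meth:`Tensor.backward` walks the recorded graph in reverse
topological order and accumulates gradients.  Only the primitives the model
needs are provided (broadcast arithmetic, batched matmul, reshape/transpose/
slice/concat/roll, exp/log/tanh/gelu, reductions, softmax, layer norm and a
dilated "same" 3D convolution); each primitive carries a hand-written
backward rule and is covered by numerical gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv3d_same"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name", "_grad_owned")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None
        self.name = name
        self._grad_owned = False

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        t = Tensor(data)
        if any(p.requires_grad for p in parents):
            t.requires_grad = True
            t._parents = tuple(parents)
            t._backward = backward
        return t

    def _accum(self, g: np.ndarray) -> None:
        # copy-on-write: keep the incoming array by reference on first
        # accumulation (it may be shared with another node's gradient) and
        # materialise an owned buffer only if a second contribution arrives
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
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
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float32)
        )
        self._grad_owned = True
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._parents = ()   # release the graph as we go
                node._backward = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor._node(out_data, (self, other), backward)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._node(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return Tensor._node(out_data, (self, other), backward)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src_shape = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(src_shape))

        return Tensor._node(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(np.transpose(g, inv))

        return Tensor._node(np.ascontiguousarray(np.transpose(self.data, axes)), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accum(full)

        return Tensor._node(out_data.copy(), (self,), backward)

    def roll(self, shifts, axes):
        def backward(g):
            if self.requires_grad:
                self._accum(np.roll(g, tuple(-s for s in shifts), axis=axes))

        return Tensor._node(np.roll(self.data, shifts, axis=axes), (self,), backward)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._node(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._node(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1 - out_data**2))

        return Tensor._node(out_data, (self,), backward)

    def gelu(self):
        """GELU with the tanh approximation."""
        c = np.float32(np.sqrt(2.0 / np.pi))
        a = np.float32(0.044715)
        x = self.data
        x2 = x * x
        inner = x2 * a
        inner += 1.0
        inner *= x
        inner *= c
        t = np.tanh(inner)
        out_data = 1.0 + t
        out_data *= x
        out_data *= np.float32(0.5)

        def backward(g):
            if self.requires_grad:
                dinner = x2 * np.float32(3 * 0.044715)
                dinner += 1.0
                dinner *= c
                sech2 = 1.0 - t * t
                sech2 *= dinner
                sech2 *= x
                sech2 += 1.0 + t
                sech2 *= np.float32(0.5)
                sech2 *= g
                self._accum(sech2)

        return Tensor._node(out_data, (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).astype(np.float32))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).astype(np.float32))

        return Tensor._node(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- fused primitives --------------------------------------------------
    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - dot))

        return Tensor._node(out_data, (self,), backward)

    def layernorm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Layer normalisation over the last axis with learned scale/offset."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out_data = gamma.data * xhat + beta.data

        def backward(g):
            if gamma.requires_grad:
                gamma._accum(
                    (g * xhat).sum(axis=tuple(range(g.ndim - 1))).astype(np.float32)
                )
            if beta.requires_grad:
                beta._accum(g.sum(axis=tuple(range(g.ndim - 1))).astype(np.float32))
            if self.requires_grad:
                n = x.shape[-1]
                gx = g * gamma.data
                term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(
                    axis=-1, keepdims=True
                )
                self._accum((term * inv).astype(np.float32))

        return Tensor._node(out_data, (self, gamma, beta), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor._node(out_data, tuple(tensors), backward)


def _shift_slices(k: int, d: int, pad: int, size: int):
    """Slice of the padded array aligned with kernel tap k at dilation d."""
    start = k * d
    return slice(start, start + size)


def conv3d_same(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """'Same'-padded 3D convolution (cross-correlation) with isotropic dilation.

    ``x`` is (B, C_in, D, H, W), ``w`` is (C_out, C_in, kz, ky, kx) with odd
    kernel sizes.  Implemented as a sum of shifted einsums over the zero-
    padded input, which keeps both directions of the gradient exact and
    vectorised.
    """
    x = Tensor._wrap(x)
    w = Tensor._wrap(w)
    B, Cin, D, H, W = x.shape
    Cout, Cin_w, kz, ky, kx = w.shape
    if Cin != Cin_w:
        raise ValueError(f"input channels {Cin} != weight channels {Cin_w}")
    if kz % 2 == 0 or ky % 2 == 0 or kx % 2 == 0:
        raise ValueError("kernel sizes must be odd for 'same' padding")
    pz, py, px = dilation * (kz // 2), dilation * (ky // 2), dilation * (kx // 2)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pz, pz), (py, py), (px, px)))
    out_data = np.zeros((B, Cout, D, H, W), dtype=np.float32)
    for iz in range(kz):
        for iy in range(ky):
            for ix in range(kx):
                sl = xp[
                    :, :,
                    _shift_slices(iz, dilation, pz, D),
                    _shift_slices(iy, dilation, py, H),
                    _shift_slices(ix, dilation, px, W),
                ]
                out_data += np.einsum(
                    "bcdhw,oc->bodhw", sl, w.data[:, :, iz, iy, ix], optimize=True
                )
    if b is not None:
        out_data += b.data.reshape(1, Cout, 1, 1, 1)

    def backward(g):
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for iz in range(kz):
                for iy in range(ky):
                    for ix in range(kx):
                        gxp[
                            :, :,
                            _shift_slices(iz, dilation, pz, D),
                            _shift_slices(iy, dilation, py, H),
                            _shift_slices(ix, dilation, px, W),
                        ] += np.einsum(
                            "bodhw,oc->bcdhw", g, w.data[:, :, iz, iy, ix], optimize=True
                        )
            x._accum(gxp[:, :, pz:pz + D, py:py + H, px:px + W])
        if w.requires_grad:
            gw = np.zeros_like(w.data)
            for iz in range(kz):
                for iy in range(ky):
                    for ix in range(kx):
                        sl = xp[
                            :, :,
                            _shift_slices(iz, dilation, pz, D),
                            _shift_slices(iy, dilation, py, H),
                            _shift_slices(ix, dilation, px, W),
                        ]
                        gw[:, :, iz, iy, ix] = np.einsum(
                            "bodhw,bcdhw->oc", g, sl, optimize=True
                        )

            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._node(out_data, parents, backward)
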