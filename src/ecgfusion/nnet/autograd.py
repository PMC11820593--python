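"""Reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records, for each produced
tensor, its parents together with closures that map the output gradient
to parent-gradient contributions. ``backward()`` runs a topological
sweep. Convolutions use ``sliding_window_view`` (im2col) with einsum
contractions; their backward passes scatter-add column gradients back
through strided slices.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "cross_entropy"]

Array = np.ndarray
GradFn = Callable[[Array], Array]


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data: Array = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad
        self._parents: list[tuple["Tensor", GradFn]] = []

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data: Array, parents: Sequence[tuple["Tensor", GradFn]]) -> "Tensor":
        out = Tensor(data)
        out._parents = [(p, fn) for p, fn in parents]
        out.requires_grad = any(p.requires_grad or p._parents for p, _ in out._parents)
        return out

    def backward(self, grad: Array | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p, _ in node._parents:
                    stack.append((p, False))

        visit(self)
        grads: dict[int, Array] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:
                node.grad = g if node.grad is None else node.grad + g
            for parent, fn in node._parents:
                contrib = fn(g)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + contrib
                else:
                    grads[key] = contrib

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- elementwise / arithmetic -----------------------------------------

    def __add__(self, other) -> "Tensor":
        o = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data + o.data
        return Tensor._make(
            data,
            [
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (o, lambda g: _unbroadcast(g, o.data.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other) -> "Tensor":
        o = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-o)

    def __mul__(self, other) -> "Tensor":
        o = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data * o.data
        return Tensor._make(
            data,
            [
                (self, lambda g: _unbroadcast(g * o.data, self.data.shape)),
                (o, lambda g: _unbroadcast(g * self.data, o.data.shape)),
            ],
        )

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        """2-D matrix product (B, n) @ (n, m)."""
        data = self.data @ other.data
        return Tensor._make(
            data,
            [
                (self, lambda g: g @ other.data.T),
                (other, lambda g: self.data.T @ g),
            ],
        )

    __matmul__ = matmul

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._make(self.data * mask, [(self, lambda g: g * mask)])

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        return Tensor._make(s, [(self, lambda g: g * s * (1.0 - s))])

    # -- reductions / shaping ---------------------------------------------

    def mean(self, axis: int, keepdims: bool = False) -> "Tensor":
        data = self.data.mean(axis=axis, keepdims=keepdims)
        n = self.data.shape[axis]
        shape = self.data.shape

        def back(g: Array) -> Array:
            if not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g / n, shape).copy()

        return Tensor._make(data, [(self, back)])

    def amax(self, axis: int, keepdims: bool = False) -> "Tensor":
        data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == data  # ties share the gradient
        counts = mask.sum(axis=axis, keepdims=True)

        def back(g: Array) -> Array:
            if not keepdims:
                g = np.expand_dims(g, axis)
            return mask * (g / counts)

        return Tensor._make(data if keepdims else data.squeeze(axis), [(self, back)])

    def sum(self) -> "Tensor":
        shape = self.data.shape
        return Tensor._make(
            np.asarray(self.data.sum()),
            [(self, lambda g: np.broadcast_to(g, shape).copy())],
        )

    def reshape(self, *shape: int) -> "Tensor":
        orig = self.data.shape
        return Tensor._make(
            self.data.reshape(*shape), [(self, lambda g: g.reshape(orig))]
        )

    # -- convolutions ------------------------------------------------------

    def conv1d(self, weight: "Tensor", bias: "Tensor" | None, stride: int, pad: int) -> "Tensor":
        """x (B,C,L) * weight (O,C,K) -> (B,O,Lo)."""
        x = self.data
        if pad:
            xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        else:
            xp = x
        k = weight.data.shape[2]
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)[:, :, ::stride]
        out = np.einsum("bclk,ock->bol", cols, weight.data, optimize=True)
        if bias is not None:
            out = out + bias.data[None, :, None]
        lo = cols.shape[2]

        def back_x(g: Array) -> Array:
            gcols = np.einsum("bol,ock->bclk", g, weight.data, optimize=True)
            gxp = np.zeros_like(xp)
            for kk in range(k):
                gxp[:, :, kk : kk + lo * stride : stride] += gcols[:, :, :, kk]
            return gxp[:, :, pad : xp.shape[2] - pad] if pad else gxp

        def back_w(g: Array) -> Array:
            return np.einsum("bol,bclk->ock", g, cols, optimize=True)

        parents: list[tuple[Tensor, GradFn]] = [(self, back_x), (weight, back_w)]
        if bias is not None:
            parents.append((bias, lambda g: g.sum(axis=(0, 2))))
        return Tensor._make(out, parents)

    def conv2d(self, weight: "Tensor", bias: "Tensor" | None, stride: int, pad: int) -> "Tensor":
        """x (B,C,H,W) * weight (O,C,Kh,Kw) -> (B,O,Ho,Wo)."""
        x = self.data
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
        kh, kw = weight.data.shape[2:]
        cols = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))[
            :, :, ::stride, ::stride
        ]
        out = np.einsum("bchwij,ocij->bohw", cols, weight.data, optimize=True)
        if bias is not None:
            out = out + bias.data[None, :, None, None]
        ho, wo = cols.shape[2], cols.shape[3]

        def back_x(g: Array) -> Array:
            gcols = np.einsum("bohw,ocij->bchwij", g, weight.data, optimize=True)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[
                        :, :, i : i + ho * stride : stride, j : j + wo * stride : stride
                    ] += gcols[:, :, :, :, i, j]
            if pad:
                return gxp[:, :, pad : xp.shape[2] - pad, pad : xp.shape[3] - pad]
            return gxp

        def back_w(g: Array) -> Array:
            return np.einsum("bohw,bchwij->ocij", g, cols, optimize=True)

        parents: list[tuple[Tensor, GradFn]] = [(self, back_x), (weight, back_w)]
        if bias is not None:
            parents.append((bias, lambda g: g.sum(axis=(0, 2, 3))))
        return Tensor._make(out, parents)

    # -- pooling -----------------------------------------------------------

    def maxpool1d(self, kernel: int, stride: int, pad: int = 0) -> "Tensor":
        x = self.data
        xp = (
            np.pad(x, ((0, 0), (0, 0), (pad, pad)), constant_values=-np.inf)
            if pad
            else x
        )
        win = np.lib.stride_tricks.sliding_window_view(xp, kernel, axis=2)[:, :, ::stride]
        out = win.max(axis=-1)
        arg = win.argmax(axis=-1)
        lo = win.shape[2]

        def back(g: Array) -> Array:
            gxp = np.zeros(xp.shape)
            for kk in range(kernel):
                mask = arg == kk
                gxp[:, :, kk : kk + lo * stride : stride] += g * mask
            return gxp[:, :, pad : xp.shape[2] - pad] if pad else gxp

        return Tensor._make(out, [(self, back)])

    def maxpool2d(self, kernel: int, stride: int) -> "Tensor":
        x = self.data
        win = np.lib.stride_tricks.sliding_window_view(x, (kernel, kernel), axis=(2, 3))[
            :, :, ::stride, ::stride
        ]
        b, c, ho, wo = win.shape[:4]
        flat = win.reshape(b, c, ho, wo, kernel * kernel)
        out = flat.max(axis=-1)
        arg = flat.argmax(axis=-1)

        def back(g: Array) -> Array:
            gx = np.zeros(x.shape)
            for kk in range(kernel * kernel):
                i, j = divmod(kk, kernel)
                mask = arg == kk
                gx[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                    g * mask
                )
            return gx

        return Tensor._make(out, [(self, back)])

    def adaptive_maxpool2d(self, out_hw: tuple[int, int]) -> "Tensor":
        """Grid max pooling to (oh, ow): cell (i,j) covers rows
        [floor(iH/oh), ceil((i+1)H/oh)) and the analogous columns."""
        x = self.data
        b, c, h, w = x.shape
        oh, ow = out_hw
        out = np.empty((b, c, oh, ow))
        regions: list[tuple[int, int, int, int]] = []
        args: list[Array] = []
        for i in range(oh):
            r0, r1 = (i * h) // oh, -(-((i + 1) * h) // oh)
            for j in range(ow):
                c0, c1 = (j * w) // ow, -(-((j + 1) * w) // ow)
                cell = x[:, :, r0:r1, c0:c1].reshape(b, c, -1)
                out[:, :, i, j] = cell.max(axis=-1)
                args.append(cell.argmax(axis=-1))
                regions.append((r0, r1, c0, c1))

        def back(g: Array) -> Array:
            gx = np.zeros(x.shape)
            bi, ci = np.meshgrid(np.arange(b), np.arange(c), indexing="ij")
            for idx, (r0, r1, c0, c1) in enumerate(regions):
                i, j = divmod(idx, ow)
                width = c1 - c0
                rr = r0 + args[idx] // width
                cc = c0 + args[idx] % width
                np.add.at(gx, (bi, ci, rr, cc), g[:, :, i, j])
            return gx

        return Tensor._make(out, [(self, back)])

    # -- regularization ----------------------------------------------------

    def dropout(self, p: float, rng: np.random.Generator, training: bool) -> "Tensor":
        if not training or p == 0.0:
            return self
        mask = (rng.random(self.data.shape) >= p) / (1.0 - p)
        return Tensor._make(self.data * mask, [(self, lambda g: g * mask)])


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = list(tensors)
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def make_back(k: int) -> GradFn:
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(int(offsets[k]), int(offsets[k + 1]))
        return lambda g: g[tuple(sl)]

    return Tensor._make(data, [(t, make_back(k)) for k, t in enumerate(ts)])


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` are integer class ids."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    loss = -np.mean(np.log(probs[np.arange(n), labels] + 1e-300))

    def back(g: Array) -> Array:
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        return g * grad / n

    return Tensor._make(np.asarray(loss), [(logits, back)])
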