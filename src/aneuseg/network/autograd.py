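"""Minimal reverse-mode automatic differentiation for the segmentation network.

Implements exactly the operations the dual-pathway CNN needs — valid 3D
convolution, 1×1×1 convolution, batch normalization, PReLU, residual adds,
center/offset cropping, channel padding, nearest-neighbour upsampling,
concatenation, two-class softmax and soft-Dice loss — on numpy arrays, with
a tape of backward closures released by topological sort.

Array layout is ``(N, C, X, Y, Z)`` throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in self.parents)

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Reverse-accumulate gradients from this (scalar) node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
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
            for p in node.parents:
                stack.append((p, False))
        self.accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- primitive ops ----------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        assert self.shape == other.shape, f"add shape mismatch {self.shape} vs {other.shape}"

        def bwd(g):
            self.accumulate(g)
            other.accumulate(g)

        return Tensor(self.data + other.data, (self, other), bwd)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


# ---------------------------------------------------------------------------
# convolution


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, X, Y, Z) -> view (N, X', Y', Z', C, k, k, k)."""
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    return windows.transpose(0, 2, 3, 4, 1, 5, 6, 7)


def conv3d(x: Tensor, w: Parameter, b: Parameter) -> Tensor:
    """Valid (unpadded) 3D convolution; ``w`` is (F, C, k, k, k), ``b`` is (F,)."""
    n, c, *_ = x.shape
    f, c_w, k, _, _ = w.shape
    assert c == c_w, f"conv3d channel mismatch: input {c}, kernel {c_w}"
    if k == 1:
        out = np.tensordot(w.data[:, :, 0, 0, 0], x.data, axes=(1, 1)).transpose(1, 0, 2, 3, 4)
        out += b.data[None, :, None, None, None]

        def bwd1(g):
            w.accumulate(
                np.tensordot(g, x.data, axes=((0, 2, 3, 4), (0, 2, 3, 4)))[..., None, None, None]
            )
            b.accumulate(g.sum(axis=(0, 2, 3, 4)))
            if x.requires_grad:
                x.accumulate(
                    np.tensordot(w.data[:, :, 0, 0, 0], g, axes=(0, 1)).transpose(1, 0, 2, 3, 4)
                )

        return Tensor(out, (x, w, b), bwd1)

    cols = _im2col(x.data, k)  # (N, X', Y', Z', C, k, k, k) strided view
    out = np.einsum("nxyzcijk,fcijk->nfxyz", cols, w.data, optimize=True)
    out += b.data[None, :, None, None, None]

    def bwd(g):
        w.accumulate(np.einsum("nxyzcijk,nfxyz->fcijk", cols, g, optimize=True))
        b.accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            pad = k - 1
            gp = np.pad(g, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
            gcols = _im2col(gp, k)
            w_flip = w.data[:, :, ::-1, ::-1, ::-1]
            x.accumulate(
                np.einsum("nxyzfijk,fcijk->ncxyz", gcols, w_flip, optimize=True)
            )

    return Tensor(out, (x, w, b), bwd)


# ---------------------------------------------------------------------------
# normalization / activation


def batchnorm(
    x: Tensor,
    gamma: Parameter,
    beta: Parameter,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, spatial). Running stats are
    updated in place during training and used verbatim at inference."""
    axes = (0, 2, 3, 4)
    gview = lambda a: a[None, :, None, None, None]  # noqa: E731
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - gview(mu)) * gview(inv)
        out = gview(gamma.data) * xhat + gview(beta.data)
        m = x.data.size / x.data.shape[1]

        def bwd(g):
            gamma.accumulate(np.sum(g * xhat, axis=axes))
            beta.accumulate(np.sum(g, axis=axes))
            if x.requires_grad:
                dxhat = g * gview(gamma.data)
                t1 = dxhat - gview(dxhat.mean(axis=axes))
                t2 = xhat * gview(np.mean(dxhat * xhat, axis=axes))
                x.accumulate(gview(inv) * (t1 - t2))
            _ = m  # keep closure explicit

        return Tensor(out, (x, gamma, beta), bwd)

    inv = 1.0 / np.sqrt(running_var + eps)
    xhat = (x.data - gview(running_mean)) * gview(inv)
    out = gview(gamma.data) * xhat + gview(beta.data)

    def bwd_eval(g):
        gamma.accumulate(np.sum(g * xhat, axis=axes))
        beta.accumulate(np.sum(g, axis=axes))
        if x.requires_grad:
            x.accumulate(g * gview(gamma.data * inv))

    return Tensor(out, (x, gamma, beta), bwd_eval)


def prelu(x: Tensor, a: Parameter) -> Tensor:
    """Parametric rectified linear unit with a per-channel negative slope."""
    av = a.data[None, :, None, None, None]
    pos = x.data > 0
    out = np.where(pos, x.data, av * x.data)

    def bwd(g):
        a.accumulate(np.sum(np.where(pos, 0.0, g * x.data), axis=(0, 2, 3, 4)))
        if x.requires_grad:
            x.accumulate(np.where(pos, g, g * av))

    return Tensor(out, (x, a), bwd)


# ---------------------------------------------------------------------------
# shape plumbing


def crop_center(x: Tensor, target: tuple[int, int, int]) -> Tensor:
    """Center-crop the spatial dims to ``target`` (offsets floor-divided)."""
    starts = [(s - t) // 2 for s, t in zip(x.shape[2:], target)]
    sl = (slice(None), slice(None)) + tuple(
        slice(s, s + t) for s, t in zip(starts, target)
    )
    out = x.data[sl]

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[sl] = g
            x.accumulate(gx)

    return Tensor(out, (x,), bwd)


def pad_channels(x: Tensor, c_out: int) -> Tensor:
    """Zero-pad (or truncate) the channel dim to ``c_out`` for residual adds."""
    c_in = x.shape[1]
    if c_in == c_out:
        return x
    if c_in > c_out:
        out = x.data[:, :c_out]

        def bwd_trunc(g):
            if x.requires_grad:
                gx = np.zeros_like(x.data)
                gx[:, :c_out] = g
                x.accumulate(gx)

        return Tensor(out, (x,), bwd_trunc)
    pad = ((0, 0), (0, c_out - c_in), (0, 0), (0, 0), (0, 0))
    out = np.pad(x.data, pad)

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g[:, :c_in])

    return Tensor(out, (x,), bwd)


def upsample_repeat(x: Tensor, r: int) -> Tensor:
    """Nearest-neighbour upsampling by integer factor ``r`` on spatial dims."""
    out = x.data.repeat(r, axis=2).repeat(r, axis=3).repeat(r, axis=4)

    def bwd(g):
        if x.requires_grad:
            n, c, X, Y, Z = x.shape
            gx = g.reshape(n, c, X, r, Y, r, Z, r).sum(axis=(3, 5, 7))
            x.accumulate(gx)

    return Tensor(out, (x,), bwd)


def crop_offset(x: Tensor, starts: tuple[int, int, int], size: tuple[int, int, int]) -> Tensor:
    sl = (slice(None), slice(None)) + tuple(
        slice(s, s + t) for s, t in zip(starts, size)
    )
    out = x.data[sl]

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[sl] = g
            x.accumulate(gx)

    return Tensor(out, (x,), bwd)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    assert a.shape[0] == b.shape[0] and a.shape[2:] == b.shape[2:]
    ca = a.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)

    def bwd(g):
        a.accumulate(g[:, :ca])
        b.accumulate(g[:, ca:])

    return Tensor(out, (a, b), bwd)


# ---------------------------------------------------------------------------
# output head


def foreground_prob(logits: Tensor) -> Tensor:
    """Two-class softmax reduced to the foreground probability channel.

    ``logits`` is (N, 2, X, Y, Z); output is (N, X, Y, Z) in [0, 1].
    """
    assert logits.shape[1] == 2, "expected a two-class logit tensor"
    z = logits.data
    p = 1.0 / (1.0 + np.exp(np.clip(z[:, 0] - z[:, 1], -60, 60)))

    def bwd(g):
        if logits.requires_grad:
            common = g * p * (1.0 - p)
            gl = np.stack([-common, common], axis=1)
            logits.accumulate(gl)

    return Tensor(p, (logits,), bwd)


def soft_dice_loss(pred: Tensor, target: np.ndarray, smooth: float = 1.0) -> Tensor:
    """1 − (2·Σ p·t + s) / (Σ p + Σ t + s), pooled over the whole batch."""
    t = np.asarray(target, dtype=pred.data.dtype)
    if t.shape != pred.shape:
        raise ValueError(f"dice shape mismatch: pred {pred.shape}, target {t.shape}")
    inter = float((pred.data * t).sum())
    denom = float(pred.data.sum() + t.sum())
    loss = 1.0 - (2.0 * inter + smooth) / (denom + smooth)

    def bwd(g):
        if pred.requires_grad:
            d = denom + smooth
            grad = -(2.0 * t * d - (2.0 * inter + smooth)) / (d * d)
            pred.accumulate(g * grad)

    return Tensor(np.asarray(loss), (pred,), bwd)
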