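"""Differentiable array operations for the targeting models.

All spatial operations take NCHW tensors.  Convolutions are stride-1 'same'
with zero padding, implemented by im2col + matmul; the Gaussian blur carries
an analytic derivative with respect to its bandwidth sigma so the smoothing
level can be learned jointly with the network weights.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import convolve1d

from cryotarget.nn.autograd import Tensor

__all__ = [
    "conv2d",
    "linear",
    "max_pool2d",
    "upsample2",
    "concat_channels",
    "global_avg_pool",
    "binary_cross_entropy",
    "gaussian_blur",
    "gaussian_kernel1d",
]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Stride-1 'same' convolution: x (N,C,H,W), weight (F,C,k,k)."""
    N, C, H, W = x.shape
    F, C2, kh, kw = weight.shape
    assert C == C2, "channel mismatch"
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    # (N, C, H, W, kh, kw) windows
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * kh * kw)
    wm = weight.data.reshape(F, C * kh * kw)
    out = cols @ wm.T
    if bias is not None:
        out = out + bias.data
    out = out.reshape(N, H, W, F).transpose(0, 3, 1, 2)

    def backward(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * H * W, F)
        dw = (g2.T @ cols).reshape(F, C, kh, kw)
        db = g2.sum(axis=0) if bias is not None else None
        dcols = (g2 @ wm).reshape(N, H, W, C, kh, kw)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + H, j:j + W] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        dx = dxp[:, :, ph:ph + H, pw:pw + W]
        if bias is not None:
            return dx, dw, db
        return dx, dw

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._make(out, parents, backward)


def linear(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """x (N, D) @ weight (D, M) + bias (M,)."""
    out = x.data @ weight.data + bias.data

    def backward(g):
        return g @ weight.data.T, x.data.T @ g, g.sum(axis=0)

    return Tensor._make(out, (x, weight, bias), backward)


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; spatial dims must be even."""
    N, C, H, W = x.shape
    assert H % 2 == 0 and W % 2 == 0, "max_pool2d needs even spatial dims"
    v = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = v.reshape(N, C, H // 2, W // 2, 4)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, arg[..., None], g[..., None], axis=-1)
        dx = dflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (dx.reshape(N, C, H, W),)

    return Tensor._make(out, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    N, C, H, W = x.shape

    def backward(g):
        return (g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)),)

    return Tensor._make(out, (x,), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        return g[:, :ca], g[:, ca:]

    return Tensor._make(out, (a, b), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over spatial dims: (N, C, H, W) -> (N, C)."""
    N, C, H, W = x.shape
    out = x.data.mean(axis=(2, 3))

    def backward(g):
        return (np.broadcast_to(g[:, :, None, None] / (H * W), x.shape).copy(),)

    return Tensor._make(out, (x,), backward)


def binary_cross_entropy(p: Tensor, target: np.ndarray,
                         weights: np.ndarray | None = None,
                         eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy between probabilities and binary targets.

    ``weights`` optionally reweights each element (e.g. inverse class
    frequency); the loss stays the weighted mean.
    """
    t = np.asarray(target, np.float64)
    pc = np.clip(p.data, eps, 1.0 - eps)
    terms = -(t * np.log(pc) + (1.0 - t) * np.log(1.0 - pc))
    if weights is None:
        loss = terms.mean()
        scale = 1.0 / t.size
        warr = None
    else:
        warr = np.asarray(weights, np.float64)
        wsum = warr.sum()
        loss = (terms * warr).sum() / wsum
        scale = None

    def backward(g):
        # clipped probabilities keep a bounded, nonzero slope so saturated
        # predictions can still recover
        base = (pc - t) / (pc * (1.0 - pc))
        if warr is None:
            return (g * base * (1.0 / t.size),)
        return (g * base * (warr / warr.sum()),)

    return Tensor._make(loss, (p,), backward)


# ---------------------------------------------------------------------------
# Gaussian blur with learnable sigma
# ---------------------------------------------------------------------------

def gaussian_kernel1d(sigma: float, with_derivative: bool = False):
    """Truncated (radius ceil(3 sigma)), renormalized 1-D Gaussian kernel.

    Optionally also returns d(kernel)/d(sigma) of the *normalized* kernel.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = max(int(math.ceil(3.0 * sigma)), 1)
    d = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-d * d / (2.0 * sigma * sigma))
    s = g.sum()
    k = g / s
    if not with_derivative:
        return k
    gp = g * (d * d) / sigma ** 3
    kp = gp / s - k * (gp.sum() / s)
    return k, kp


def gaussian_blur(x: Tensor, sigma: Tensor) -> Tensor:
    """Separable 2-D Gaussian blur, differentiable in both input and sigma.

    The 2-D kernel is the outer product of the truncated, renormalized 1-D
    kernel with itself; borders are zero-padded.  The sigma gradient uses the
    analytic kernel derivative via the product rule on the separable form.
    """
    sig = float(sigma.data)
    k, kp = gaussian_kernel1d(sig, with_derivative=True)

    def conv_rows(a, kern):
        return convolve1d(a, kern, axis=-2, mode="constant")

    def conv_cols(a, kern):
        return convolve1d(a, kern, axis=-1, mode="constant")

    xr = conv_rows(x.data, k)
    out = conv_cols(xr, k)

    def backward(g):
        # symmetric kernel: convolution transpose equals convolution
        dx = conv_rows(conv_cols(g, k), k)
        # dB/dsigma = (k' (x) k + k (x) k') * x
        db_dsig = conv_cols(conv_rows(x.data, kp), k) + conv_cols(xr, kp)
        dsig = np.array((g * db_dsig).sum())
        return dx, dsig

    return Tensor._make(out, (x, sigma), backward)
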