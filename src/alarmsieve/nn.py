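"""Minimal NumPy neural-network primitives with hand-written gradients.

Only what the encoder needs: strided 1-D convolution with zero 'same'
padding, batch normalization, ReLU, inverted dropout, global max pooling and
an Adam optimizer. Activations are float32; forward passes in inference mode
are pure functions of (parameters, input).

Convolutions are evaluated im2col-style: a contiguous patch tensor is built
once per layer and reused by the backward pass, so both directions reduce to
large GEMMs. Peak memory scales with ``batch * Tout * Cin * kernel``; the
training loop's batch size is the knob that bounds it.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ValidationError

DTYPE = np.float32


def same_pad(t_in: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """Output length and (left, right) zero padding for 'same' conv."""
    t_out = -(-t_in // stride)
    pad = max((t_out - 1) * stride + kernel - t_in, 0)
    return t_out, pad // 2, pad - pad // 2


def conv1d_forward(x, w, b, stride):
    """x: (N, Cin, T); w: (Cin, D, Cout); b: (Cout,) -> y: (N, Cout, Tout).

    When the kernel size is a multiple of the stride (true for every block of
    the default architecture) the input is reshaped into stride-width frames
    and the convolution becomes ``D/stride`` batched GEMMs on contiguous
    slices — no strided gather in either direction. Other kernel sizes fall
    back to a sliding-window contraction.
    """
    x = np.ascontiguousarray(x, dtype=DTYPE)
    n, c_in, t_in = x.shape
    c_in_w, d, c_out = w.shape
    if c_in != c_in_w:
        raise ValidationError(f"conv input channels {c_in} != weight {c_in_w}")
    if t_in < 1:
        raise ValidationError("conv input must have at least one time step")
    t_out, pl, _ = same_pad(t_in, d, stride)

    if d % stride == 0:
        q = d // stride
        tf = t_out + q - 1
        xp = np.zeros((n, c_in, tf * stride), dtype=DTYPE)
        xp[:, :, pl : pl + t_in] = x
        # frames[n, t, c*stride] == xp[n, c, t*stride : (t+1)*stride]
        frames = np.ascontiguousarray(
            xp.reshape(n, c_in, tf, stride).transpose(0, 2, 1, 3)
        ).reshape(n, tf, c_in * stride)
        y2 = np.zeros((n, t_out, c_out), dtype=DTYPE)
        for qi in range(q):
            wq = w[:, qi * stride : (qi + 1) * stride, :].reshape(
                c_in * stride, c_out
            )
            y2 += frames[:, qi : qi + t_out, :] @ wq
        y = np.ascontiguousarray(y2.transpose(0, 2, 1))
        y += b[None, :, None]
        cache = ("framed", frames, w, stride, pl, t_in, tf)
        return y, cache

    xp = np.pad(x, ((0, 0), (0, 0), (pl, max(
        (t_out - 1) * stride + d - t_in - pl, 0))))
    v = sliding_window_view(xp, d, axis=2)[:, :, ::stride, :]  # (N,Cin,Tout,D)
    y = np.tensordot(v, w, axes=([1, 3], [0, 1])).transpose(0, 2, 1)
    y = np.ascontiguousarray(y) + b[None, :, None]
    cache = ("generic", xp, w, stride, pl, t_in, None)
    return y.astype(DTYPE), cache


def conv1d_backward(dy, cache, need_dx=True):
    """Gradients of conv1d. Returns (dx, dw, db); dx is None if not needed."""
    kind, stored, w, stride, pl, t_in, tf = cache
    n, c_out, t_out = dy.shape
    c_in, d, _ = w.shape
    db = dy.sum(axis=(0, 2)).astype(DTYPE)
    dy2 = np.ascontiguousarray(dy.transpose(0, 2, 1))  # (N, Tout, Cout)

    if kind == "framed":
        frames = stored
        q = d // stride
        dw = np.empty_like(w)
        dframes = np.zeros_like(frames) if need_dx else None
        for qi in range(q):
            sl = frames[:, qi : qi + t_out, :]
            dwq = np.tensordot(sl, dy2, axes=([0, 1], [0, 1]))
            dw[:, qi * stride : (qi + 1) * stride, :] = dwq.reshape(
                c_in, stride, c_out
            )
            if need_dx:
                wq = w[:, qi * stride : (qi + 1) * stride, :].reshape(
                    c_in * stride, c_out
                )
                dframes[:, qi : qi + t_out, :] += dy2 @ wq.T
        if not need_dx:
            return None, dw, db
        dxp = np.ascontiguousarray(
            dframes.reshape(n, tf, c_in, stride).transpose(0, 2, 1, 3)
        ).reshape(n, c_in, tf * stride)
        return dxp[:, :, pl : pl + t_in], dw, db

    xp = stored
    v = sliding_window_view(xp, d, axis=2)[:, :, ::stride, :]
    dw = np.tensordot(v, dy, axes=([0, 2], [0, 2])).astype(DTYPE)
    if not need_dx:
        return None, dw, db
    dxp = np.zeros_like(xp)
    idx = stride * np.arange(t_out)
    g = np.tensordot(dy, w, axes=([1], [2]))  # (N, Tout, Cin, D)
    for j in range(d):
        dxp[:, :, idx + j] += g[:, :, :, j].transpose(0, 2, 1)
    return dxp[:, :, pl : pl + t_in], dw, db


def batchnorm_forward(x, gamma, beta, running_mean, running_var,
                      training, momentum=0.1, eps=1e-5):
    """Per-channel batch norm over (N, T). Updates running stats in place."""
    if training:
        mean = x.mean(axis=(0, 2))
        var = x.var(axis=(0, 2))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
    y = gamma[None, :, None] * xhat + beta[None, :, None]
    cache = (xhat, gamma, inv_std, training)
    return y.astype(DTYPE), cache


def batchnorm_backward(dy, cache):
    xhat, gamma, inv_std, training = cache
    n_eff = dy.shape[0] * dy.shape[2]
    dgamma = (dy * xhat).sum(axis=(0, 2)).astype(DTYPE)
    dbeta = dy.sum(axis=(0, 2)).astype(DTYPE)
    g = gamma[None, :, None] * inv_std[None, :, None]
    if not training:
        return dy * g, dgamma, dbeta
    dx = g * (
        dy
        - dbeta[None, :, None] / n_eff
        - xhat * dgamma[None, :, None] / n_eff
    )
    return dx.astype(DTYPE), dgamma, dbeta


def relu_forward(x):
    y = np.maximum(x, 0.0)
    return y, (x > 0.0)


def relu_backward(dy, mask):
    return dy * mask


def dropout_forward(x, p, training, rng):
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x, None
    if not 0.0 <= p < 1.0:
        raise ValidationError(f"dropout rate must be in [0,1), got {p}")
    mask = (rng.random(x.shape, dtype=np.float32) >= p).astype(DTYPE) / DTYPE(1.0 - p)
    return x * mask, mask


def dropout_backward(dy, mask):
    return dy if mask is None else dy * mask


def global_maxpool_forward(x):
    """x: (N, C, T) -> (N, C); stores argmax for backward."""
    arg = x.argmax(axis=2)
    y = np.take_along_axis(x, arg[:, :, None], axis=2)[:, :, 0]
    return y, (arg, x.shape)


def global_maxpool_backward(dy, cache):
    arg, shape = cache
    dx = np.zeros(shape, dtype=DTYPE)
    np.put_along_axis(dx, arg[:, :, None], dy[:, :, None], axis=2)
    return dx


def sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adam with optional decoupled-from-bias L2 (added to grads upstream)."""

    def __init__(self, params: dict[str, np.ndarray], lr=0.001,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, grad in grads.items():
            if key not in self.params:
                raise ValidationError(f"gradient for unknown parameter {key!r}")
            g = np.asarray(grad, dtype=np.float64)
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            mhat = self.m[key] / (1 - b1 ** self.t)
            vhat = self.v[key] / (1 - b2 ** self.t)
            self.params[key] -= (
                self.lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(self.params[key].dtype)
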