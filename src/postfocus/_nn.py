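"""Minimal numpy neural-network primitives with hand-written backprop.

The deployment environment has no deep-learning framework, so the small
networks used by this package (a convolutional focus classifier and a
conditional U-Net noise predictor) are built from the functional primitives
in this module.  Every ``*_forward`` returns ``(output, cache)`` and the
matching ``*_backward`` consumes the upstream gradient plus that cache.

Activations are laid out channels-last, ``(N, H, W, C)``: the 3x3 "same"
convolution then reduces to one large GEMM over ``(N*H*W, 9*C)`` patch
matrices, which is where nearly all the compute lives.  All primitives are
dtype-preserving so the test suite can run exact finite-difference gradient
checks in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "he_conv",
    "he_dense",
    "conv3_forward",
    "conv3_backward",
    "dense_forward",
    "dense_backward",
    "relu_forward",
    "relu_backward",
    "silu_forward",
    "silu_backward",
    "avgpool2_forward",
    "avgpool2_backward",
    "upsample2_forward",
    "upsample2_backward",
    "groupnorm_forward",
    "groupnorm_backward",
    "attention_forward",
    "attention_backward",
    "softmax",
    "softmax_xent",
    "Adam",
]


# ---------------------------------------------------------------------------
# initializers

def he_conv(rng: np.random.Generator, in_ch: int, out_ch: int, k: int = 3,
            dtype=np.float32) -> np.ndarray:
    """He-normal init for a k x k convolution kernel, shape (k, k, Cin, Cout)."""
    fan_in = in_ch * k * k
    return rng.normal(0.0, np.sqrt(2.0 / fan_in),
                      (k, k, in_ch, out_ch)).astype(dtype)


def he_dense(rng: np.random.Generator, in_dim: int, out_dim: int,
             dtype=np.float32) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / in_dim), (in_dim, out_dim)).astype(dtype)


# ---------------------------------------------------------------------------
# 3x3 "same" convolution (zero padding) via patch-matrix GEMM

def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, 9*C) patch matrix with zero padding of 1."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # (n, h, w, c, 3, 3) -> patch-index major, channel minor; reshape copies
    return win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, 9 * c)


def _col2im3(dcols: np.ndarray, shape: tuple) -> np.ndarray:
    n, h, w, c = shape
    dcols = dcols.reshape(n, h, w, 9, c)
    dxp = np.zeros((n, h + 2, w + 2, c), dtype=dcols.dtype)
    for k in range(9):
        i, j = divmod(k, 3)
        dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, k, :]
    return dxp[:, 1:-1, 1:-1, :]


def conv3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x (N,H,W,C), W (3,3,C,O), b (O,) -> y (N,H,W,O)."""
    n, h, w, c = x.shape
    o = W.shape[-1]
    cols = _im2col3(x)                         # (NHW, 9C)
    y = cols @ W.reshape(-1, o)
    y += b
    return y.reshape(n, h, w, o), (cols, x.shape, W)


def conv3_backward(dy: np.ndarray, cache):
    cols, xshape, W = cache
    n, h, w, c = xshape
    o = W.shape[-1]
    dyf = dy.reshape(n * h * w, o)
    dW = (cols.T @ dyf).reshape(W.shape)
    db = dyf.sum(axis=0)
    dcols = dyf @ W.reshape(-1, o).T
    dx = _col2im3(dcols, xshape)
    return dx, dW, db


# ---------------------------------------------------------------------------
# dense

def dense_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    return x @ W + b, (x, W)


def dense_backward(dy: np.ndarray, cache):
    x, W = cache
    return dy @ W.T, x.T @ dy, dy.sum(axis=0)


# ---------------------------------------------------------------------------
# activations

def relu_forward(x: np.ndarray):
    y = np.maximum(x, 0)
    return y, (x > 0)


def relu_backward(dy: np.ndarray, cache):
    return dy * cache


def silu_forward(x: np.ndarray):
    s = 1.0 / (1.0 + np.exp(-x))
    return x * s, (x, s)


def silu_backward(dy: np.ndarray, cache):
    x, s = cache
    return dy * (s * (1.0 + x * (1.0 - s)))


# ---------------------------------------------------------------------------
# 2x2 average pool / nearest-neighbour x2 upsample (spatial axes 1, 2)

def avgpool2_forward(x: np.ndarray):
    n, h, w, c = x.shape
    y = x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))
    return y, x.shape


def avgpool2_backward(dy: np.ndarray, cache):
    return np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) * np.asarray(0.25, dy.dtype)


def upsample2_forward(x: np.ndarray):
    y = np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)
    return y, x.shape


def upsample2_backward(dy: np.ndarray, cache):
    n, h, w, c = cache
    return dy.reshape(n, h, 2, w, 2, c).sum(axis=(2, 4))


# ---------------------------------------------------------------------------
# group normalization (channels grouped; stats over spatial x group-channels)

def _group_mean(a_sum_c: np.ndarray, g: int, m: int) -> np.ndarray:
    """Per-channel sums (N, C) -> per-channel group means (N, C)."""
    n, c = a_sum_c.shape
    cg = c // g
    gm = a_sum_c.reshape(n, g, cg).sum(axis=-1) / m
    return np.repeat(gm, cg, axis=1)


def groupnorm_forward(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
                      groups: int, eps: float = 1e-5):
    # statistics assembled from per-channel sums: reductions keep the
    # contiguous channel axis, which is much faster than strided group axes
    n, h, w, c = x.shape
    m = h * w * (c // groups)
    mu_c = _group_mean(x.sum(axis=(1, 2)), groups, m)[:, None, None, :]
    var_c = (_group_mean((x * x).sum(axis=(1, 2)), groups, m)[:, None, None, :]
             - mu_c * mu_c)
    inv_c = 1.0 / np.sqrt(var_c + np.asarray(eps, x.dtype))
    xhat = (x - mu_c) * inv_c
    y = xhat * gamma + beta
    return y, (xhat, inv_c, gamma, groups)


def groupnorm_backward(dy: np.ndarray, cache):
    xhat, inv_c, gamma, g = cache
    n, h, w, c = xhat.shape
    m = h * w * (c // g)
    dgamma = (dy * xhat).sum(axis=(0, 1, 2))
    dbeta = dy.sum(axis=(0, 1, 2))
    dxhat = dy * gamma
    m1 = _group_mean(dxhat.sum(axis=(1, 2)), g, m)[:, None, None, :]
    m2 = _group_mean((dxhat * xhat).sum(axis=(1, 2)), g, m)[:, None, None, :]
    dx = inv_c * (dxhat - m1 - xhat * m2)
    return dx, dgamma, dbeta


# ---------------------------------------------------------------------------
# single-head self-attention over spatial tokens, with residual connection

def attention_forward(x: np.ndarray, Wq, Wk, Wv, Wo):
    """x (N,H,W,C); all weights (C,C).  Returns x + proj(softmax(QK^T)V)."""
    n, h, w, c = x.shape
    xf = x.reshape(n, h * w, c)
    q = xf @ Wq
    k = xf @ Wk
    v = xf @ Wv
    # float() keeps the scalar weakly typed so float32 activations stay float32
    scale = 1.0 / float(np.sqrt(c))
    s = np.matmul(q, k.transpose(0, 2, 1)) * scale        # (N, L, L)
    s -= s.max(axis=-1, keepdims=True)
    p = np.exp(s)
    p /= p.sum(axis=-1, keepdims=True)
    yattn = np.matmul(p, v)                               # (N, L, C)
    y = x + (yattn @ Wo).reshape(n, h, w, c)
    return y, (xf, q, k, v, p, yattn, Wq, Wk, Wv, Wo, scale, (n, h, w, c))


def attention_backward(dy: np.ndarray, cache):
    xf, q, k, v, p, yattn, Wq, Wk, Wv, Wo, scale, shape = cache
    n, h, w, c = shape
    dyf = dy.reshape(n, h * w, c)
    dWo = np.matmul(yattn.transpose(0, 2, 1), dyf).sum(axis=0)
    dyattn = dyf @ Wo.T
    dp = np.matmul(dyattn, v.transpose(0, 2, 1))
    dv = np.matmul(p.transpose(0, 2, 1), dyattn)
    ds = p * (dp - (dp * p).sum(axis=-1, keepdims=True))
    dq = np.matmul(ds, k) * scale
    dk = np.matmul(ds.transpose(0, 2, 1), q) * scale
    dxf = dq @ Wq.T + dk @ Wk.T + dv @ Wv.T
    dWq = np.matmul(xf.transpose(0, 2, 1), dq).sum(axis=0)
    dWk = np.matmul(xf.transpose(0, 2, 1), dk).sum(axis=0)
    dWv = np.matmul(xf.transpose(0, 2, 1), dv).sum(axis=0)
    dx = dy + dxf.reshape(n, h, w, c)
    return dx, dWq, dWk, dWv, dWo


# ---------------------------------------------------------------------------
# losses

def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy; labels are int class indices. Returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Adam with classic L2 weight decay (added to the gradient)."""

    def __init__(self, params: dict, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for key, p in self.params.items():
            g = grads[key]
            if self.weight_decay and p.ndim > 1:
                g = g + self.weight_decay * p
            m = self.m[key]
            v = self.v[key]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
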