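"""Network definitions built on the numpy primitives in ``_nn``.

Two architectures live here:

* :class:`ClassifierNet` — a small convolutional classifier (conv blocks with
  2x2 pooling, global average pooling, linear head).
* :class:`UNet` — a U-shaped encoder/decoder with group normalization, SiLU,
  optional self-attention at chosen resolution levels, and optional sinusoidal
  timestep conditioning.  With ``use_time=True`` and a 2-channel input it is
  the conditional noise predictor of the diffusion restorer; with
  ``use_time=False`` it doubles as the direct-regression restoration baseline.

Activations are channels-last ``(N, H, W, C)``.  Parameters are flat
``{name: ndarray}`` dicts so they serialize to ``.npz`` checkpoints and plug
straight into :class:`postfocus._nn.Adam`.
"""

from __future__ import annotations

import numpy as np

from . import _nn


def _ngroups(channels: int, max_groups: int = 8) -> int:
    g = min(max_groups, channels)
    while channels % g:
        g -= 1
    return g


def sinusoidal_embedding(t: np.ndarray, dim: int, dtype=np.float32) -> np.ndarray:
    """Transformer-style sinusoidal embedding of integer timesteps, (N, dim)."""
    t = np.asarray(t, dtype=np.float64).reshape(-1)
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half) / max(half - 1, 1))
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=1)
    if emb.shape[1] < dim:
        emb = np.pad(emb, ((0, 0), (0, dim - emb.shape[1])))
    return emb.astype(dtype)


class ClassifierNet:
    """Conv blocks (conv3 -> ReLU -> pool) + global average pool + linear head."""

    def __init__(self, conv_widths=(8, 16, 32, 32), in_ch: int = 1,
                 n_classes: int = 2, seed: int = 0, dtype=np.float32):
        self.conv_widths = tuple(conv_widths)
        self.in_ch = in_ch
        self.n_classes = n_classes
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        p = {}
        c_prev = in_ch
        for i, c in enumerate(self.conv_widths):
            p[f"conv{i}_W"] = _nn.he_conv(rng, c_prev, c, dtype=dtype)
            p[f"conv{i}_b"] = np.zeros(c, dtype=dtype)
            c_prev = c
        p["head_W"] = _nn.he_dense(rng, c_prev, n_classes, dtype=dtype)
        p["head_b"] = np.zeros(n_classes, dtype=dtype)
        self.params = p

    def forward(self, x: np.ndarray, train: bool = False):
        """x (N, H, W, C) -> logits (N, n_classes)."""
        p = self.params
        caches = [] if train else None
        h = x.astype(self.dtype, copy=False)
        n_blocks = len(self.conv_widths)
        for i in range(n_blocks):
            h, c_conv = _nn.conv3_forward(h, p[f"conv{i}_W"], p[f"conv{i}_b"])
            h, c_relu = _nn.relu_forward(h)
            if i < n_blocks - 1:
                h, c_pool = _nn.avgpool2_forward(h)
            else:
                c_pool = None
            if train:
                caches.append((c_conv, c_relu, c_pool))
        feat = h.mean(axis=(1, 2))                      # global average pool
        logits, c_head = _nn.dense_forward(feat, p["head_W"], p["head_b"])
        if train:
            return logits, (caches, c_head, h.shape)
        return logits

    def backward(self, dlogits: np.ndarray, cache):
        caches, c_head, feat_shape = cache
        grads = {}
        dfeat, grads["head_W"], grads["head_b"] = _nn.dense_backward(dlogits, c_head)
        n, h, w, c = feat_shape
        dh = np.broadcast_to(dfeat[:, None, None, :] / (h * w),
                             feat_shape).astype(dfeat.dtype)
        for i in range(len(self.conv_widths) - 1, -1, -1):
            c_conv, c_relu, c_pool = caches[i]
            if c_pool is not None:
                dh = _nn.avgpool2_backward(dh, c_pool)
            dh = _nn.relu_backward(dh, c_relu)
            dh, grads[f"conv{i}_W"], grads[f"conv{i}_b"] = _nn.conv3_backward(dh, c_conv)
        return grads


class UNet:
    """U-Net noise predictor / regression net.

    ``channel_mult`` fixes the number of resolution levels; the input spatial
    size must be divisible by ``2 ** (levels - 1)``.  Attention (single-head,
    full spatial, residual) is inserted after the two conv blocks of each
    level listed in ``attention_levels`` on the encoder path.
    """

    def __init__(self, in_ch: int = 2, out_ch: int = 1, base_channels: int = 16,
                 channel_mult=(1, 2, 2), attention_levels=(2,), temb_dim: int = 32,
                 use_time: bool = True, seed: int = 0, dtype=np.float32):
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.base_channels = base_channels
        self.channel_mult = tuple(channel_mult)
        self.attention_levels = tuple(a for a in attention_levels
                                      if a < len(self.channel_mult))
        self.temb_dim = temb_dim
        self.use_time = use_time
        self.dtype = dtype
        self.levels = len(self.channel_mult)
        self.ch = [base_channels * m for m in self.channel_mult]

        rng = np.random.default_rng(seed)
        p = {}
        p["in_W"] = _nn.he_conv(rng, in_ch, self.ch[0], dtype=dtype)
        p["in_b"] = np.zeros(self.ch[0], dtype=dtype)
        if use_time:
            p["t1_W"] = _nn.he_dense(rng, temb_dim, temb_dim, dtype=dtype)
            p["t1_b"] = np.zeros(temb_dim, dtype=dtype)
            p["t2_W"] = _nn.he_dense(rng, temb_dim, temb_dim, dtype=dtype)
            p["t2_b"] = np.zeros(temb_dim, dtype=dtype)

        def add_block(name, cin, cout):
            p[f"{name}_W"] = _nn.he_conv(rng, cin, cout, dtype=dtype)
            p[f"{name}_b"] = np.zeros(cout, dtype=dtype)
            p[f"{name}_g"] = np.ones(cout, dtype=dtype)
            p[f"{name}_be"] = np.zeros(cout, dtype=dtype)
            if use_time:
                p[f"{name}_tW"] = (_nn.he_dense(rng, temb_dim, cout, dtype=dtype)
                                   * np.asarray(0.1, dtype))
                p[f"{name}_tb"] = np.zeros(cout, dtype=dtype)

        for l in range(self.levels):
            cin = self.ch[0] if l == 0 else self.ch[l - 1]
            add_block(f"d{l}0", cin, self.ch[l])
            add_block(f"d{l}1", self.ch[l], self.ch[l])
            if l in self.attention_levels:
                c = self.ch[l]
                for w in ("Wq", "Wk", "Wv", "Wo"):
                    p[f"attn{l}_{w}"] = (rng.normal(0, 1.0 / np.sqrt(c), (c, c))
                                         .astype(dtype))
        for l in range(self.levels - 2, -1, -1):
            add_block(f"u{l}0", self.ch[l + 1] + self.ch[l], self.ch[l])
            add_block(f"u{l}1", self.ch[l], self.ch[l])
        # zero-init output conv: the untrained net predicts exactly zero
        p["out_W"] = np.zeros((3, 3, self.ch[0], out_ch), dtype=dtype)
        p["out_b"] = np.zeros(out_ch, dtype=dtype)
        self.params = p

    # -- blocks -------------------------------------------------------------

    def _block_forward(self, name, x, temb, train):
        p = self.params
        cout = p[f"{name}_b"].shape[0]
        h, c_conv = _nn.conv3_forward(x, p[f"{name}_W"], p[f"{name}_b"])
        h, c_gn = _nn.groupnorm_forward(h, p[f"{name}_g"], p[f"{name}_be"],
                                        _ngroups(cout))
        if self.use_time:
            h = h + (temb @ p[f"{name}_tW"] + p[f"{name}_tb"])[:, None, None, :]
        h, c_act = _nn.silu_forward(h)
        return h, (c_conv, c_gn, c_act) if train else None

    def _block_backward(self, name, dy, cache, grads, dtemb, temb):
        c_conv, c_gn, c_act = cache
        dh = _nn.silu_backward(dy, c_act)
        if self.use_time:
            dlin = dh.sum(axis=(1, 2))
            grads[f"{name}_tW"] = temb.T @ dlin
            grads[f"{name}_tb"] = dlin.sum(axis=0)
            dtemb += dlin @ self.params[f"{name}_tW"].T
        dh, grads[f"{name}_g"], grads[f"{name}_be"] = _nn.groupnorm_backward(dh, c_gn)
        dx, grads[f"{name}_W"], grads[f"{name}_b"] = _nn.conv3_backward(dh, c_conv)
        return dx

    # -- full network -------------------------------------------------------

    def forward(self, x: np.ndarray, t: np.ndarray | None = None,
                train: bool = False):
        """x (N, H, W, in_ch); t integer timesteps (N,) when ``use_time``."""
        p = self.params
        x = x.astype(self.dtype, copy=False)
        if self.use_time:
            temb0 = sinusoidal_embedding(t, self.temb_dim, self.dtype)
            h1, c_t1 = _nn.dense_forward(temb0, p["t1_W"], p["t1_b"])
            h1s, c_ts = _nn.silu_forward(h1)
            temb, c_t2 = _nn.dense_forward(h1s, p["t2_W"], p["t2_b"])
        else:
            temb = None
        tape = {} if train else None

        h, c_in = _nn.conv3_forward(x, p["in_W"], p["in_b"])
        if train:
            tape["in"] = c_in
        skips = []
        for l in range(self.levels):
            h, cb0 = self._block_forward(f"d{l}0", h, temb, train)
            h, cb1 = self._block_forward(f"d{l}1", h, temb, train)
            if train:
                tape[f"d{l}"] = (cb0, cb1)
            if l in self.attention_levels:
                h, c_at = _nn.attention_forward(h, p[f"attn{l}_Wq"], p[f"attn{l}_Wk"],
                                                p[f"attn{l}_Wv"], p[f"attn{l}_Wo"])
                if train:
                    tape[f"attn{l}"] = c_at
            skips.append(h)
            if l < self.levels - 1:
                h, c_pool = _nn.avgpool2_forward(h)
                if train:
                    tape[f"pool{l}"] = c_pool
        for l in range(self.levels - 2, -1, -1):
            h, c_up = _nn.upsample2_forward(h)
            h = np.concatenate([h, skips[l]], axis=-1)
            h, cb0 = self._block_forward(f"u{l}0", h, temb, train)
            h, cb1 = self._block_forward(f"u{l}1", h, temb, train)
            if train:
                tape[f"u{l}"] = (c_up, cb0, cb1)
        out, c_out = _nn.conv3_forward(h, p["out_W"], p["out_b"])
        if train:
            tape["out"] = c_out
            tape["temb"] = (temb, c_t1, c_ts, c_t2) if self.use_time else None
            return out, tape
        return out

    def backward(self, dout: np.ndarray, tape):
        grads = {}
        if self.use_time:
            temb = tape["temb"][0]
            dtemb = np.zeros_like(temb)
        else:
            temb, dtemb = None, None

        dh, grads["out_W"], grads["out_b"] = _nn.conv3_backward(dout, tape["out"])
        dskips = [None] * self.levels
        for l in range(0, self.levels - 1):
            c_up, cb0, cb1 = tape[f"u{l}"]
            dh = self._block_backward(f"u{l}1", dh, cb1, grads, dtemb, temb)
            dh = self._block_backward(f"u{l}0", dh, cb0, grads, dtemb, temb)
            c_hi = self.ch[l + 1]
            dskips[l] = dh[..., c_hi:]
            dh = _nn.upsample2_backward(dh[..., :c_hi], c_up)
        for l in range(self.levels - 1, -1, -1):
            if l < self.levels - 1:
                dh = _nn.avgpool2_backward(dh, tape[f"pool{l}"])
                dh = dh + dskips[l]
            if l in self.attention_levels:
                dh, dWq, dWk, dWv, dWo = _nn.attention_backward(dh, tape[f"attn{l}"])
                grads[f"attn{l}_Wq"] = dWq
                grads[f"attn{l}_Wk"] = dWk
                grads[f"attn{l}_Wv"] = dWv
                grads[f"attn{l}_Wo"] = dWo
            cb0, cb1 = tape[f"d{l}"]
            dh = self._block_backward(f"d{l}1", dh, cb1, grads, dtemb, temb)
            dh = self._block_backward(f"d{l}0", dh, cb0, grads, dtemb, temb)
        dx, grads["in_W"], grads["in_b"] = _nn.conv3_backward(dh, tape["in"])
        if self.use_time:
            _, c_t1, c_ts, c_t2 = tape["temb"]
            dh1s, grads["t2_W"], grads["t2_b"] = _nn.dense_backward(dtemb, c_t2)
            dh1 = _nn.silu_backward(dh1s, c_ts)
            _, grads["t1_W"], grads["t1_b"] = _nn.dense_backward(dh1, c_t1)
        return dx, grads
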