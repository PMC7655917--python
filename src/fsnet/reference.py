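"""Straight-line scalar reference implementations of the attention and
skip-fusion blocks.

These evaluate the block equations element by element with explicit Python
loops, reading only the raw weight arrays of a built block.  They share no
code with the vectorised autodiff path in :mod:`fsnet.nn`, so agreement
between the two is a meaningful correctness check rather than a tautology.
Intended for tests and verification runs on small tensors only.
"""

from __future__ import annotations

import math

import numpy as np


def _sigmoid(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-v))


def _dense(w2d: np.ndarray, b: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """y[o] = sum_i w2d[o, i] * vec[i] + b[o], written as loops."""
    out = np.zeros(w2d.shape[0], dtype=np.float64)
    for o in range(w2d.shape[0]):
        acc = float(b[o])
        for i in range(w2d.shape[1]):
            acc += float(w2d[o, i]) * float(vec[i])
        out[o] = acc
    return out


def _conv1x1(w2d: np.ndarray, b: np.ndarray, feat: np.ndarray) -> np.ndarray:
    """1x1 convolution on a (C_in, H, W) map via per-pixel loops."""
    c_out = w2d.shape[0]
    _, h, wdt = feat.shape
    out = np.zeros((c_out, h, wdt), dtype=np.float64)
    for i in range(h):
        for j in range(wdt):
            out[:, i, j] = _dense(w2d, b, feat[:, i, j])
    return out


def _w(conv) -> np.ndarray:
    return conv.weight.data[:, :, 0, 0].astype(np.float64)


def _b(conv) -> np.ndarray:
    return conv.bias.data.astype(np.float64)


def channel_attention_reference(cab, feature: np.ndarray) -> np.ndarray:
    """Per-channel weight of one channel-attention block on a (C,H,W) map."""
    c = feature.shape[0]
    d_max = np.array([feature[k].max() for k in range(c)], dtype=np.float64)
    d_avg = np.array([feature[k].mean() for k in range(c)], dtype=np.float64)

    def bottleneck(d: np.ndarray) -> np.ndarray:
        d = np.maximum(_dense(_w(cab.fc1), _b(cab.fc1), d), 0.0)
        d = np.maximum(_dense(_w(cab.fc2), _b(cab.fc2), d), 0.0)
        d = _dense(_w(cab.fc3), _b(cab.fc3), d)
        return np.maximum(d, 0.0) if cab.final_relu else d

    cat = np.concatenate([bottleneck(d_max), bottleneck(d_avg)])
    pre = _dense(_w(cab.reduce), _b(cab.reduce), cat)
    return np.array([_sigmoid(v) for v in pre])


def csab_reference(block, x: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Full CSAB output for one (C,H,W) sample pair, by scalar evaluation."""
    x = x.astype(np.float64)
    g = g.astype(np.float64)
    c, h, wdt = x.shape
    alpha1 = channel_attention_reference(block.cab_g, g)
    alpha2 = channel_attention_reference(block.cab_x, x)
    g_l = np.zeros_like(g)
    x_l = np.zeros_like(x)
    for k in range(c):
        for i in range(h):
            for j in range(wdt):
                g_l[k, i, j] = alpha1[k] * g[k, i, j]
                x_l[k, i, j] = alpha2[k] * x[k, i, j]
    f_wg = _conv1x1(_w(block.sab.w_g), _b(block.sab.w_g), g_l)
    f_wx = _conv1x1(_w(block.sab.w_x), _b(block.sab.w_x), x_l)
    cat = np.concatenate([f_wg, f_wx], axis=0)
    psi = _conv1x1(_w(block.sab.psi), _b(block.sab.psi), cat)[0]
    f = np.zeros_like(x)
    for k in range(c):
        for i in range(h):
            for j in range(wdt):
                f[k, i, j] = _sigmoid(psi[i, j]) * x_l[k, i, j] * g_l[k, i, j]
    return _conv1x1(_w(block.merge), _b(block.merge), np.concatenate([f, x], axis=0))


def skip_fuse_reference(skip, x1: np.ndarray, x2: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Variant-d skip fusion for one sample: two CSAB passes, per-path 1x1
    reduction of [F_i, g], then channel concatenation."""
    f1 = csab_reference(skip.csab1, x1, g)
    f2 = csab_reference(skip.csab2, x2, g)
    x13 = _conv1x1(_w(skip.reduce1), _b(skip.reduce1),
                   np.concatenate([f1, g.astype(np.float64)], axis=0))
    x23 = _conv1x1(_w(skip.reduce2), _b(skip.reduce2),
                   np.concatenate([f2, g.astype(np.float64)], axis=0))
    return np.concatenate([x13, x23], axis=0)
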