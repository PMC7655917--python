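"""Composite training objective: L_total = eta * (L_MSE + L_SSIM) + gamma * L_BCE.

The fusion sub-network contributes a reconstruction term (MSE between the
decoder's reconstruction and the stacked CT+MRI input) and a structural term
(1 - SSIM between the fused image and each input modality, averaged); the
segmentation sub-network contributes pixel-wise binary cross-entropy against
the tumor mask.  The two groups are balanced with eta = 0.02 and gamma = 1
by default — the fusion losses are roughly fifty times larger than the
segmentation loss early in training, and the weighting keeps the BCE term in
charge.

SSIM follows the standard Wang et al. formulation: 11x11 Gaussian window
with sigma 1.5, stabilizers C1 = (0.01 L)^2 and C2 = (0.03 L)^2 at dynamic
range L = 1, averaged over all fully-valid windows.  It is implemented on
the autodiff graph so the fusion encoder trains through it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor


@dataclass(frozen=True)
class SsimConfig:
    window: int = 11
    sigma: float = 1.5
    c1: float = 0.01 ** 2
    c2: float = 0.03 ** 2


@dataclass
class LossComponents:
    """The three loss terms and their weighted total, as graph tensors."""

    mse: Tensor
    ssim_loss: Tensor
    bce: Tensor
    total: Tensor
    eta: float
    gamma: float

    def as_floats(self) -> dict[str, float]:
        return {"mse": float(self.mse.data), "ssim_loss": float(self.ssim_loss.data),
                "bce": float(self.bce.data), "total": float(self.total.data)}


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def mse_loss(reconstruction, target) -> Tensor:
    """Mean squared error over every element of the batch."""
    reconstruction, target = _as_tensor(reconstruction), _as_tensor(target)
    if reconstruction.shape != target.shape:
        raise ValueError(f"shape mismatch {reconstruction.shape} vs {target.shape}")
    return ((reconstruction - target) ** 2).mean()


def gaussian_window(size: int, sigma: float, dtype=np.float64) -> np.ndarray:
    ax = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    k = np.outer(g, g)
    return (k / k.sum()).astype(dtype)


def ssim(a, b, config: SsimConfig = SsimConfig()) -> Tensor:
    """Mean structural similarity of two (N, C, H, W) batches.

    Gaussian-weighted local moments, population (not sample) covariance,
    averaged over the windows that fit entirely inside the image.
    """
    a, b = _as_tensor(a), _as_tensor(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    n, c, h, w = a.shape
    if h < config.window or w < config.window:
        raise ValueError(f"image {h}x{w} smaller than SSIM window {config.window}")
    kern = gaussian_window(config.window, config.sigma, a.dtype)
    weight = Tensor(np.broadcast_to(kern, (1, 1, *kern.shape)).copy())

    def filt(t: Tensor) -> Tensor:
        # depthwise: fold channels into the batch axis, single-channel conv
        flat = t.reshape(n * c, 1, h, w)
        return nn.conv2d(flat, weight)

    mu_a, mu_b = filt(a), filt(b)
    mu_aa, mu_bb, mu_ab = mu_a * mu_a, mu_b * mu_b, mu_a * mu_b
    var_a = filt(a * a) - mu_aa
    var_b = filt(b * b) - mu_bb
    cov = filt(a * b) - mu_ab
    num = (2.0 * mu_ab + config.c1) * (2.0 * cov + config.c2)
    den = (mu_aa + mu_bb + config.c1) * (var_a + var_b + config.c2)
    return (num / den).mean()


def ssim_loss(reference, fused, config: SsimConfig = SsimConfig()) -> Tensor:
    """1 - SSIM, comparing the fused image with each reference channel.

    ``reference`` is (N, C, H, W) — the stacked input modalities — and
    ``fused`` is (N, 1, H, W); the single fused channel is scored against
    each modality and the results are averaged, so both CT and MRI structure
    constrain the fusion.  Ranges over [0, 2].
    """
    reference, fused = _as_tensor(reference), _as_tensor(fused)
    c = reference.shape[1]
    if fused.shape[1] == c:
        mean_ssim = ssim(reference, fused, config)
    elif fused.shape[1] == 1:
        total = None
        for k in range(c):
            s = ssim(_slice_channel(reference, k), fused, config)
            total = s if total is None else total + s
        mean_ssim = total * (1.0 / c)
    else:
        raise ValueError("fused must have 1 channel or match the reference")
    return 1.0 - mean_ssim


def _slice_channel(t: Tensor, k: int) -> Tensor:
    out = nn.autograd._make(t.data[:, k:k + 1], (t,))

    def bw(g):
        full = np.zeros_like(t.data)
        full[:, k:k + 1] = g
        t._accumulate(full)
    out._backward = bw
    return out


def bce_loss(prediction, target, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy with predictions clamped to [eps, 1-eps]."""
    prediction, target = _as_tensor(prediction), _as_tensor(target)
    if prediction.shape != target.shape:
        raise ValueError(f"shape mismatch {prediction.shape} vs {target.shape}")
    tdata = np.asarray(target.data)
    if not np.all(np.isin(tdata, [0, 1])):
        raise ValueError("BCE target must be binary {0,1}")
    p = prediction.clamp(eps, 1.0 - eps)
    t = Tensor(tdata.astype(p.dtype))
    return -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()


def composite_loss(reconstruction, fusion_input, fused, prediction, mask,
                   eta: float = 0.02, gamma: float = 1.0,
                   ssim_config: SsimConfig = SsimConfig()) -> LossComponents:
    """Assemble the weighted objective from the cascade's outputs.

    ``reconstruction`` (N,2,H,W) vs ``fusion_input`` (N,2,H,W) feeds MSE;
    ``fused`` (N,1,H,W) vs ``fusion_input`` feeds the SSIM term;
    ``prediction`` vs ``mask`` feeds BCE.  When the fusion stage is disabled
    pass ``reconstruction=None``/``fused=None`` and the fusion terms are zero.
    """
    zero = Tensor(np.zeros((), dtype=np.float64))
    mse = mse_loss(reconstruction, fusion_input) if reconstruction is not None else zero
    ssim_l = ssim_loss(fusion_input, fused, ssim_config) if fused is not None else zero
    bce = bce_loss(prediction, mask)
    total = eta * (mse + ssim_l) + gamma * bce
    return LossComponents(mse=mse, ssim_loss=ssim_l, bce=bce, total=total,
                          eta=eta, gamma=gamma)
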