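"""Evaluate the composite loss and the segmentation metrics on toy data.

The objective is L_total = eta*(L_MSE + L_SSIM) + gamma*L_BCE with
eta = 0.02 and gamma = 1: the fusion terms (reconstruction MSE and
1 - SSIM of the fused image against each modality) are two orders of
magnitude larger than the segmentation BCE early in training, so the small
eta keeps the mask loss in charge.
"""

import numpy as np

from fsnet.losses import composite_loss
from fsnet.metrics import ConfusionCounts, compute_metrics

rng = np.random.default_rng(0)
stacked = rng.random((1, 2, 32, 32))          # CT+MRI input
fused = rng.random((1, 1, 32, 32))            # fusion output
recon = rng.random((1, 2, 32, 32))            # D_phi reconstruction
prob = np.clip(rng.random((1, 1, 32, 32)), 0.05, 0.95)
mask = (rng.random((1, 1, 32, 32)) > 0.8).astype(float)

comps = composite_loss(recon, stacked, fused, prob, mask)
vals = comps.as_floats()
print("loss components on random tensors:")
for k, v in vals.items():
    print(f"  {k:10s} {v:.4f}")
print(f"  identity check: 0.02*({vals['mse']:.4f}+{vals['ssim_loss']:.4f}) + "
      f"{vals['bce']:.4f} = {0.02 * (vals['mse'] + vals['ssim_loss']) + vals['bce']:.4f}")

rep = compute_metrics(ConfusionCounts(tp=3, tn=10, fp=1, fn=2))
print("\nmetrics for confusion counts tp=3 fp=1 fn=2 tn=10:")
print(f"  ACC={rep.acc:.4f}  PPV={rep.ppv:.4f}  JS={rep.js:.4f}  DC={rep.dc:.4f}")
print(f"  Dice-Jaccard identity: 2*JS/(1+JS) = {2 * rep.js / (1 + rep.js):.4f}")
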