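"""Synthetic co-registered CT/MRI slice phantoms with ground-truth tumor masks.

Clinical paired CT + T2-MRI glioma data are rarely shareable, so the toolkit
ships a generator that reproduces the structural properties the segmentation
method relies on, without claiming radiological realism:

* the two modalities are co-registered pixel-for-pixel;
* the modalities are complementary: the tumor is high-contrast on T2 MRI and
  faint on CT, while the skull ring is bright on CT and faint on MRI;
* each slice has a binary whole-tumor mask, a single connected blob with an
  irregular (low-frequency perturbed ellipse) boundary;
* slices are grouped into pseudo-patients so dataset splits can be done at
  the patient level.

Everything is driven by integer-seeded :class:`numpy.random.Generator`
streams keyed on ``(seed, index)``, so a fixed spec yields a bit-identical
dataset on any platform.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic slice family.

    Intensities live in [0, 1].  ``tumor_radius_range`` is a fraction of the
    image side.  ``tumor_contrast_*`` is the mean intensity the tumor adds
    over the surrounding tissue in each modality, before noise; the CT
    contrast must be smaller than the MRI contrast (the modality asymmetry
    the fusion network exploits).  ``texture_amplitude`` scales the smooth
    intra-tissue texture; ``boundary_amplitude`` scales the radial
    perturbation of the tumor outline (0 gives an exact ellipse).
    """

    image_size: int = 256
    n_samples: int = 120
    tumor_radius_range: tuple[float, float] = (0.08, 0.18)
    tumor_contrast_mri: float = 0.45
    tumor_contrast_ct: float = 0.08
    noise_sigma: float = 0.02
    seed: int = 0
    slices_per_patient: int = 33
    texture_amplitude: float = 0.02
    boundary_amplitude: float = 0.12
    eccentricity_range: tuple[float, float] = (0.7, 1.0)

    def __post_init__(self):
        if self.image_size < 32 or self.image_size % 2:
            raise ValueError("image_size must be even and >= 32")
        lo, hi = self.tumor_radius_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError(f"invalid tumor_radius_range {self.tumor_radius_range}")
        if not self.tumor_contrast_ct < self.tumor_contrast_mri:
            raise ValueError("CT tumor contrast must be below MRI contrast")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")


@dataclass
class ImagePair:
    """One co-registered (CT, MRI) slice with its binary whole-tumor mask."""

    ct: np.ndarray
    mri: np.ndarray
    mask: np.ndarray
    patient_id: str
    slice_index: int

    def __post_init__(self):
        if not (self.ct.shape == self.mri.shape == self.mask.shape):
            raise ValueError("ct, mri and mask must share one shape")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("mask must be binary {0,1}")


def _smooth_noise(rng: np.random.Generator, size: int, sigma_px: float = 2.0) -> np.ndarray:
    """Zero-mean smooth random field with unit-ish amplitude."""
    f = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma_px)
    f -= f.mean()
    m = np.abs(f).max()
    return f / m if m > 0 else f


def generate_phantom(spec: PhantomSpec, index: int) -> ImagePair:
    """Render slice ``index`` of the family; deterministic in (seed, index)."""
    if not 0 <= index < spec.n_samples:
        raise IndexError(f"index {index} out of range [0, {spec.n_samples})")
    s = spec.image_size
    rng = np.random.default_rng([spec.seed, index])

    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    cy = cx = (s - 1) / 2.0

    # head geometry: elliptical skull ring with brain interior
    ax_y, ax_x = 0.46 * s, 0.42 * s
    rho_head = np.sqrt(((yy - cy) / ax_y) ** 2 + ((xx - cx) / ax_x) ** 2)
    brain = rho_head < 0.92
    skull = (rho_head >= 0.92) & (rho_head < 1.0)

    # tumor: perturbed ellipse inside the brain
    r_frac = rng.uniform(*spec.tumor_radius_range)
    r0 = r_frac * s
    ang = rng.uniform(0, 2 * np.pi)
    ecc = rng.uniform(*spec.eccentricity_range)
    margin = 0.45 * s - r0 * 1.3
    tc_y = cy + rng.uniform(-margin, margin) * 0.6
    tc_x = cx + rng.uniform(-margin, margin) * 0.6
    harmonics = rng.integers(2, 5, size=2)
    phases = rng.uniform(0, 2 * np.pi, size=2)
    amps = rng.uniform(0.4, 1.0, size=2)
    amps *= spec.boundary_amplitude / max(amps.sum(), 1e-12)

    dy, dx = yy - tc_y, xx - tc_x
    ry = dy * np.cos(ang) + dx * np.sin(ang)
    rx = -dy * np.sin(ang) + dx * np.cos(ang)
    theta = np.arctan2(ry, rx)
    radius = np.sqrt((ry / ecc) ** 2 + rx ** 2)
    boundary = r0 * (1.0 + sum(a * np.cos(h * theta + p)
                               for a, h, p in zip(amps, harmonics, phases)))
    mask = (radius < boundary) & brain

    # textures (per-modality smooth fields; consumed in fixed order)
    tex_ct = _smooth_noise(rng, s) * spec.texture_amplitude
    tex_mri = _smooth_noise(rng, s) * spec.texture_amplitude

    ct = np.zeros((s, s))
    mri = np.zeros((s, s))
    ct[brain] = 0.35 + tex_ct[brain]
    mri[brain] = 0.40 + tex_mri[brain]
    ct[skull] = 0.90
    mri[skull] = 0.12
    # tumor appears homogeneous, sitting `contrast` above the tissue base
    ct[mask] = 0.35 + spec.tumor_contrast_ct
    mri[mask] = 0.40 + spec.tumor_contrast_mri

    if spec.noise_sigma > 0:
        ct = ct + rng.normal(0, spec.noise_sigma, (s, s))
        mri = mri + rng.normal(0, spec.noise_sigma, (s, s))

    pid = f"P{index // spec.slices_per_patient:03d}"
    return ImagePair(ct=np.clip(ct, 0, 1), mri=np.clip(mri, 0, 1),
                     mask=mask.astype(np.uint8),
                     patient_id=pid,
                     slice_index=index % spec.slices_per_patient)


def tissue_ring(pair: ImagePair, width: int = 6) -> np.ndarray:
    """Boolean ring of brain tissue just outside the tumor mask (for
    contrast measurements); excludes skull and background."""
    dil = ndimage.binary_dilation(pair.mask, iterations=width)
    ring = dil & ~pair.mask.astype(bool)
    s = pair.mask.shape[0]
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    cy = cx = (s - 1) / 2.0
    rho = np.sqrt(((yy - cy) / (0.46 * s)) ** 2 + ((xx - cx) / (0.42 * s)) ** 2)
    return ring & (rho < 0.92)


def _save_png(path: str, arr: np.ndarray, binary: bool = False) -> None:
    if binary:
        data = (arr * 255).astype(np.uint8)
    else:
        data = np.round(np.clip(arr, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path, format="PNG")


def generate_dataset(spec: PhantomSpec, out_dir: str) -> pd.DataFrame:
    """Write the full family as 8-bit PNGs plus a CSV manifest.

    Layout: ``out_dir/{ct,mri,mask}/<patient>_<slice>.png`` and
    ``out_dir/manifest.csv`` with columns patient_id, slice_index and the
    three file paths (relative to ``out_dir``).
    """
    for sub in ("ct", "mri", "mask"):
        os.makedirs(os.path.join(out_dir, sub), exist_ok=True)
    rows = []
    for index in range(spec.n_samples):
        pair = generate_phantom(spec, index)
        stem = f"{pair.patient_id}_{pair.slice_index:03d}.png"
        paths = {sub: os.path.join(sub, stem) for sub in ("ct", "mri", "mask")}
        _save_png(os.path.join(out_dir, paths["ct"]), pair.ct)
        _save_png(os.path.join(out_dir, paths["mri"]), pair.mri)
        _save_png(os.path.join(out_dir, paths["mask"]), pair.mask, binary=True)
        rows.append({"patient_id": pair.patient_id,
                     "slice_index": pair.slice_index,
                     "ct_path": paths["ct"], "mri_path": paths["mri"],
                     "mask_path": paths["mask"]})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
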