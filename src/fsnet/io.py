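"""Reading and writing slice datasets.

On-disk layout: a root directory with ``ct/``, ``mri/`` and ``mask/``
subdirectories of identically named 8/16-bit grayscale PNG or TIFF files
plus a ``manifest.csv`` (columns patient_id, slice_index, ct_path, mri_path,
mask_path).  Intensities are rescaled to [0, 1] by the dtype maximum; masks
are binarized at half range.  NIfTI volumes are sliced axially and resampled
to the network input size.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

from .phantom import ImagePair


def _load_gray(path: str) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        raise ValueError(f"{path}: expected a grayscale image")
    info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
    scale = info.max if info else 1.0
    return arr.astype(np.float64) / scale


@dataclass
class SliceDataset:
    """Manifest plus lazy pixel access for one on-disk dataset."""

    root: str
    manifest: pd.DataFrame

    def __len__(self) -> int:
        return len(self.manifest)

    def load_pair(self, i: int) -> ImagePair:
        row = self.manifest.iloc[i]
        ct = _load_gray(os.path.join(self.root, row["ct_path"]))
        mri = _load_gray(os.path.join(self.root, row["mri_path"]))
        mask = (_load_gray(os.path.join(self.root, row["mask_path"])) >= 0.5)
        return ImagePair(ct=ct, mri=mri, mask=mask.astype(np.uint8),
                         patient_id=str(row["patient_id"]),
                         slice_index=int(row["slice_index"]))

    def load_all(self) -> list[ImagePair]:
        return [self.load_pair(i) for i in range(len(self))]


def read_slice_dataset(root: str) -> SliceDataset:
    """Validate and open a dataset directory.

    Every manifest row's three files must exist, decode, and share one
    shape; all offending paths are reported together.
    """
    manifest_path = os.path.join(root, "manifest.csv")
    if not os.path.isfile(manifest_path):
        raise FileNotFoundError(f"missing manifest: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    required = {"patient_id", "slice_index", "ct_path", "mri_path", "mask_path"}
    missing_cols = required - set(manifest.columns)
    if missing_cols:
        raise ValueError(f"manifest lacks columns: {sorted(missing_cols)}")
    problems = []
    for _, row in manifest.iterrows():
        shapes = {}
        for key in ("ct_path", "mri_path", "mask_path"):
            path = os.path.join(root, row[key])
            if not os.path.isfile(path):
                problems.append(f"missing file: {path}")
                continue
            try:
                shapes[key] = _load_gray(path).shape
            except Exception as exc:
                problems.append(f"undecodable image: {path} ({exc})")
        if len(set(shapes.values())) > 1:
            problems.append(
                f"shape mismatch for {row['ct_path']}: "
                + ", ".join(f"{k}={v}" for k, v in shapes.items()))
    if problems:
        raise ValueError("invalid dataset:\n" + "\n".join(problems))
    return SliceDataset(root=root, manifest=manifest)


def read_nifti_volume(path: str, axis: int = 2, target_size: int = 256,
                      is_mask: bool = False, normalize: str = "minmax"):
    """Slice a NIfTI volume into 2D images resampled to ``target_size``.

    Images use bilinear resampling and per-volume normalization (min-max by
    default, ``zscore`` optional, constant volumes map to zeros); masks use
    nearest-neighbour resampling and stay binary.
    """
    try:
        vol = np.asanyarray(nib.load(path).get_fdata(), dtype=np.float64)
    except Exception as exc:
        raise ValueError(f"unreadable NIfTI volume {path}: {exc}") from exc
    if vol.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {vol.shape}")
    if not is_mask:
        if normalize == "minmax":
            lo, hi = vol.min(), vol.max()
            vol = (vol - lo) / (hi - lo) if hi > lo else np.zeros_like(vol)
        elif normalize == "zscore":
            sd = vol.std()
            vol = (vol - vol.mean()) / sd if sd > 0 else np.zeros_like(vol)
            vol = np.clip((vol + 3) / 6, 0, 1)  # squash to [0,1] for the net
        else:
            raise ValueError("normalize must be 'minmax' or 'zscore'")
    slices = []
    for k in range(vol.shape[axis]):
        sl = np.take(vol, k, axis=axis)
        order = 0 if is_mask else 1
        out = resize(sl, (target_size, target_size), order=order,
                     preserve_range=True, anti_aliasing=False)
        if is_mask:
            out = (out >= 0.5).astype(np.uint8)
        slices.append(out)
    return slices
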