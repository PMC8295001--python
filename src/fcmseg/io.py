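"""Image and label-map I/O for NIfTI and PNG.

Arrays are indexed (row, col[, slice]), 0-based.  NIfTI affines are passed
through untouched; PNG intensity images are read as grayscale floats on
[0, 1]; PNG label maps encode class k as gray level k * floor(255/(K-1)) so
they are human-viewable yet exactly invertible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import nibabel as nib
import numpy as np


@dataclass
class Image:
    """Intensity grid plus (for NIfTI) the spatial metadata for round-trips."""

    values: np.ndarray
    affine: Optional[np.ndarray] = None
    header: Optional[object] = None

    @property
    def shape(self):
        return self.values.shape


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(path) -> Image:
    """Read a NIfTI volume or a 2-D grayscale PNG as float intensities."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        try:
            img = nib.load(str(path))
        except Exception as exc:
            raise ValueError(f"could not read {path} as NIfTI: {exc}") from exc
        values = np.asarray(img.get_fdata(), dtype=np.float64)
        return Image(values=values, affine=img.affine, header=img.header)
    if path.suffix.lower() == ".png":
        try:
            raw = iio.imread(path)
        except Exception as exc:
            raise ValueError(f"could not read {path} as PNG: {exc}") from exc
        if raw.ndim == 3:  # RGB(A): collapse to luminance
            raw = raw[..., :3].mean(axis=-1)
        scale = float(np.iinfo(raw.dtype).max) if np.issubdtype(
            raw.dtype, np.integer) else 1.0
        return Image(values=raw.astype(np.float64) / scale)
    raise ValueError(f"unsupported image format: {path.suffix!r} "
                     "(expected .nii, .nii.gz or .png)")


def write_image(image, path, reference: Optional[Image] = None) -> None:
    """Write float intensities: 16-bit grayscale PNG (2-D) or float32 NIfTI."""
    path = Path(path)
    values = np.asarray(getattr(image, "values", image), dtype=np.float64)
    if _is_nifti(path):
        affine = getattr(image, "affine", None)
        if affine is None and reference is not None:
            affine = reference.affine
        nib.save(nib.Nifti1Image(values.astype(np.float32),
                                 affine if affine is not None else np.eye(4)),
                 str(path))
        return
    if path.suffix.lower() == ".png":
        if values.ndim != 2:
            raise ValueError("PNG output supports 2-D images only")
        if values.min() < 0 or values.max() > 1:
            raise ValueError("PNG output expects intensities in [0, 1]")
        iio.imwrite(path, np.round(values * 65535).astype(np.uint16))
        return
    raise ValueError(f"unsupported image format: {path.suffix!r}")


def write_labelmap(labels, path, reference: Optional[Image] = None) -> None:
    """Write an integer label map; NIfTI inherits the reference affine."""
    path = Path(path)
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("label map must be integer-typed")
    if _is_nifti(path):
        affine = reference.affine if reference is not None else None
        nib.save(nib.Nifti1Image(labels.astype(np.int16),
                                 affine if affine is not None else np.eye(4)),
                 str(path))
        return
    if path.suffix.lower() == ".png":
        if labels.ndim != 2:
            raise ValueError("PNG label output supports 2-D maps only")
        k = int(labels.max()) + 1
        if k > 256:
            raise ValueError("PNG label maps support at most 256 classes")
        step = 255 // (k - 1) if k > 1 else 0
        iio.imwrite(path, (labels * step).astype(np.uint8))
        return
    raise ValueError(f"unsupported label format: {path.suffix!r}")


def read_labelmap(path) -> np.ndarray:
    """Read a label map; PNG gray levels are mapped back to dense 0..K-1 ids."""
    path = Path(path)
    if _is_nifti(path):
        return np.asarray(nib.load(str(path)).get_fdata()).astype(np.int64)
    if path.suffix.lower() == ".png":
        raw = iio.imread(path)
        if raw.ndim == 3:
            raw = raw[..., 0]
        levels = np.unique(raw)
        lut = {v: i for i, v in enumerate(levels)}
        return np.vectorize(lut.get)(raw).astype(np.int64)
    raise ValueError(f"unsupported label format: {path.suffix!r}")
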