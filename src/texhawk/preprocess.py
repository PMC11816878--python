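"""Image normalization: FWHM Gaussian smoothing, resizing, dataset splitting.

Smoothing is specified in millimetres of full width at half maximum (the unit
neuroimaging pipelines report); the conversion to a pixel-space sigma assumes
an isotropic pixel pitch.  Brain extraction is reduced to an optional binary
foreground-mask multiply — full skull stripping is an external-tool concern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize
from sklearn.model_selection import train_test_split

__all__ = [
    "PreprocessConfig",
    "fwhm_to_sigma",
    "gaussian_smooth",
    "resize_image",
    "apply_foreground_mask",
    "split_dataset",
    "load_gray_image",
    "preprocess_image",
]

#: FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian kernel
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class PreprocessConfig:
    fwhm_mm: float = 4.0
    voxel_mm: float = 1.0
    target_size: tuple[int, int] = (224, 224)
    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be > 0")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if min(self.target_size) < 1:
            raise ValueError("target_size must be positive")


def fwhm_to_sigma(fwhm_mm: float, voxel_mm: float = 1.0) -> float:
    """Convert a smoothing kernel FWHM in mm to a Gaussian sigma in pixels."""
    if voxel_mm <= 0:
        raise ValueError(f"voxel_mm must be > 0, got {voxel_mm}")
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    return fwhm_mm / (voxel_mm * FWHM_PER_SIGMA)


def gaussian_smooth(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian-smooth a gray image with reflective boundaries.

    Sigma 0 is the identity.  Reflection avoids edge darkening, so the mean
    intensity is preserved up to floating-point rounding.
    """
    if sigma_px < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma_px}")
    img = np.asarray(image, dtype=np.float64)
    if sigma_px == 0:
        return img.copy()
    return ndimage.gaussian_filter(img, sigma=sigma_px, mode="reflect")


def resize_image(image: np.ndarray, target_size: tuple[int, int], mode: str = "bilinear") -> np.ndarray:
    """Resize to ``target_size``; nearest mode is exact pixel replication."""
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("cannot resize an empty image")
    if min(target_size) < 1:
        raise ValueError(f"target_size must be positive, got {target_size}")
    if mode not in ("bilinear", "nearest"):
        raise ValueError(f"unknown resize mode {mode!r}")
    if tuple(img.shape) == tuple(target_size):
        return img.copy()
    order = 0 if mode == "nearest" else 1
    return _sk_resize(img, target_size, order=order, mode="edge", anti_aliasing=False, preserve_range=True)


def apply_foreground_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero out background pixels given a binary foreground mask."""
    img = np.asarray(image, dtype=np.float64)
    m = np.asarray(mask)
    if m.shape != img.shape:
        raise ValueError(f"mask shape {m.shape} != image shape {img.shape}")
    return img * (m > 0)


def split_dataset(items, train_fraction: float = 0.70, seed: int = 0, stratified: bool = True):
    """Disjoint, exhaustive train/test partition of ``(item, label)`` pairs.

    Stratified mode preserves the class ratio within rounding and requires
    both classes to be present.
    """
    items = list(items)
    if len(items) < 2:
        raise ValueError("need at least 2 items to split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    labels = [lab for _, lab in items]
    strat = labels if stratified else None
    if stratified and len(set(labels)) < 2:
        raise ValueError("stratified split requires both classes present")
    train, test = train_test_split(
        items, train_size=train_fraction, random_state=seed, shuffle=True, stratify=strat
    )
    return train, test


def load_gray_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image from PNG/TIFF or a single-slice NIfTI file."""
    path = Path(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a single-slice NIfTI, got shape {data.shape}")
        return data.astype(np.float64)
    import imageio.v3 as iio

    data = iio.imread(path)
    if data.ndim == 3:  # collapse identical RGB channels
        data = data.mean(axis=-1)
    return data.astype(np.float64)


def preprocess_image(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Smooth (FWHM -> sigma) then resize to the target dims, in that order."""
    config = config or PreprocessConfig()
    sigma = fwhm_to_sigma(config.fwhm_mm, config.voxel_mm)
    return resize_image(gaussian_smooth(image, sigma), config.target_size)
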