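"""Synthetic two-class fixtures: textured gray images and planted feature tables.

Real Alzheimer's MRI collections (ADNI, MIRIAD) are access-restricted, so the
test substrate is generated: (a) image classes that differ in co-occurrence
texture (spatially correlated noise with a controllable blob size — smoother
blobs give lower GLCM contrast and higher homogeneity), and (b) feature tables
in which a known subset of columns carries a class-mean shift, so selection
methods can be scored against ground truth.  Every generator is a pure
function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .table import FeatureTable

__all__ = [
    "TextureClassSpec",
    "PlantedTableSpec",
    "make_textured_image",
    "make_image_dataset",
    "make_planted_feature_table",
]


@dataclass(frozen=True)
class TextureClassSpec:
    """One image class: mean intensity, spatial correlation length, pixel noise.

    ``blob_scale`` is the Gaussian smoothing sigma (pixels) applied to white
    noise before quantization; ``math.inf`` produces a flat field.  ``noise_sd``
    is independent per-pixel noise added after smoothing, in gray levels.
    """

    label: int
    base_level: float
    blob_scale: float = 4.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.blob_scale < 1:
            raise ValueError(f"blob_scale must be >= 1 pixel, got {self.blob_scale}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass(frozen=True)
class PlantedTableSpec:
    """Feature table with a planted informative subset.

    Informative columns are Gaussian with a between-class mean shift of
    ``effect_size`` (in units of the within-class standard deviation); the
    remaining columns are class-independent N(0, 1) noise.  The default 40
    columns mirror a fused 20 deep + 20 texture feature set.
    """

    n_samples: int = 200
    n_features: int = 40
    n_informative: int = 5
    effect_size: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if not 0 < self.n_informative <= self.n_features:
            raise ValueError(
                f"need 0 < n_informative <= n_features, got {self.n_informative}/{self.n_features}"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


def make_textured_image(
    spec: TextureClassSpec,
    size: tuple[int, int] = (64, 64),
    levels: int = 32,
    seed: int = 0,
) -> np.ndarray:
    """Generate one quantized textured image for a class spec.

    White noise is smoothed to ``blob_scale``, standardized, scaled to a fixed
    fraction of the gray range, shifted to ``base_level``, perturbed by pixel
    noise, and rounded into ``[0, levels-1]``.
    """
    h, w = size
    if h < 8 or w < 8:
        raise ValueError(f"image size must be at least 8x8, got {size}")
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    if not 0 <= spec.base_level <= levels - 1:
        raise ValueError(f"base_level {spec.base_level} outside [0, {levels - 1}]")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((h, w))
    pixel_noise = rng.standard_normal((h, w))  # drawn unconditionally to keep the stream stable
    if math.isinf(spec.blob_scale):
        field = np.zeros((h, w))
    else:
        field = ndimage.gaussian_filter(noise, sigma=spec.blob_scale, mode="wrap")
        sd = field.std()
        if sd > 0:
            field = (field - field.mean()) / sd
    amplitude = (levels - 1) / 6.0  # texture spans ~+-3 sd of the gray range
    img = spec.base_level + amplitude * field + spec.noise_sd * pixel_noise
    return np.clip(np.rint(img), 0, levels - 1).astype(np.int64)


def make_image_dataset(
    n_per_class: int,
    specs: tuple[TextureClassSpec, TextureClassSpec],
    size: tuple[int, int] = (64, 64),
    levels: int = 32,
    seed: int = 0,
) -> list[tuple[np.ndarray, int]]:
    """Balanced labeled image set: ``n_per_class`` images from each class spec."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if len(specs) != 2:
        raise ValueError(f"exactly two class specs required, got {len(specs)}")
    if specs[0].label == specs[1].label:
        raise ValueError("class specs must carry distinct labels")
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=2 * n_per_class)
    dataset = []
    for k, spec in enumerate(specs):
        for i in range(n_per_class):
            img = make_textured_image(spec, size=size, levels=levels, seed=int(seeds[k * n_per_class + i]))
            dataset.append((img, spec.label))
    return dataset


def make_planted_feature_table(spec: PlantedTableSpec) -> FeatureTable:
    """Feature table with ``n_informative`` planted class-informative columns.

    Returns a :class:`FeatureTable` whose ``informative`` attribute records the
    planted column names for recovery scoring.  Classes are balanced; the class
    mean of each informative column is ``+-effect_size/2`` (unit within-class
    spread).
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    y = np.zeros(n, dtype=np.int64)
    y[n // 2 :] = 1
    X = rng.standard_normal((n, p))
    informative_idx = np.sort(rng.choice(p, size=spec.n_informative, replace=False))
    shift = spec.effect_size * (y - 0.5)  # -e/2 for class 0, +e/2 for class 1
    X[:, informative_idx] += shift[:, None]
    names = [f"feature_{i:03d}" for i in range(p)]
    frame = pd.DataFrame(X, columns=names)
    return FeatureTable(
        X=frame,
        y=y,
        informative=[names[i] for i in informative_idx],
    )
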