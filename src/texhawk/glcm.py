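"""Gray-level co-occurrence matrices and Haralick-style texture statistics.

A GLCM tabulates, for one spatial offset (distance, angle), how often a pixel
of gray level ``i`` has a neighbor of gray level ``j``.  Its low-order moments
(energy, contrast, homogeneity, correlation, entropy) are classic scalar
texture descriptors.  The angle convention, with image rows increasing
downward, is::

      0 deg -> ( 0, +d)      45 deg -> (-d, +d)
     90 deg -> (-d,  0)     135 deg -> (-d, -d)

Only these four angles are supported; with a symmetric matrix they cover all
eight radius-1 neighbor directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GLCMConfig",
    "GLCMatrix",
    "TextureStats",
    "angle_to_offset",
    "quantize_image",
    "compute_glcm",
    "glcm_statistics",
    "extract_texture_vector",
    "texture_feature_names",
]

#: statistics computed per (distance, angle), in vector order
STAT_NAMES = ("energy", "contrast", "homogeneity", "correlation", "entropy")

_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class GLCMConfig:
    """Parameters of co-occurrence extraction.

    levels
        Number of gray levels the image is represented with (intensities must
        lie in ``[0, levels-1]``).  256 covers full 8-bit range; small fixtures
        typically down-quantize to 16-64 levels.
    distances
        Pixel radii of the offsets (1 or 2 are the usual choices).
    angles_deg
        Offset directions, a subset of {0, 45, 90, 135}.
    symmetric
        Count each pixel pair in both directions (the dominant convention).
    normalize
        Divide counts by their total so entries are pair probabilities.
    """

    levels: int = 256
    distances: tuple[int, ...] = (1,)
    angles_deg: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if not self.distances or any(d < 1 for d in self.distances):
            raise ValueError("distances must be a non-empty list of radii >= 1")
        bad = set(self.angles_deg) - set(_ANGLE_OFFSETS)
        if bad or not self.angles_deg:
            raise ValueError(f"angles must be drawn from {sorted(_ANGLE_OFFSETS)}, got {self.angles_deg}")


@dataclass(frozen=True)
class GLCMatrix:
    """One co-occurrence matrix with its generating offset."""

    p: np.ndarray
    distance: int
    angle_deg: int
    normalized: bool

    def __post_init__(self) -> None:
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError(f"co-occurrence matrix must be square, got shape {self.p.shape}")
        if np.any(self.p < 0):
            raise ValueError("co-occurrence entries must be non-negative")
        if self.normalized and abs(float(self.p.sum()) - 1.0) > 1e-9:
            raise ValueError("normalized GLCM entries must sum to 1")


@dataclass(frozen=True)
class TextureStats:
    energy: float
    contrast: float
    homogeneity: float
    correlation: float
    entropy: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.energy, self.contrast, self.homogeneity, self.correlation, self.entropy)


def angle_to_offset(angle_deg: int, distance: int) -> tuple[int, int]:
    """Map a GLCM angle to a (row, col) displacement at the given radius."""
    if angle_deg not in _ANGLE_OFFSETS:
        raise ValueError(f"unsupported angle {angle_deg}; choose from {sorted(_ANGLE_OFFSETS)}")
    if distance < 1:
        raise ValueError(f"distance must be >= 1, got {distance}")
    dr, dc = _ANGLE_OFFSETS[angle_deg]
    return dr * distance, dc * distance


def quantize_image(image: np.ndarray, levels: int, source_levels: int | None = None) -> np.ndarray:
    """Uniformly bin an integer gray image down to ``levels`` gray levels.

    ``source_levels`` defaults to ``max(image) + 1`` rounded up to the nearest
    power-of-two-ish 8-bit range; pass 256 for 8-bit input explicitly when the
    image does not use its full range.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D gray image")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if source_levels is None:
        source_levels = int(img.max()) + 1
    if source_levels <= levels:
        return img.astype(np.int64)
    out = (img.astype(np.int64) * levels) // source_levels
    return np.clip(out, 0, levels - 1)


def compute_glcm(
    image: np.ndarray,
    config: GLCMConfig,
    offset: tuple[int, int],
) -> GLCMatrix:
    """Count co-occurring gray-level pairs at one (distance, angle) offset.

    Entry ``(i, j)`` counts ordered pixel pairs with reference level ``i`` and
    the neighbor at the offset having level ``j``; optionally symmetrized
    (each pair counted in both directions) and normalized to probabilities.
    """
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D gray image")
    if np.any(img < 0) or np.any(img >= config.levels):
        raise ValueError(f"image intensities must lie in [0, {config.levels - 1}]; quantize first")
    distance, angle_deg = offset
    dr, dc = angle_to_offset(angle_deg, distance)
    h, w = img.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError(f"offset ({dr}, {dc}) exceeds image extent {img.shape}")

    # reference window and its displaced neighbor window
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    ref = img[r0:r1, c0:c1].astype(np.int64).ravel()
    nb = img[r0 + dr : r1 + dr, c0 + dc : c1 + dc].astype(np.int64).ravel()
    if ref.size == 0:
        raise ValueError("offset leaves no valid pixel pairs")

    L = config.levels
    counts = np.bincount(ref * L + nb, minlength=L * L).reshape(L, L).astype(np.float64)
    if config.symmetric:
        counts = counts + counts.T
    if config.normalize:
        counts = counts / counts.sum()
    return GLCMatrix(p=counts, distance=distance, angle_deg=angle_deg, normalized=config.normalize)


def glcm_statistics(glcm: GLCMatrix) -> TextureStats:
    """Energy, contrast, homogeneity, correlation and entropy of one GLCM.

    energy = sum p^2; contrast = sum (i-j)^2 p; homogeneity = sum p/(1+|i-j|);
    correlation = sum (i-mu_i)(j-mu_j) p / (sigma_i sigma_j) (0 when either
    marginal is degenerate); entropy = -sum p log2 p with 0*log(0) = 0.
    """
    if not glcm.normalized:
        raise ValueError("glcm_statistics requires a normalized matrix")
    p = glcm.p
    L = p.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    diff = i - j

    energy = float(np.sum(p * p))
    contrast = float(np.sum(diff * diff * p))
    homogeneity = float(np.sum(p / (1.0 + np.abs(diff))))

    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(np.sum(np.arange(L) * pi))
    mu_j = float(np.sum(np.arange(L) * pj))
    var_i = float(np.sum((np.arange(L) - mu_i) ** 2 * pi))
    var_j = float(np.sum((np.arange(L) - mu_j) ** 2 * pj))
    if var_i <= 0 or var_j <= 0:
        correlation = 0.0  # degenerate marginal: no linear dependence to measure
    else:
        correlation = float(np.sum((i - mu_i) * (j - mu_j) * p) / np.sqrt(var_i * var_j))

    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return TextureStats(energy, contrast, homogeneity, correlation, entropy)


def texture_feature_names(config: GLCMConfig) -> list[str]:
    """Feature names in extraction order: distance-major, then angle, then statistic."""
    return [
        f"glcm:d{d}_a{a}_{s}"
        for d in config.distances
        for a in config.angles_deg
        for s in STAT_NAMES
    ]


def extract_texture_vector(image: np.ndarray, config: GLCMConfig | None = None) -> tuple[np.ndarray, list[str]]:
    """Concatenate texture statistics over all configured offsets.

    The default configuration (distance 1, four angles, five statistics)
    yields exactly 20 named features per image.
    """
    config = config or GLCMConfig()
    values: list[float] = []
    for d in config.distances:
        for a in config.angles_deg:
            stats = glcm_statistics(compute_glcm(image, config, (d, a)))
            values.extend(stats.as_tuple())
    return np.asarray(values, dtype=np.float64), texture_feature_names(config)
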