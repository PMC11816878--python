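"""Deep-feature extraction backends and deep+texture feature fusion.

The deep stage is a pluggable contract: any object with ``name``,
``output_dim``, ``deterministic`` and an ``extract(image)`` method can supply
per-image feature vectors.  The bundled backend is a fixed random-feature
convolutional network — seeded, untrained convolution/ReLU/pooling layers
followed by global average pooling and a seeded linear projection to the
output dimension.  Random convolutional features are a standard cheap image
embedding; they are deterministic, require no weight files, and preserve
enough spatial statistics to separate texture classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import ndimage

__all__ = [
    "FeatureExtractorBackend",
    "RandomConvBackend",
    "extract_deep_features",
    "fuse_features",
    "FusionScaler",
    "FusedFeatureVector",
]


@runtime_checkable
class FeatureExtractorBackend(Protocol):
    """Contract every deep-feature backend satisfies."""

    name: str
    output_dim: int
    deterministic: bool

    def extract(self, image: np.ndarray) -> np.ndarray: ...


@dataclass
class RandomConvBackend:
    """Seeded random-projection convolutional stack.

    Two convolution + ReLU + average-pooling stages, global average pooling,
    then a fixed linear projection to ``output_dim``.  All weights are drawn
    once from ``seed``; extraction is a pure function of the image.
    ``center_input`` subtracts the image mean first, which makes features
    invariant to constant intensity shifts.
    """

    output_dim: int = 20
    seed: int = 0
    n_kernels: tuple[int, int] = (8, 16)
    kernel_size: int = 3
    pool: int = 4
    center_input: bool = True
    name: str = "random-conv"
    deterministic: bool = True

    def __post_init__(self) -> None:
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")
        rng = np.random.default_rng(self.seed)
        k = self.kernel_size
        c1, c2 = self.n_kernels
        # He-style scaling keeps activations O(1) through the stack
        self._k1 = rng.standard_normal((c1, k, k)) * np.sqrt(2.0 / (k * k))
        self._k2 = rng.standard_normal((c2, c1, k, k)) * np.sqrt(2.0 / (c1 * k * k))
        self._proj = rng.standard_normal((self.output_dim, c2)) / np.sqrt(c2)

    def _pool(self, x: np.ndarray) -> np.ndarray:
        p = self.pool
        h, w = x.shape[-2] // p * p, x.shape[-1] // p * p
        x = x[..., :h, :w]
        return x.reshape(*x.shape[:-2], h // p, p, w // p, p).mean(axis=(-3, -1))

    def extract(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=np.float64)
        if img.ndim != 2:
            raise ValueError("expected a 2-D gray image")
        if min(img.shape) < self.pool * self.pool:
            raise ValueError(f"image {img.shape} too small for two {self.pool}x pooling stages")
        if self.center_input:
            img = img - img.mean()
        scale = img.std()
        if scale > 0:
            img = img / scale
        a1 = np.stack([ndimage.convolve(img, k, mode="reflect") for k in self._k1])
        a1 = self._pool(np.maximum(a1, 0.0))
        a2 = np.stack(
            [
                sum(ndimage.convolve(a1[c], self._k2[m, c], mode="reflect") for c in range(a1.shape[0]))
                for m in range(self._k2.shape[0])
            ]
        )
        a2 = self._pool(np.maximum(a2, 0.0))
        gap = a2.mean(axis=(-2, -1))
        return self._proj @ gap


def extract_deep_features(image: np.ndarray, backend: FeatureExtractorBackend) -> np.ndarray:
    """Run one image through a backend and validate the output contract."""
    vec = np.asarray(backend.extract(image), dtype=np.float64)
    if vec.shape != (backend.output_dim,):
        raise ValueError(f"backend {backend.name!r} returned shape {vec.shape}, expected ({backend.output_dim},)")
    if not np.all(np.isfinite(vec)):
        raise ValueError(f"backend {backend.name!r} produced non-finite features")
    return vec


@dataclass(frozen=True)
class FusedFeatureVector:
    """Deep-then-texture concatenation with provenance-tagged names."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values/names length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("fused feature names must be unique")


def fuse_features(
    deep: np.ndarray,
    texture: np.ndarray,
    deep_names: list[str] | None = None,
    texture_names: list[str] | None = None,
) -> FusedFeatureVector:
    """Concatenate deep and texture features (deep first) with tagged names."""
    deep = np.asarray(deep, dtype=np.float64)
    texture = np.asarray(texture, dtype=np.float64)
    if not (np.all(np.isfinite(deep)) and np.all(np.isfinite(texture))):
        raise ValueError("fuse_features requires finite inputs")
    if deep_names is None:
        deep_names = [f"deep:{i:03d}" for i in range(deep.size)]
    if texture_names is None:
        texture_names = [f"glcm:{i:03d}" for i in range(texture.size)]
    names = tuple(deep_names) + tuple(texture_names)
    return FusedFeatureVector(values=np.concatenate([deep, texture]), names=names)


class FusionScaler:
    """Per-feature standardization fit on the training split only.

    Columns are shifted/scaled to mean 0, spread 1 using training statistics;
    the same statistics are reused at test time so no test information leaks
    into the representation.  Zero-variance columns are left centered only.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FusionScaler":
        X = np.asarray(X, dtype=np.float64)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.scale_ = sd
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None or self.scale_ is None:
            raise RuntimeError("FusionScaler used before fit")
        return (np.asarray(X, dtype=np.float64) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)
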