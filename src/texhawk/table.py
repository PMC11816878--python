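"""Shared in-memory container for labeled feature tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureTable"]


@dataclass
class FeatureTable:
    """Samples x named features with binary labels.

    ``X`` holds one column per feature; ``y`` the 0/1 labels.  ``informative``
    optionally records ground-truth informative column names for synthetic
    tables with planted signal.
    """

    X: pd.DataFrame
    y: np.ndarray
    informative: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        if len(self.X) != len(self.y):
            raise ValueError(f"{len(self.X)} rows vs {len(self.y)} labels")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if self.informative is not None:
            missing = set(self.informative) - set(self.X.columns)
            if missing:
                raise ValueError(f"informative columns not in table: {sorted(missing)}")

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def values(self) -> np.ndarray:
        return self.X.to_numpy(dtype=np.float64)

    def subset(self, mask_bits: np.ndarray) -> "FeatureTable":
        """Restrict to the columns selected by a binary mask."""
        bits = np.asarray(mask_bits).astype(bool)
        if bits.size != self.n_features:
            raise ValueError(f"mask length {bits.size} != {self.n_features} features")
        return FeatureTable(X=self.X.loc[:, bits], y=self.y.copy(), informative=self.informative)

    def to_csv(self, path: str | Path) -> None:
        out = self.X.copy()
        out["label"] = self.y
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        frame = pd.read_csv(path)
        if "label" not in frame.columns:
            raise ValueError("feature CSV must contain a 'label' column")
        y = frame.pop("label").to_numpy()
        return cls(X=frame, y=y)
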