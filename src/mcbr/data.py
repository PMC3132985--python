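"""Dataset container and centering utilities."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RegressionDataset", "CenteringRecord", "center_dataset"]

# The model has no explicit prior on the intercept; fitting runs on
# column-centered X and mean-centered y, and the intercept is recovered as
# mean(y) - mean_row(X) @ w at prediction time.


@dataclass
class RegressionDataset:
    """An (X, y) regression pair, optionally with voxel geometry.

    Rows of ``X`` are samples (e.g. activation images), columns are
    features (voxels); ``y`` is the continuous behavioral target.
    ``feature_coords`` holds one integer (x, y, z) triple per feature for
    volumetric data, in the package-wide x-fastest linear order.
    """

    X: np.ndarray
    y: np.ndarray
    feature_coords: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite entries")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite entries")
        if self.y.shape[0] != self.X.shape[0]:
            raise ValueError(
                f"y has {self.y.shape[0]} entries but X has {self.X.shape[0]} rows"
            )
        if self.feature_coords is not None:
            self.feature_coords = np.asarray(self.feature_coords, dtype=int)
            if self.feature_coords.shape != (self.X.shape[1], 3):
                raise ValueError("feature_coords must have shape (p, 3)")
            if len({tuple(c) for c in self.feature_coords}) != self.X.shape[1]:
                raise ValueError("feature_coords must be unique")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class CenteringRecord:
    """Column means of X and mean of y removed before inference."""

    x_mean: np.ndarray
    y_mean: float

    def intercept(self, w: np.ndarray) -> float:
        """Intercept of the uncentered affine model given centered-fit weights."""
        return float(self.y_mean - self.x_mean @ w)


def center_dataset(data: RegressionDataset) -> tuple[RegressionDataset, CenteringRecord]:
    """Column-center X and mean-center y; return the centered data and means."""
    if data.n < 2:
        raise ValueError("centering requires at least 2 samples")
    x_mean = data.X.mean(axis=0)
    y_mean = float(data.y.mean())
    centered = RegressionDataset(
        X=data.X - x_mean,
        y=data.y - y_mean,
        feature_coords=data.feature_coords,
        meta=dict(data.meta),
    )
    return centered, CenteringRecord(x_mean=x_mean, y_mean=y_mean)


def check_target_scale(y: np.ndarray) -> None:
    """Warn when y is badly scaled for the universal priors.

    The class-specific priors are calibrated for targets whose variance is
    within a few orders of magnitude of 1; outside [1e-2, 1e3] the ladder
    of prior precisions may not bracket the weight scale.
    """
    v = float(np.var(y))
    if v > 0 and not (1e-2 <= v <= 1e3):
        warnings.warn(
            f"sample variance of y is {v:.3g}, outside [1e-2, 1e3]; consider "
            "standardizing the target (standardize_y=True)",
            UserWarning,
            stacklevel=3,
        )
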