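"""Synthetic benchmarks with known ground truth.

Two generators are provided:

``make_sparse_regression``
    An ill-posed sparse design (p = 200, n = 50 train + 50 test by
    default): i.i.d. standard-normal features with

        y = 2(X1 + X2 - X3 - X4) + 0.5(X5 + X6 - X7 - X8) + eps,
        eps ~ N(0, 1),

    so 8 of 200 features are informative (four strong, four weak) and
    var(y) = 4*4 + 0.25*4 + 1 = 18.

``make_volumetric``
    100 images of 12x12x12 standard-normal voxels, Gaussian-smoothed
    (sd 2 voxels) to mimic the spatial correlation of real fMRI data.
    Four 2x2x2 regions of interest carry weights (-0.5, 0.5, -0.5, 0.5);
    per image, half of the 32 informative voxel weights are dropped
    (spatial variability), and noise is scaled for a 5 dB signal-to-noise
    ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .data import RegressionDataset

__all__ = [
    "SimulationTruth",
    "make_sparse_regression",
    "make_volumetric",
    "snr_noise_sd",
]


@dataclass
class SimulationTruth:
    """Generating weights and support for recovery scoring."""

    w_true: np.ndarray
    support: np.ndarray          # indices of nonzero generating weights
    noise_sd: float
    roi_blocks: list | None = None       # [(origin triple, weight), ...]
    dropout_masks: np.ndarray | None = None   # (n, p) 0/1, zeros only in support

    def __post_init__(self):
        self.w_true = np.asarray(self.w_true, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        if not np.array_equal(np.sort(self.support), np.flatnonzero(self.w_true)):
            raise ValueError("support must index the nonzero entries of w_true")
        if self.dropout_masks is not None:
            off_support = np.delete(self.dropout_masks, self.support, axis=1)
            if not np.all(off_support == 1):
                raise ValueError("dropout may only zero weights inside the support")


def make_sparse_regression(
    n_train: int = 50,
    n_test: int = 50,
    p: int = 200,
    seed: int | None = None,
) -> tuple[RegressionDataset, RegressionDataset, SimulationTruth]:
    """Sparse ill-posed regression benchmark; returns (train, test, truth)."""
    if p < 8:
        raise ValueError("the design requires p >= 8")
    rng = np.random.default_rng(seed)
    w_true = np.zeros(p)
    w_true[:8] = [2.0, 2.0, -2.0, -2.0, 0.5, 0.5, -0.5, -0.5]
    n = n_train + n_test
    X = rng.standard_normal((n, p))
    y = X @ w_true + rng.standard_normal(n)
    meta = {"design": "sparse_regression", "seed": seed}
    train = RegressionDataset(X=X[:n_train], y=y[:n_train], meta=dict(meta, split="train"))
    test = RegressionDataset(X=X[n_train:], y=y[n_train:], meta=dict(meta, split="test"))
    truth = SimulationTruth(w_true=w_true, support=np.arange(8), noise_sd=1.0)
    return train, test, truth


def snr_noise_sd(signal_variance: float, snr_db: float) -> float:
    """Noise sd giving 10 log10(var(signal)/var(noise)) = snr_db."""
    if signal_variance <= 0:
        raise ValueError("signal_variance must be positive")
    return float(np.sqrt(signal_variance / 10.0 ** (snr_db / 10.0)))


def _roi_origins(grid: tuple, roi_size: tuple, n_rois: int) -> list[tuple]:
    """Deterministic ROI corners: one per octant, offset 2 voxels from the faces."""
    lows, highs = [], []
    for g, s in zip(grid, roi_size):
        lows.append(2)
        highs.append(g - 2 - s)
    octants = [(0, 0, 0), (1, 1, 0), (1, 0, 1), (0, 1, 1),
               (1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1)]
    origins = []
    for oc in octants[:n_rois]:
        origins.append(tuple(highs[a] if oc[a] else lows[a] for a in range(3)))
    return origins


def make_volumetric(
    n: int = 100,
    grid: tuple = (12, 12, 12),
    roi_size: tuple = (2, 2, 2),
    roi_weights: tuple = (-0.5, 0.5, -0.5, 0.5),
    smooth_sd: float = 2.0,
    dropout: float = 0.5,
    snr_db: float = 5.0,
    seed: int | None = None,
) -> tuple[RegressionDataset, SimulationTruth]:
    """Volumetric benchmark; returns (dataset, truth).

    Voxel volumes are drawn i.i.d. N(0, 1) and smoothed with an isotropic
    Gaussian kernel (zero padding at the boundary, kernel truncated at
    4 sd).  The target is the weighted sum of the *smoothed* in-support
    voxels after the per-image dropout, plus Gaussian noise scaled to the
    requested SNR (signal variance estimated empirically from the n
    noiseless targets).  Features are flattened x-fastest and
    ``feature_coords`` is populated.
    """
    grid = tuple(int(g) for g in grid)
    roi_size = tuple(int(s) for s in roi_size)
    n_rois = len(roi_weights)
    origins = _roi_origins(grid, roi_size, n_rois)

    # weight volume; overlapping or out-of-bounds ROIs are an error
    w_vol = np.zeros(grid)
    occupied = np.zeros(grid, dtype=bool)
    blocks = []
    for origin, wt in zip(origins, roi_weights):
        sl = tuple(slice(o, o + s) for o, s in zip(origin, roi_size))
        for o, s, g in zip(origin, roi_size, grid):
            if o < 0 or o + s > g:
                raise ValueError("ROI does not fit inside the grid")
        if occupied[sl].any():
            raise ValueError("ROIs overlap")
        occupied[sl] = True
        w_vol[sl] = wt
        blocks.append((origin, float(wt)))

    rng = np.random.default_rng(seed)
    vols = rng.standard_normal((n, *grid))
    smoothed = gaussian_filter(
        vols, sigma=(0.0, smooth_sd, smooth_sd, smooth_sd),
        mode="constant", cval=0.0, truncate=4.0,
    )

    # x-fastest flattening shared by readers, writers and map export
    p = int(np.prod(grid))
    X = np.stack([smoothed[l].ravel(order="F") for l in range(n)])
    w_flat = w_vol.ravel(order="F")
    support = np.flatnonzero(w_flat)
    coords = np.stack(np.unravel_index(np.arange(p), grid, order="F"), axis=1)

    # per-image retained support: exactly (1 - dropout) of the ROI voxels
    n_drop = int(round(dropout * support.size))
    masks = np.ones((n, p), dtype=int)
    for l in range(n):
        dropped = rng.choice(support, size=n_drop, replace=False)
        masks[l, dropped] = 0

    y0 = np.einsum("lp,p->l", X[:, support] * masks[:, support], w_flat[support])
    gamma = snr_noise_sd(float(np.var(y0)), snr_db)
    y = y0 + rng.normal(0.0, gamma, size=n)

    achieved = 10.0 * np.log10(np.var(y0) / gamma**2)
    data = RegressionDataset(
        X=X,
        y=y,
        feature_coords=coords,
        meta={
            "design": "volumetric",
            "grid": grid,
            "seed": seed,
            "snr_db_target": snr_db,
            "snr_db_achieved": float(achieved),
            "noise_sd": gamma,
        },
    )
    truth = SimulationTruth(
        w_true=w_flat,
        support=support,
        noise_sd=gamma,
        roi_blocks=blocks,
        dropout_masks=masks,
    )
    return data, truth
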