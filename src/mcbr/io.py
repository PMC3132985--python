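"""Dataset and configuration I/O.

Three dataset formats are supported:

* delimited text — one table with feature columns plus a target column
  (default name ``y``);
* binary array pairs — ``<stem>_X.npy`` / ``<stem>_y.npy``;
* volumetric NIfTI — a 4-D image stack plus a 3-D binary mask; rows are
  images and columns are in-mask voxels in x-fastest linear order
  (index = x + nx*y + nx*ny*z), the single convention shared by the
  reader, the writer and the weight-map export, so fitted weight vectors
  can be written back as NIfTI maps.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import RegressionDataset

__all__ = [
    "read_delimited",
    "write_delimited",
    "read_array_pair",
    "write_array_pair",
    "read_nifti",
    "write_nifti_dataset",
    "write_weight_map",
    "load_config",
    "save_config",
    "validate_config",
]


# -- delimited text ---------------------------------------------------------

def read_delimited(path, target: str = "y") -> RegressionDataset:
    df = pd.read_csv(path, sep=None, engine="python")
    if target not in df.columns:
        raise ValueError(f"target column {target!r} not found in {path}")
    y = df[target].to_numpy(dtype=float)
    X = df.drop(columns=[target]).to_numpy(dtype=float)
    return RegressionDataset(X=X, y=y, meta={"source": str(path)})


def write_delimited(path, data: RegressionDataset, target: str = "y") -> None:
    df = pd.DataFrame(data.X, columns=[f"x{j}" for j in range(data.p)])
    df[target] = data.y
    df.to_csv(path, index=False)


# -- binary array pairs -----------------------------------------------------

def read_array_pair(stem) -> RegressionDataset:
    stem = Path(stem)
    X = np.load(stem.parent / f"{stem.name}_X.npy")
    y = np.load(stem.parent / f"{stem.name}_y.npy")
    return RegressionDataset(X=X, y=y, meta={"source": str(stem)})


def write_array_pair(stem, data: RegressionDataset) -> None:
    stem = Path(stem)
    np.save(stem.parent / f"{stem.name}_X.npy", data.X)
    np.save(stem.parent / f"{stem.name}_y.npy", data.y)


# -- NIfTI ------------------------------------------------------------------

def _mask_linear_index(mask: np.ndarray) -> np.ndarray:
    """In-mask voxel indices in the x-fastest linear order."""
    return np.flatnonzero(mask.ravel(order="F"))


def read_nifti(image_path, mask_path, y=None) -> RegressionDataset:
    """Extract an (images x in-mask voxels) matrix from a 4-D stack.

    ``y`` may be given directly or read separately; when absent a zero
    target placeholder is stored (prediction-only use).
    """
    import nibabel as nib

    img = nib.load(str(image_path))
    mask_img = nib.load(str(mask_path))
    vols = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(mask_img.dataobj) > 0
    if vols.ndim != 4:
        raise ValueError("image stack must be 4-D (x, y, z, images)")
    if mask.shape != vols.shape[:3]:
        raise ValueError("mask shape must match the image grid")
    idx = _mask_linear_index(mask)
    n = vols.shape[3]
    flat = vols.reshape(-1, n, order="F")  # (p_total, n), x-fastest rows
    X = flat[idx].T
    coords = np.stack(np.unravel_index(idx, mask.shape, order="F"), axis=1)
    y = np.zeros(n) if y is None else np.asarray(y, dtype=float)
    return RegressionDataset(
        X=X,
        y=y,
        feature_coords=coords,
        meta={"source": str(image_path), "mask": str(mask_path), "grid": mask.shape},
    )


def write_nifti_dataset(image_path, mask_path, data: RegressionDataset, grid) -> None:
    """Write a dataset as a 4-D NIfTI stack plus an all-ones mask."""
    import nibabel as nib

    grid = tuple(grid)
    vols = data.X.T.reshape(*grid, data.n, order="F")
    nib.save(nib.Nifti1Image(vols, np.eye(4)), str(image_path))
    nib.save(
        nib.Nifti1Image(np.ones(grid, dtype=np.uint8), np.eye(4)), str(mask_path)
    )


def write_weight_map(path, w: np.ndarray, mask_path) -> None:
    """Write a per-voxel vector (weights, class labels, ...) back as NIfTI."""
    import nibabel as nib

    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    idx = _mask_linear_index(mask)
    if idx.size != w.shape[0]:
        raise ValueError(
            f"vector has {w.shape[0]} entries but mask has {idx.size} voxels"
        )
    flat = np.zeros(mask.size)
    flat[idx] = w
    vol = flat.reshape(mask.shape, order="F")
    nib.save(nib.Nifti1Image(vol, mask_img.affine), str(path))


# -- run configuration ------------------------------------------------------

CONFIG_KEYS = {
    "simulate": {
        "kind", "out_dir", "format", "seed", "n_train", "n_test", "p",
        "n", "grid", "smooth_sd", "dropout", "snr_db",
    },
    "fit": {
        "data", "target", "image", "mask", "engine", "preset", "k",
        "iters", "burn_in", "seed", "out", "trace", "standardize_y",
    },
    "predict": {"model", "data", "target", "out"},
    "evaluate": {"model", "data", "target", "truth", "out"},
    "benchmark": {"trials", "seed", "out_dir", "methods", "reference"},
}


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(path, cfg: dict) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def validate_config(cfg: dict, command: str) -> dict:
    """Reject unknown keys by name; return the config unchanged."""
    allowed = CONFIG_KEYS[command]
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(
            f"unknown config keys for {command!r}: {sorted(unknown)}"
        )
    return cfg
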