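"""The MCBR model and its fitted-results object.

Multiclass sparse Bayesian regression is the linear model

    y = X w + b + eps,    eps ~ N(0, alpha^-1 I),

in which each weight w_j has a zero-mean Gaussian prior whose precision
lambda_{z_j} is shared within a latent class z_j in {0, ..., K-1}.  The
class precisions carry Gamma(lambda1_k, lambda2_k) priors, the noise
precision a Gamma(alpha1, alpha2) prior, and the class proportions pi a
symmetric Dirichlet(eta) prior; labels themselves are categorical given
pi.  K = 1 recovers Bayesian ridge regression and K = p with frozen
singleton labels recovers automatic relevance determination, so the model
interpolates between global and per-feature regularization while learning
the grouping from the data.

Usage mirrors statsmodels::

    model = MCBR(y, X)                      # universal K = 9 priors
    res = model.fit(method="gibbs", seed=0)
    res.summary()
    res.predict(X_new)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data import CenteringRecord, RegressionDataset, center_dataset, check_target_scale
from .hyperparams import (
    GIBBS_DEFAULT_BURN_IN,
    GIBBS_DEFAULT_N_ITER,
    VB_DEFAULT_N_ITER,
    MCBRHyperparams,
    gamma_log_density,
    universal_hyperparams,
)

__all__ = ["MCBR", "MCBRResults", "joint_log_density", "predict"]


def joint_log_density(
    y: np.ndarray,
    X: np.ndarray,
    w: np.ndarray,
    alpha: float,
    lam: np.ndarray,
    z: np.ndarray,
    pi: np.ndarray,
    hp: MCBRHyperparams,
) -> float:
    """Log of the full joint p(y, w, alpha, lambda, z, pi) on centered data.

    The single source of truth for the generative model: the sum of the
    Gaussian likelihood, the Gaussian weight prior with per-feature
    precision lambda_{z_j}, the Gamma priors on alpha and each lambda_k,
    the categorical label prior given pi, and the Dirichlet prior on pi.
    Both inference engines' conditionals/updates are derived from it.
    """
    n, p = X.shape
    resid = y - X @ w
    lam_z = lam[z]
    log2pi = np.log(2.0 * np.pi)

    ll = 0.5 * n * (np.log(alpha) - log2pi) - 0.5 * alpha * float(resid @ resid)
    lw = 0.5 * float(np.sum(np.log(lam_z))) - 0.5 * p * log2pi - 0.5 * float(
        lam_z @ w**2
    )
    la = gamma_log_density(alpha, hp.alpha1, hp.alpha2)
    llam = float(np.sum(gamma_log_density(lam, hp.lambda1, hp.lambda2)))
    lz = float(np.sum(np.log(pi[z])))
    lpi = float(
        gammaln(hp.K * hp.eta)
        - hp.K * gammaln(hp.eta)
        + (hp.eta - 1.0) * np.sum(np.log(pi))
    )
    return ll + lw + la + llam + lz + lpi


def predict(X_new: np.ndarray, w: np.ndarray, intercept: float) -> np.ndarray:
    """Affine prediction X_new @ w + b."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != w.shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} features, model has {w.shape[0]}"
        )
    return X_new @ w + intercept


class MCBR:
    """Multiclass sparse Bayesian regression model.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Continuous target (the behavioral variable).
    exog : array-like, shape (n, p)
        Feature matrix; rows are samples (images), columns features (voxels).
    hyperparams : MCBRHyperparams, optional
        Prior constants; defaults to the universal K = 9 preset.
    feature_coords : array-like of int, shape (p, 3), optional
        Voxel grid positions for volumetric data.
    standardize_y : bool
        If True, y is scaled to unit variance before fitting and
        predictions are returned on the original scale.  Off by default;
        a warning is emitted when var(y) falls outside [1e-2, 1e3].
    """

    def __init__(
        self,
        endog,
        exog,
        hyperparams: MCBRHyperparams | None = None,
        feature_coords=None,
        meta: dict | None = None,
        standardize_y: bool = False,
    ):
        self.data = RegressionDataset(
            X=np.asarray(exog, dtype=float),
            y=np.asarray(endog, dtype=float),
            feature_coords=feature_coords,
            meta=meta or {},
        )
        self.hyperparams = hyperparams if hyperparams is not None else universal_hyperparams()
        if self.hyperparams.fixed_assignments and self.hyperparams.K != self.data.p:
            raise ValueError("fixed-assignment (ARD) hyperparams require K == p")
        self.standardize_y = standardize_y
        self._y_scale = float(np.std(self.data.y)) if standardize_y else 1.0
        if standardize_y and self._y_scale == 0:
            raise ValueError("cannot standardize a constant target")
        if not standardize_y:
            check_target_scale(self.data.y)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_dataset(cls, data: RegressionDataset, **kwargs) -> "MCBR":
        return cls(
            data.y,
            data.X,
            feature_coords=data.feature_coords,
            meta=data.meta,
            **kwargs,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target: str = "y", **kwargs) -> "MCBR":
        """Build from a DataFrame with one target column, rest features."""
        if target not in df.columns:
            raise ValueError(f"target column {target!r} not in dataframe")
        y = df[target].to_numpy(dtype=float)
        X = df.drop(columns=[target]).to_numpy(dtype=float)
        return cls(y, X, **kwargs)

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        method: str = "gibbs",
        n_iter: int | None = None,
        burn_in: int | None = None,
        seed: int | None = None,
        tol: float = 1e-8,
        keep_trace: bool = False,
        trace_stream=None,
    ) -> "MCBRResults":
        """Fit by Gibbs sampling (``method="gibbs"``) or mean-field VB.

        ``n_iter``/``burn_in``/``seed`` override the values stored in the
        hyperparameters; engine defaults are 5000/4000 sweeps for Gibbs
        and 500 cycles for VB.  ``tol`` is the relative free-energy early
        stop for VB.
        """
        from .gibbs import run_gibbs
        from .vb import run_vb

        hp = self.hyperparams
        if seed is None:
            seed = hp.seed
        rng = np.random.default_rng(seed)

        y_work = self.data.y / self._y_scale
        work = RegressionDataset(
            X=self.data.X, y=y_work, feature_coords=self.data.feature_coords
        )
        centered, record = center_dataset(work)

        if method == "gibbs":
            n_iter = n_iter if n_iter is not None else (hp.n_iter or GIBBS_DEFAULT_N_ITER)
            if burn_in is None:
                burn_in = hp.burn_in if hp.burn_in is not None else min(
                    GIBBS_DEFAULT_BURN_IN, int(0.8 * n_iter)
                )
            out = run_gibbs(
                centered.y,
                centered.X,
                hp,
                n_iter=n_iter,
                burn_in=burn_in,
                rng=rng,
                keep_trace=keep_trace,
                trace_stream=trace_stream,
            )
            z_prob = np.zeros((self.data.p, hp.K))
            z_prob[np.arange(self.data.p), out["z"]] = 1.0
            out["z_prob"] = z_prob
            out["converged"] = True
        elif method == "vb":
            n_iter = n_iter if n_iter is not None else VB_DEFAULT_N_ITER
            burn_in = 0
            out = run_vb(centered.y, centered.X, hp, n_iter=n_iter, rng=rng, tol=tol)
        else:
            raise ValueError(f"unknown method {method!r}; use 'gibbs' or 'vb'")

        # rescale back to the original target units
        record = CenteringRecord(
            x_mean=record.x_mean, y_mean=record.y_mean * self._y_scale
        )
        return MCBRResults(
            model=self,
            method=method,
            w=out["w"] * self._y_scale,
            centering=record,
            alpha=out["alpha"],
            lam=out["lam"],
            z=out["z"],
            z_prob=out["z_prob"],
            pi=out["pi"],
            occupancy=out["occupancy"],
            trace=out.get("trace"),
            converged=out["converged"],
            n_iter=n_iter,
            burn_in=burn_in,
            seed=seed,
            y_scale=self._y_scale,
        )


class MCBRResults:
    """Posterior point estimates and diagnostics of a fitted MCBR model.

    Attributes
    ----------
    params : ndarray (p,)
        Weight estimate on the original target scale (post-burn-in mean
        for Gibbs, variational mean for VB).
    intercept : float
        Recovered from the centering record.
    alpha : float
        Noise-precision point estimate (on the working target scale).
    lam : ndarray (K,)
        Class precision estimates.
    z : ndarray (p,) of int
        Class assignment, in {0..K-1}: final sweep for Gibbs, argmax
        responsibility for VB.
    z_prob : ndarray (p, K)
        Row-stochastic class membership (one-hot for Gibbs).
    pi : ndarray (K,)
        Class proportion estimate.
    occupancy : ndarray (K,) of int
        Hard class sizes; sums to p.
    trace : dict
        Per-iteration diagnostics (``alpha`` and optional ``w`` for Gibbs,
        ``free_energy`` for VB).
    """

    def __init__(
        self,
        model: MCBR | None,
        method: str,
        w: np.ndarray,
        centering: CenteringRecord,
        alpha: float,
        lam: np.ndarray,
        z: np.ndarray,
        z_prob: np.ndarray,
        pi: np.ndarray,
        occupancy: np.ndarray,
        trace: dict | None,
        converged: bool,
        n_iter: int,
        burn_in: int,
        seed: int | None,
        y_scale: float = 1.0,
    ):
        row_sums = z_prob.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ValueError("z_prob rows must sum to 1")
        if not np.allclose(pi.sum(), 1.0, atol=1e-9):
            raise ValueError("pi must sum to 1")
        if not np.array_equal(np.bincount(z, minlength=lam.shape[0]), occupancy):
            raise ValueError("occupancy inconsistent with z")
        self.model = model
        self.method = method
        self.y_scale = y_scale
        self.w = w
        self.centering = centering
        self.alpha = float(alpha)
        self.lam = lam
        self.z = z
        self.z_prob = z_prob
        self.pi = pi
        self.occupancy = occupancy
        self.trace = trace
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.burn_in = int(burn_in)
        self.seed = seed

    # statsmodels-style aliases
    @property
    def params(self) -> np.ndarray:
        return self.w

    @property
    def intercept(self) -> float:
        return self.centering.intercept(self.w)

    @property
    def K(self) -> int:
        return self.lam.shape[0]

    @property
    def p(self) -> int:
        return self.w.shape[0]

    def predict(self, X_new) -> np.ndarray:
        return predict(X_new, self.w, self.intercept)

    def score(self, X, y) -> float:
        """Explained-variance ratio zeta on (X, y)."""
        from .evaluation import explained_variance

        return explained_variance(np.asarray(y, dtype=float), self.predict(X))

    # -- reporting --------------------------------------------------------
    def class_table(self) -> pd.DataFrame:
        """One row per class: precision, proportion, size, mean |w|."""
        rows = []
        for k in range(self.K):
            members = self.z == k
            rows.append(
                {
                    "class": k,
                    "precision": self.lam[k],
                    "pi": self.pi[k],
                    "size": int(self.occupancy[k]),
                    "mean_abs_w": float(np.mean(np.abs(self.w[members])))
                    if members.any()
                    else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Multiclass Sparse Bayesian Regression Results",
            "=" * 45,
            f"Engine:            {'Gibbs sampling' if self.method == 'gibbs' else 'variational Bayes'}",
            f"No. features (p):  {self.p}",
            f"Classes (K):       {self.K}",
            f"Iterations:        {self.n_iter} (burn-in {self.burn_in})"
            if self.method == "gibbs"
            else f"Iterations:        {self.n_iter} (converged: {self.converged})",
            f"Noise precision:   {self.alpha:.4g}",
            f"Intercept:         {self.intercept:.4g}",
        ]
        if self.method == "vb" and self.trace and "free_energy" in self.trace:
            lines.append(f"Free energy:       {self.trace['free_energy'][-1]:.6g}")
        lines.append("")
        occupied = self.class_table()
        occupied = occupied[occupied["size"] > 0]
        lines.append("Occupied classes:")
        lines.append(
            occupied.to_string(
                index=False,
                formatters={
                    "precision": "{:.3g}".format,
                    "pi": "{:.3f}".format,
                    "mean_abs_w": "{:.4g}".format,
                },
            )
        )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<MCBRResults method={self.method!r} p={self.p} K={self.K} "
            f"occupied={int((self.occupancy > 0).sum())}>"
        )

    # -- plotting ---------------------------------------------------------
    def plot_weight_distribution(self, ax=None, bins: int = 60):
        """Histogram of fitted weights, colored markers showing class labels."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.w, bins=bins, color="lightgray", edgecolor="k")
        cmap = plt.get_cmap("tab10")
        for k in np.flatnonzero(self.occupancy):
            members = self.w[self.z == k]
            ax.plot(
                members,
                np.full(members.shape, -0.5),
                ".",
                color=cmap(k % 10),
                label=f"class {k}",
            )
        ax.set_xlabel("weight")
        ax.set_ylabel("count")
        ax.legend(fontsize="small")
        return ax

    # -- serialization ----------------------------------------------------
    _REQUIRED = (
        "method", "w", "x_mean", "y_mean", "alpha", "lam", "z", "z_prob",
        "pi", "occupancy", "n_iter", "burn_in",
    )

    def save(self, path: str | Path) -> None:
        """Serialize to a portable JSON archive (no trace, no model data)."""
        d = {
            "format": "mcbr-results",
            "version": 1,
            "method": self.method,
            "w": self.w.tolist(),
            "x_mean": self.centering.x_mean.tolist(),
            "y_mean": self.centering.y_mean,
            "alpha": self.alpha,
            "lam": self.lam.tolist(),
            "z": self.z.tolist(),
            "z_prob": self.z_prob.tolist(),
            "pi": self.pi.tolist(),
            "occupancy": self.occupancy.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "burn_in": self.burn_in,
            "seed": self.seed,
            "y_scale": self.y_scale,
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def load(cls, path: str | Path) -> "MCBRResults":
        """Load an archive; unknown trailing fields are ignored, missing
        required ones raise a named KeyError."""
        d = json.loads(Path(path).read_text())
        missing = [k for k in cls._REQUIRED if k not in d]
        if missing:
            raise KeyError(f"model archive missing required fields: {missing}")
        return cls(
            model=None,
            method=d["method"],
            w=np.asarray(d["w"], dtype=float),
            centering=CenteringRecord(
                x_mean=np.asarray(d["x_mean"], dtype=float), y_mean=float(d["y_mean"])
            ),
            alpha=d["alpha"],
            lam=np.asarray(d["lam"], dtype=float),
            z=np.asarray(d["z"], dtype=int),
            z_prob=np.asarray(d["z_prob"], dtype=float),
            pi=np.asarray(d["pi"], dtype=float),
            occupancy=np.asarray(d["occupancy"], dtype=int),
            trace=None,
            converged=d.get("converged", True),
            n_iter=d["n_iter"],
            burn_in=d["burn_in"],
            seed=d.get("seed"),
            y_scale=d.get("y_scale", 1.0),
        )
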