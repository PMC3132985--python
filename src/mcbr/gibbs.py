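"""Gibbs sampler for MCBR.

Each sweep draws the five blocks from their full conditionals in the fixed
order z, lambda, pi, alpha, w:

* ``z_j  | .`` categorical with P(z_j = k) proportional to
  pi_k * N(w_j; 0, 1/lambda_k), computed in log space;
* ``lambda_k | .`` Gamma(lambda1_k + n_k/2, lambda2_k + S_k/2) with n_k the
  class count and S_k the sum of squared member weights;
* ``pi | .`` Dirichlet(eta + n_1, ..., eta + n_K);
* ``alpha | .`` Gamma(alpha1 + n/2, alpha2 + ||y - Xw||^2 / 2);
* ``w | .`` multivariate Gaussian with precision alpha X'X + diag(lambda_z)
  and mean alpha * precision^-1 X'y, drawn through a Cholesky factor.

The point estimate averages w, alpha, lambda and pi over the post-burn-in
sweeps; the class assignment reported is the one of the final sweep.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .hyperparams import MCBRHyperparams

__all__ = [
    "sample_w",
    "sample_alpha",
    "sample_lambda",
    "sample_z",
    "sample_pi",
    "run_gibbs",
]


def sample_w(
    rng: np.random.Generator,
    XtX: np.ndarray,
    Xty: np.ndarray,
    alpha: float,
    prior_precisions: np.ndarray,
) -> np.ndarray:
    """Draw w from N(alpha P^-1 X'y, P^-1), P = alpha X'X + diag(prior_precisions).

    On a Cholesky failure the precision diagonal is jittered once by
    1e-10 times its mean; a second failure raises.
    """
    p = XtX.shape[0]
    P = alpha * XtX
    P[np.diag_indices_from(P)] += prior_precisions
    try:
        L = cholesky(P, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        P[np.diag_indices_from(P)] += 1e-10 * np.mean(np.diag(P))
        L = cholesky(P, lower=True, check_finite=False)
    u = solve_triangular(L, alpha * Xty, lower=True, check_finite=False)
    mean = solve_triangular(L.T, u, lower=False, check_finite=False)
    noise = solve_triangular(
        L.T, rng.standard_normal(p), lower=False, check_finite=False
    )
    return mean + noise


def sample_alpha(
    rng: np.random.Generator,
    alpha1: float,
    alpha2: float,
    n: int,
    rss: float,
) -> float:
    """Draw the noise precision from Gamma(alpha1 + n/2, alpha2 + rss/2)."""
    return float(rng.gamma(alpha1 + 0.5 * n, 1.0 / (alpha2 + 0.5 * rss)))


def sample_lambda(
    rng: np.random.Generator,
    lambda1: np.ndarray,
    lambda2: np.ndarray,
    counts: np.ndarray,
    sq_sums: np.ndarray,
) -> np.ndarray:
    """Draw each class precision from Gamma(lambda1_k + n_k/2, lambda2_k + S_k/2).

    Empty classes (n_k = 0, S_k = 0) draw from their prior, which is what
    lets pruned classes be repopulated later.
    """
    shape = lambda1 + 0.5 * counts
    rate = lambda2 + 0.5 * sq_sums
    return rng.gamma(shape, 1.0 / rate)


def sample_z(
    rng: np.random.Generator,
    w: np.ndarray,
    lam: np.ndarray,
    pi: np.ndarray,
) -> np.ndarray:
    """Draw class labels: P(z_j = k) ∝ pi_k sqrt(lam_k) exp(-lam_k w_j^2 / 2)."""
    # log-space with per-row max subtraction to avoid under/overflow; a
    # lambda_k that underflowed to 0 contributes -inf, i.e. probability 0
    with np.errstate(divide="ignore"):
        logp = np.log(pi) + 0.5 * np.log(lam) - 0.5 * np.outer(w**2, lam)
    rowmax = logp.max(axis=1, keepdims=True)
    if not np.all(np.isfinite(rowmax)):
        raise FloatingPointError("all class log-probabilities are -inf")
    logp -= rowmax
    prob = np.exp(logp)
    prob /= prob.sum(axis=1, keepdims=True)
    u = rng.random(w.shape[0])
    cum = np.cumsum(prob, axis=1)
    return np.minimum((u[:, None] > cum).sum(axis=1), lam.shape[0] - 1)


def sample_pi(
    rng: np.random.Generator,
    eta: float,
    counts: np.ndarray,
) -> np.ndarray:
    """Draw class proportions from Dirichlet(eta + counts)."""
    if counts.shape[0] == 1:
        return np.ones(1)
    return rng.dirichlet(eta + counts)


def run_gibbs(
    y: np.ndarray,
    X: np.ndarray,
    hp: MCBRHyperparams,
    n_iter: int,
    burn_in: int,
    rng: np.random.Generator,
    keep_trace: bool = False,
    trace_stream=None,
) -> dict:
    """Run the sampler on centered data and return posterior point estimates.

    Parameters
    ----------
    y, X : centered target and design matrix.
    hp : hyperparameters; if ``hp.fixed_assignments`` the z and pi sweeps
        are skipped and z_j = j stays frozen (ARD).
    n_iter, burn_in : total sweeps and discarded initial sweeps.
    rng : the random generator driving every draw.
    keep_trace : additionally record the post-burn-in w samples.
    trace_stream : optional text stream receiving one tab-separated line
        per sweep (iteration, alpha, occupied class count, log joint).

    Returns a dict with keys ``w, alpha, lam, pi, z, occupancy`` and
    ``trace`` (per-sweep alpha, plus w samples when requested).
    """
    from .model import joint_log_density

    n, p = X.shape
    K = hp.K
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    if hp.fixed_assignments and K != p:
        raise ValueError("fixed assignments require K == p")

    XtX = X.T @ X
    Xty = X.T @ y

    # initialization: random z (frozen identity for ARD), w = 0, alpha and
    # lambda at their prior means, uniform pi
    if hp.fixed_assignments:
        z = np.arange(p)
    else:
        z = rng.integers(K, size=p)
    w = np.zeros(p)
    lam = hp.lambda_prior_mean.copy()
    alpha = hp.alpha_prior_mean
    pi = np.full(K, 1.0 / K)

    n_keep = n_iter - burn_in
    w_sum = np.zeros(p)
    alpha_sum = 0.0
    lam_sum = np.zeros(K)
    pi_sum = np.zeros(K)
    alpha_trace = np.empty(n_iter)
    w_trace = np.empty((n_keep, p)) if keep_trace else None

    for it in range(n_iter):
        if not hp.fixed_assignments:
            z = sample_z(rng, w, lam, pi)
        counts = np.bincount(z, minlength=K).astype(float)
        sq_sums = np.bincount(z, weights=w**2, minlength=K)
        lam = sample_lambda(rng, hp.lambda1, hp.lambda2, counts, sq_sums)
        if not hp.fixed_assignments:
            pi = sample_pi(rng, hp.eta, counts)
        resid = y - X @ w
        alpha = sample_alpha(rng, hp.alpha1, hp.alpha2, n, float(resid @ resid))
        w = sample_w(rng, XtX, Xty, alpha, lam[z])

        if not (np.isfinite(alpha) and np.all(np.isfinite(w))):
            raise FloatingPointError(f"non-finite sampler state at iteration {it}")

        alpha_trace[it] = alpha
        if trace_stream is not None:
            # clamp precisions/proportions that underflowed to 0 so the
            # diagnostic log joint stays evaluable
            lj = joint_log_density(
                y, X, w, alpha, np.maximum(lam, 1e-300),
                z, np.maximum(pi, 1e-300), hp,
            )
            trace_stream.write(
                f"{it}\t{alpha:.8g}\t{int((counts > 0).sum())}\t{lj:.8g}\n"
            )
        if it >= burn_in:
            w_sum += w
            alpha_sum += alpha
            lam_sum += lam
            pi_sum += pi
            if keep_trace:
                w_trace[it - burn_in] = w

    occupancy = np.bincount(z, minlength=K)
    trace = {"alpha": alpha_trace}
    if keep_trace:
        trace["w"] = w_trace
    return {
        "w": w_sum / n_keep,
        "alpha": alpha_sum / n_keep,
        "lam": lam_sum / n_keep,
        "pi": pi_sum / n_keep,
        "z": z,
        "occupancy": occupancy,
        "trace": trace,
    }
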