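"""Shared test helpers (independent oracles and VB cycle checkers)."""

import numpy as np
from scipy.special import gammaln

from mcbr.vb import (
    free_energy,
    init_state,
    update_qalpha,
    update_qlambda,
    update_qpi,
    update_qw,
    update_qz,
)


def vb_cycle_with_checks(y, X, hp, rng, n_cycles=3):
    """Run VB cycles asserting the free energy never decreases after any
    single coordinate update; returns the final free energy."""
    XtX, Xty = X.T @ X, X.T @ y
    st = init_state(X, hp, rng)
    f = free_energy(st, y, X, XtX, hp)
    updates = [
        lambda: update_qz(st),
        lambda: update_qlambda(st, hp.lambda1, hp.lambda2),
        lambda: update_qpi(st, hp.eta),
        lambda: update_qalpha(st, y, X, XtX, hp.alpha1, hp.alpha2),
        lambda: update_qw(st, XtX, Xty),
    ]
    for _ in range(n_cycles):
        for step in updates:
            step()
            f_new = free_energy(st, y, X, XtX, hp)
            assert f_new >= f - 1e-8 * abs(f), "free energy decreased"
            f = f_new
    return f


def brute_force_posterior_moments(y, X, hp, n_lam=110, n_alpha=200):
    """Posterior means of (alpha, lambda_1, lambda_2) for K = 2 by exhaustive
    enumeration of assignments and log-grid integration over the precisions.

    Marginalizes w analytically (y | z, lambda, alpha is Gaussian with
    covariance alpha^-1 I + X A^-1 X'), pi analytically (Dirichlet-
    multinomial over z), and integrates alpha and the two lambdas on dense
    logarithmic grids.  Completely independent of the Gibbs code path.
    """
    n, p = X.shape
    K = hp.K
    assert K == 2

    def gamma_logpdf(x, a, b):
        return a * np.log(b) + (a - 1) * np.log(x) - b * x - gammaln(a)

    def log_dirichlet_multinomial(counts):
        return (
            gammaln(K * hp.eta)
            - gammaln(K * hp.eta + counts.sum())
            + np.sum(gammaln(hp.eta + counts) - gammaln(hp.eta))
        )

    agrid = np.exp(np.linspace(np.log(1e-3), np.log(1e3), n_alpha))
    lgrid = np.exp(np.linspace(np.log(1e-4), np.log(1e4), n_lam))
    law = np.gradient(np.log(agrid))
    llw = np.gradient(np.log(lgrid))
    log_prior_a = gamma_logpdf(agrid, hp.alpha1, hp.alpha2) + np.log(agrid)

    Z = 0.0
    num = np.zeros(3)  # alpha, lam1, lam2
    for code in range(K**p):
        z = np.array([(code >> j) & 1 for j in range(p)])
        counts = np.bincount(z, minlength=K).astype(float)
        lz = log_dirichlet_multinomial(counts)
        for i1, l1 in enumerate(lgrid):
            lp1 = gamma_logpdf(l1, hp.lambda1[0], hp.lambda2[0]) + np.log(l1)
            for i2, l2 in enumerate(lgrid):
                lam = np.array([l1, l2])
                S = (X / lam[z]) @ X.T
                evals, evecs = np.linalg.eigh(S)
                yt = evecs.T @ y
                var = 1.0 / agrid[:, None] + np.clip(evals, 0, None)[None, :]
                loglik = -0.5 * np.sum(
                    np.log(2 * np.pi * var) + (yt**2)[None, :] / var, axis=1
                )
                lp = (
                    loglik + log_prior_a + lz + lp1
                    + gamma_logpdf(l2, hp.lambda1[1], hp.lambda2[1]) + np.log(l2)
                )
                wgt = np.exp(lp) * (law * llw[i1] * llw[i2])
                s = wgt.sum()
                Z += s
                num[0] += (wgt * agrid).sum()
                num[1] += s * l1
                num[2] += s * l2
    return num / Z
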