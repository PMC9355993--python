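"""Independent reference computations used to validate the main code paths.

These deliberately avoid the package's batched/conjugate machinery:

* :func:`ml_mixed_model_fit` maximises the marginal likelihood of the
  single-population (K=1) multivariate linear mixed model directly with
  a quasi-Newton optimiser, profiling the linear parameters by GLS — a
  classical fit against which the Gibbs posterior means can be checked.
* :func:`mc_marginal_loglik` evaluates the subject-level marginal
  likelihood by plain Monte-Carlo integration over the random effects,
  a brute-force check of the closed-form Gaussian marginal.

They are slower and dimension-limited by design; use the samplers and
closed forms for real work.
"""

from __future__ import annotations

import contextlib
import warnings

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import qmc

from .errors import ConvergenceError
from .mixture import MixtureModel, _Design
from .dataset import CohortDataset

_LOG2PI = np.log(2.0 * np.pi)


@contextlib.contextmanager
def _suppress_sobol_balance_warning():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="The balance properties of Sobol"
        )
        yield


def _subject_blocks(design: _Design):
    """Per-subject (y, W, n_obs) with region-major stacking and the joint
    linear design W = [X-part | Z] over theta = (vec beta, mu)."""
    R, p, C = design.R, design.p, design.C
    d = design.d
    blocks = []
    for s0, ni in zip(design.starts, design.n_i):
        sl = slice(s0, s0 + ni)
        T = design.Tpoly[sl]              # (ni, p)
        Z = np.kron(np.eye(R), T)         # (ni*R, d)
        y = design.Y[sl].T.ravel()        # region-major
        m = ni * R
        Xb = np.zeros((m, R * C))
        if C:
            X = design.X[sl]              # (ni, C)
            for r in range(R):
                Xb[r * ni:(r + 1) * ni, r * C:(r + 1) * C] = X
        W = np.hstack([Xb, Z])
        blocks.append((y, W, Z, ni))
    return blocks


def ml_mixed_model_fit(
    ds: CohortDataset,
    trend_order: int = 1,
    fixed_covariates: tuple[str, ...] = ("field_strength", "etiv"),
    maxiter: int = 400,
) -> dict:
    """Direct numerical ML fit of the K=1 multivariate linear mixed model.

    Optimises the Cholesky factor of the random-effect covariance and the
    log residual variances; profiles (beta, mu) by GLS at every step.
    Returns ``{"beta": (R, C), "mu": (d,), "Sigma": (d, d),
    "sigma2": (R,), "nll": float}``.
    """
    design = _Design(ds, trend_order, fixed_covariates)
    R, C, d = design.R, design.C, design.d
    blocks = _subject_blocks(design)
    tril = np.tril_indices(d)
    diag_pos = np.flatnonzero(tril[0] == tril[1])

    def unpack(theta):
        Lv = theta[: len(tril[0])].copy()
        Lv[diag_pos] = np.exp(Lv[diag_pos])
        L = np.zeros((d, d))
        L[tril] = Lv
        sigma2 = np.exp(theta[len(tril[0]):])
        return L, sigma2

    def nll(theta):
        L, sigma2 = unpack(theta)
        Sigma = L @ L.T
        AtA = 0.0
        Aty = 0.0
        yty = 0.0
        logdet = 0.0
        n_obs = 0
        for y, W, Z, ni in blocks:
            Dv = np.repeat(sigma2, ni)
            V = Z @ Sigma @ Z.T + np.diag(Dv)
            try:
                Lc = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return 1e12
            logdet += 2.0 * np.sum(np.log(np.diag(Lc)))
            sol = np.linalg.solve(Lc, np.column_stack([W, y]))
            Ws, ys = sol[:, :-1], sol[:, -1]
            AtA = AtA + Ws.T @ Ws
            Aty = Aty + Ws.T @ ys
            yty += ys @ ys
            n_obs += len(y)
        try:
            theta_hat = np.linalg.solve(AtA, Aty)
        except np.linalg.LinAlgError:
            return 1e12
        quad = yty - theta_hat @ Aty
        return 0.5 * (logdet + quad + n_obs * _LOG2PI)

    # moment start: pooled OLS residual variance, modest RE covariance
    resvar = float(np.var(design.Y))
    x0 = np.zeros(len(tril[0]) + R)
    x0[diag_pos] = 0.5 * np.log(max(resvar, 1e-3) / 2.0)
    x0[len(tril[0]):] = np.log(max(resvar, 1e-3) / 2.0)
    res = minimize(nll, x0, method="L-BFGS-B",
                   options={"maxiter": maxiter, "maxfun": 200000})
    if not np.isfinite(res.fun):
        raise ConvergenceError(f"reference ML fit failed: {res.message}")
    L, sigma2 = unpack(res.x)
    Sigma = L @ L.T
    # recover the profiled linear parameters at the optimum
    AtA = 0.0
    Aty = 0.0
    for y, W, Z, ni in blocks:
        Dv = np.repeat(sigma2, ni)
        V = Z @ Sigma @ Z.T + np.diag(Dv)
        Lc = np.linalg.cholesky(V)
        sol = np.linalg.solve(Lc, np.column_stack([W, y]))
        AtA = AtA + sol[:, :-1].T @ sol[:, :-1]
        Aty = Aty + sol[:, :-1].T @ sol[:, -1]
    theta_hat = np.linalg.solve(AtA, Aty)
    beta = theta_hat[: R * C].reshape(R, C)
    mu = theta_hat[R * C:]
    return {"beta": beta, "mu": mu, "Sigma": Sigma, "sigma2": sigma2,
            "nll": float(res.fun)}


def mc_marginal_loglik(
    model: MixtureModel,
    values: np.ndarray,
    durations: np.ndarray,
    covariates: np.ndarray | None,
    k: int,
    n_draws: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate of one subject's marginal log-likelihood under
    cluster ``k``: log (1/S) sum_s N(y | b_s), b_s ~ N(mu_k, Sigma_k).

    Uses scrambled-Sobol quasi-Monte-Carlo draws from the random-effect
    distribution, which keeps the estimator a plain average over
    ``n_draws`` samples while cutting its variance by orders of
    magnitude relative to pseudo-random sampling."""
    values = np.atleast_2d(np.asarray(values, float))
    durations = np.atleast_1d(np.asarray(durations, float))
    n_vis, R = values.shape
    p = model.n_trend
    T = np.column_stack([durations ** a for a in range(p)])
    Z = np.kron(np.eye(R), T)
    y = values.T.ravel()
    if model.beta.size:
        X = np.atleast_2d(np.asarray(covariates, float))
        if X.shape[0] == 1 and n_vis > 1:
            X = np.repeat(X, n_vis, axis=0)
        y = y - (X @ model.beta.T).T.ravel()
    Dv = np.repeat(model.sigma2, n_vis)
    with np.errstate(all="ignore"), _suppress_sobol_balance_warning():
        engine = qmc.MultivariateNormalQMC(
            mean=model.mu[k], cov=model.Sigma[k], seed=seed
        )
        b = engine.random(n_draws)
    resid = y[None, :] - b @ Z.T
    ll = -0.5 * (
        len(y) * _LOG2PI + np.sum(np.log(Dv))
        + np.sum(resid ** 2 / Dv[None, :], axis=1)
    )
    return float(logsumexp(ll) - np.log(n_draws))
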