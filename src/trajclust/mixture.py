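"""Bayesian mixture of multivariate linear mixed models over w-value
trajectories anchored at clinical disease onset.

Observation model. For subject i, region r, visit j at disease duration
t_ij (years since onset):

    w_irj = x_ij' beta_r + b_ir0 + b_ir1 t_ij (+ b_ir2 t_ij^2) + e_irj,
    e_irj ~ N(0, sigma2_r),

with the stacked region-major random-effect vector
b_i = (b_i10, b_i11(, b_i12), b_i20, ...) of dimension d = R * (T+1)
following a cluster-specific multivariate Gaussian

    b_i | z_i = k ~ N(mu_k, Sigma_k),      z_i ~ Categorical(pi).

Fixed effects (scanner field strength and standardised eTIV by default)
are shared across clusters; the cluster-specific random-effect means
carry the atrophy level at onset (intercepts) and the progression rate
(slopes), and the cluster-specific covariances Sigma_k encode how
regions co-vary — the raw material of the covariance-network post hoc
analysis.

Inference is a fixed-scan partially-collapsed Gibbs sampler with
conjugate updates: (1) beta and (2) each mu_k are drawn with the random
effects integrated out (collapsed Gaussian steps — conditioning on
sampled b instead leaves both random-walking against the subject
effects, which is painfully slow for subject-constant covariates such
as scanner field strength and for correlated trend terms), then (3) b_i
given the fresh beta and mu, (4) z_i, (5) Sigma_k via inverse-Wishart,
(6) pi via Dirichlet, (7) sigma2_r via inverse-Gamma. Because b is
re-drawn immediately after the collapsed steps and before anything else
conditions on it, the scan targets the exact posterior.
Randomness is drawn from counter-based
Philox streams keyed by (seed, sweep, update block), so chains are
bit-reproducible and independent of storage order. After sampling,
draws are relabeled by greedy matching of the cluster means to a
running reference and clusters are reported in order of decreasing
mixture weight.

The per-draw model deviance is the observed-data form with random
effects integrated out analytically,

    deviance = -2 sum_i log sum_k pi_k N(y_i; X_i beta + Z_i mu_k,
                                         Z_i Sigma_k Z_i' + D_i),

which is comparable across cluster counts and trend orders.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from scipy.stats import invwishart

from .dataset import CohortDataset
from .errors import NumericalError, ParameterError, SchemaError

log = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass
class MixturePriors:
    """Weakly-informative priors on the w-scale.

    alpha: symmetric Dirichlet concentration on the weights.
    m0, s0: Normal prior N(m0*1, s0^2*I) on each cluster mean.
    nu0, psi0: inverse-Wishart prior IW(nu0, Psi0) on each Sigma_k;
        nu0=None resolves to d+2 (the smallest df with a finite mean).
        psi0=None (default) sets Psi0 empirically so the prior mean
        equals the diagonal of the initial within-cluster covariance —
        weakly informative on the actual scale of the random effects
        (intercepts and per-year slopes live on very different scales,
        so a fixed isotropic scale matrix would overwhelm the smaller
        components). A scalar psi0 forces Psi0 = psi0 * I.
    a0, b0: inverse-Gamma prior on each residual variance.
    tau2: prior variance of each fixed-effect coefficient.
    """

    alpha: float = 1.0
    m0: float = 0.0
    s0: float = 10.0
    nu0: float | None = None
    psi0: float | None = None
    a0: float = 0.01
    b0: float = 0.01
    tau2: float = 100.0


@dataclass
class MCMCOptions:
    n_iter: int = 6000
    burn_in: int = 3000
    thin: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.burn_in < self.n_iter):
            raise ParameterError("need 0 < burn_in < n_iter")
        if self.thin < 1:
            raise ParameterError("thin must be >= 1")


@dataclass
class MixtureSpec:
    """Everything that defines one mixture fit."""

    K: int
    trend_order: int = 1          # 1 linear, 2 quadratic
    fixed_covariates: tuple[str, ...] = ("field_strength", "etiv")
    priors: MixturePriors = field(default_factory=MixturePriors)
    mcmc: MCMCOptions = field(default_factory=MCMCOptions)
    dim_cap: int = 60             # warn above this random-effect dimension
    # deviance-guided restarts: short pilot chains from several
    # deterministic allocations; the lowest-deviance mode seeds the main
    # chain (label modes of mixtures are hard to leave once entered)
    n_restarts: int = 8
    pilot_sweeps: int = 200

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ParameterError("K must be >= 1")
        if self.trend_order not in (1, 2):
            raise ParameterError("trend_order must be 1 (linear) or 2 (quadratic)")
        bad = set(self.fixed_covariates) - {"field_strength", "etiv"}
        if bad:
            raise ParameterError(f"unknown fixed covariates: {sorted(bad)}")


@dataclass
class MixtureState:
    """One complete parameter state of the sampler."""

    pi: np.ndarray        # (K,)
    mu: np.ndarray        # (K, d)
    Sigma: np.ndarray     # (K, d, d)
    beta: np.ndarray      # (R, C)
    sigma2: np.ndarray    # (R,)
    z: np.ndarray         # (n,) int
    b: np.ndarray         # (n, d)


@dataclass
class MixtureModel:
    """Point-estimate (posterior mean) mixture parameters plus the
    metadata needed to apply the model to new data."""

    K: int
    trend_order: int
    region_names: tuple[str, ...]
    fixed_covariates: tuple[str, ...]
    etiv_mean: float
    etiv_sd: float
    cov_center: np.ndarray
    pi: np.ndarray
    mu: np.ndarray
    Sigma: np.ndarray
    beta: np.ndarray
    sigma2: np.ndarray

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    @property
    def n_trend(self) -> int:
        return self.trend_order + 1

    def encode_covariates(
        self, field_strength: str = "1.5T", etiv: float | None = None
    ) -> np.ndarray:
        """Code raw covariate values the way the model was fitted
        (3T indicator and standardised eTIV, both centred)."""
        vals = []
        for i, name in enumerate(self.fixed_covariates):
            if name == "field_strength":
                vals.append(float(field_strength == "3T"))
            elif name == "etiv":
                z = 0.0 if etiv is None else (etiv - self.etiv_mean) / self.etiv_sd
                vals.append(z)
        return np.asarray(vals) - self.cov_center

    def mu_block(self, block: str) -> np.ndarray:
        """(K, R) cluster means of one trend block
        (``intercept`` | ``slope`` | ``quad``)."""
        idx = {"intercept": 0, "slope": 1, "quad": 2}[block]
        if idx > self.trend_order:
            raise ParameterError(f"model has no {block!r} term")
        return self.mu.reshape(self.K, self.n_regions, self.n_trend)[:, :, idx]


@dataclass
class MCMCSamples:
    """Retained, relabeled posterior draws plus per-draw deviance."""

    K: int
    trend_order: int
    region_names: tuple[str, ...]
    fixed_covariates: tuple[str, ...]
    etiv_mean: float
    etiv_sd: float
    cov_center: np.ndarray
    subject_ids: tuple[str, ...]
    pi: np.ndarray        # (S, K)
    mu: np.ndarray        # (S, K, d)
    Sigma: np.ndarray     # (S, K, d, d)
    beta: np.ndarray      # (S, R, C)
    sigma2: np.ndarray    # (S, R)
    z: np.ndarray         # (S, n) int
    deviance: np.ndarray  # (S,)
    n_iter: int
    burn_in: int
    thin: int
    seed: int
    empty_fraction: np.ndarray | None = None  # (K,)
    init_record: dict | None = None

    @property
    def n_draws(self) -> int:
        return self.pi.shape[0]

    def posterior_mean_model(self) -> MixtureModel:
        return MixtureModel(
            K=self.K, trend_order=self.trend_order,
            region_names=tuple(self.region_names),
            fixed_covariates=tuple(self.fixed_covariates),
            etiv_mean=self.etiv_mean, etiv_sd=self.etiv_sd,
            cov_center=self.cov_center,
            pi=self.pi.mean(0), mu=self.mu.mean(0),
            Sigma=self.Sigma.mean(0), beta=self.beta.mean(0),
            sigma2=self.sigma2.mean(0),
        )


@dataclass
class AssignmentResult:
    """Per-subject posterior cluster probabilities and hard labels.

    Labels are 1-based. ``ambiguous`` flags subjects whose probability
    mass is split across clusters (max < 0.5 and runner-up > 0.3 by
    default).
    """

    subject_ids: tuple[str, ...]
    probs: np.ndarray          # (n, K) rows on the simplex
    labels: np.ndarray         # (n,) in 1..K
    n_visits: np.ndarray       # (n,)
    median_duration: dict[int, float]   # cluster label -> median years
    ambiguous: np.ndarray      # (n,) bool

    def to_frame(self) -> pd.DataFrame:
        K = self.probs.shape[1]
        df = pd.DataFrame({
            "subject_id": self.subject_ids,
            "n_visits": self.n_visits,
            "label": self.labels,
            "ambiguous": self.ambiguous,
        })
        for k in range(K):
            df[f"p_{k + 1}"] = self.probs[:, k]
        return df


# ---------------------------------------------------------------------------
# design: stacked arrays + per-subject sufficient statistics
# ---------------------------------------------------------------------------

class _Design:
    """Stacked observation arrays and per-subject cross products."""

    def __init__(
        self,
        ds: CohortDataset,
        trend_order: int,
        fixed_covariates: tuple[str, ...],
        etiv_mean: float | None = None,
        etiv_sd: float | None = None,
        cov_center: np.ndarray | None = None,
    ) -> None:
        if ds.unit_state != "w":
            raise SchemaError("mixture model expects w-transformed data")
        df = ds.visits
        if not (df["diagnosis"] == "AD").all():
            raise SchemaError("mixture model expects an AD-only dataset")
        t = df["disease_duration"].to_numpy(float)
        if not np.all(np.isfinite(t)) or np.any(t < 0):
            raise SchemaError("disease durations must be finite and >= 0")

        self.region_names = tuple(ds.atlas.region_names)
        self.R = len(self.region_names)
        self.p = trend_order + 1
        self.d = self.R * self.p
        self.Y = ds.values_matrix()
        self.t = t
        self.Tpoly = np.column_stack([t ** a for a in range(self.p)])

        subj = df["subject_id"].to_numpy()
        self.subject_ids = tuple(dict.fromkeys(subj))
        sid_index = {s: i for i, s in enumerate(self.subject_ids)}
        self.subj_idx = np.array([sid_index[s] for s in subj])
        self.n = len(self.subject_ids)
        self.N = len(df)
        # canonical sort guarantees contiguous subject blocks
        self.starts = np.flatnonzero(
            np.r_[True, self.subj_idx[1:] != self.subj_idx[:-1]]
        )
        self.n_i = np.diff(np.r_[self.starts, self.N])

        cols = []
        etiv = df["etiv"].to_numpy(float)
        self.etiv_mean = float(np.mean(etiv)) if etiv_mean is None else etiv_mean
        self.etiv_sd = float(np.std(etiv)) if etiv_sd is None else etiv_sd
        if self.etiv_sd <= 0:
            self.etiv_sd = 1.0
        for name in fixed_covariates:
            if name == "field_strength":
                cols.append((df["field_strength"] == "3T").to_numpy(float))
            elif name == "etiv":
                cols.append((etiv - self.etiv_mean) / self.etiv_sd)
        self.C = len(cols)
        X = np.column_stack(cols) if cols else np.empty((self.N, 0))
        # centre the covariates: uncentred codes put the fixed effects on
        # a ridge with the cluster intercept means and stall the sampler
        if cov_center is None:
            cov_center = X.mean(axis=0) if self.C else np.empty(0)
        self.cov_center = np.asarray(cov_center, float)
        self.X = X - self.cov_center[None, :] if self.C else X
        self.XtX = self.X.T @ self.X

        # per-subject T'T blocks, shared across regions
        outer = self.Tpoly[:, :, None] * self.Tpoly[:, None, :]
        self.M = np.add.reduceat(outer, self.starts, axis=0)   # (n, p, p)
        # per-subject cross products for the collapsed fixed-effect update
        if self.C:
            self.XT = np.add.reduceat(
                self.X[:, :, None] * self.Tpoly[:, None, :], self.starts, axis=0
            )                                                  # (n, C, p)
            self.XY = np.add.reduceat(
                self.X[:, :, None] * self.Y[:, None, :], self.starts, axis=0
            )                                                  # (n, C, R)
        self.G0 = self.cross_products(self.Y)                  # (n, R, p)

    def cross_products(self, resid: np.ndarray) -> np.ndarray:
        """(n, R, p) per-subject T' resid blocks."""
        arr = resid[:, :, None] * self.Tpoly[:, None, :]
        return np.add.reduceat(arr, self.starts, axis=0)

    def precision_blocks(self, sigma2: np.ndarray) -> np.ndarray:
        """(n, d, d) block-diagonal Z' D^-1 Z matrices."""
        n, R, p = self.n, self.R, self.p
        A = np.zeros((n, self.d, self.d))
        A5 = A.reshape(n, R, p, R, p)
        for r in range(R):
            A5[:, r, :, r, :] = self.M / sigma2[r]
        return A


# ---------------------------------------------------------------------------
# counter-based RNG streams
# ---------------------------------------------------------------------------

_BLOCK = {"init": 0, "b": 1, "z": 2, "pi": 3, "beta": 4, "sigma2": 5,
          "sigma_k": 6,      # per-cluster Sigma streams use 6 + k
          "mu_k": 512}       # per-cluster mu streams use 512 + k


def _stream(seed: int, sweep: int, block: int) -> np.random.Generator:
    key = np.array([np.uint64(seed), np.uint64(sweep) << np.uint64(16)
                    | np.uint64(block)], dtype=np.uint64)
    return np.random.Generator(np.random.Philox(key=key))


# ---------------------------------------------------------------------------
# marginal likelihood (random effects integrated out)
# ---------------------------------------------------------------------------

def _chol_logdet(mats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    try:
        L = np.linalg.cholesky(mats)
    except np.linalg.LinAlgError as exc:
        conds = np.linalg.cond(mats)
        raise NumericalError(
            f"covariance not SPD (max condition number {np.max(conds):.3g})"
        ) from exc
    logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=-2, axis2=-1)), axis=-1)
    return L, logdet


def _marginal_logliks(
    design: _Design,
    pi: np.ndarray,
    mu: np.ndarray,
    Sigma: np.ndarray,
    beta: np.ndarray,
    sigma2: np.ndarray,
) -> np.ndarray:
    """(n, K) log N(y_i; X_i beta + Z_i mu_k, Z_i Sigma_k Z_i' + D_i).

    Uses the matrix-determinant/Woodbury identities so all linear algebra
    happens in the d-dimensional random-effect space, batched over
    subjects.
    """
    K = mu.shape[0]
    resid = design.Y - design.X @ beta.T
    G = design.cross_products(resid)
    gflat = (G / sigma2[None, :, None]).reshape(design.n, design.d)
    A = design.precision_blocks(sigma2)
    s = np.add.reduceat((resid ** 2 / sigma2).sum(axis=1), design.starts)
    logdetD = design.n_i * np.sum(np.log(sigma2))

    out = np.empty((design.n, K))
    for k in range(K):
        Lk, logdet_S = _chol_logdet(Sigma[k])
        Sinv = np.linalg.inv(Sigma[k])
        C = Sinv[None] + A
        Lc, logdetC = _chol_logdet(C)
        Amu = A @ mu[k]
        mvec = gflat - Amu
        w = np.linalg.solve(Lc, mvec[:, :, None])[:, :, 0]
        quad_corr = np.sum(w ** 2, axis=1)
        quad = (
            s - 2.0 * gflat @ mu[k] + Amu @ mu[k]
            - quad_corr
        )
        # Amu @ mu[k] above is per-subject: (n,d) @ (d,) -> (n,)
        logdetV = logdetD + logdet_S + logdetC
        out[:, k] = -0.5 * (design.n_i * design.R * _LOG2PI + logdetV + quad)
    return out


def _deviance(design: _Design, pi, mu, Sigma, beta, sigma2) -> float:
    ll = _marginal_logliks(design, pi, mu, Sigma, beta, sigma2)
    return float(-2.0 * np.sum(logsumexp(ll + np.log(pi)[None, :], axis=1)))


def marginal_cluster_loglik(
    model: MixtureModel,
    values: np.ndarray,
    durations: np.ndarray,
    covariates: np.ndarray | None,
    k: int,
) -> float:
    """Closed-form marginal log-likelihood of one subject under cluster k.

    ``values`` is (n_visits, R) in w-units, ``durations`` the visit
    disease durations in years, ``covariates`` the fixed-covariate row(s)
    (already coded: 3T indicator, standardised eTIV). Random effects are
    integrated out analytically, so the value is defined for single-visit
    subjects. Built directly in the observation space (dense), which also
    serves as a cross-check of the batched low-dimensional path.
    """
    values = np.atleast_2d(np.asarray(values, float))
    durations = np.atleast_1d(np.asarray(durations, float))
    n_vis, R = values.shape
    if R != model.n_regions:
        raise SchemaError("values width does not match model regions")
    p = model.n_trend
    T = np.column_stack([durations ** a for a in range(p)])
    Z = np.kron(np.eye(R), T)                      # region-major stacking
    y = values.T.ravel()
    D = np.repeat(model.sigma2, n_vis)
    V = Z @ model.Sigma[k] @ Z.T + np.diag(D)
    mean = Z @ model.mu[k]
    if model.beta.size:
        X = np.atleast_2d(np.asarray(covariates, float))
        if X.shape[0] == 1 and n_vis > 1:
            X = np.repeat(X, n_vis, axis=0)
        fixed = (X @ model.beta.T).T.ravel()
        mean = mean + fixed
    e = y - mean
    L, logdet = _chol_logdet(V)
    w = np.linalg.solve(L, e)
    return float(-0.5 * (len(y) * _LOG2PI + logdet + w @ w))


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def _init_features(design: _Design) -> tuple[np.ndarray, float]:
    """Low-noise per-subject (intercept, slope) summaries for initialisation.

    Raw per-subject OLS intercepts extrapolate back to onset and are very
    noisy for subjects first seen late in the disease; instead the
    intercept summary is the subject's mean w minus a pooled per-region
    slope times the mean duration, and the slope summary is the subject
    OLS slope shrunk toward the pooled slope with an empirical-Bayes
    weight based on its sampling variance. Returns an (n, R, 2) array and
    the pooled residual variance.
    """
    n, R = design.n, design.R
    # pooled slopes from within-subject centring (free of subject effects)
    tcent = np.empty_like(design.t)
    Ycent = np.empty_like(design.Y)
    for s0, ni in zip(design.starts, design.n_i):
        sl = slice(s0, s0 + ni)
        tcent[sl] = design.t[sl] - design.t[sl].mean()
        Ycent[sl] = design.Y[sl] - design.Y[sl].mean(axis=0)
    den = max(float(np.sum(tcent ** 2)), 1e-9)
    slope_pooled = (tcent @ Ycent) / den                      # (R,)

    feats = np.zeros((n, R, 2))
    ols_slopes = np.tile(slope_pooled, (n, 1))
    se2 = np.full(n, np.inf)
    ssr, nres = 0.0, 0
    for i, (s0, ni) in enumerate(zip(design.starts, design.n_i)):
        sl = slice(s0, s0 + ni)
        t = design.t[sl]
        Yb = design.Y[sl]
        feats[i, :, 0] = Yb.mean(axis=0) - slope_pooled * t.mean()
        stt = float(np.sum((t - t.mean()) ** 2))
        if ni >= 2 and stt > 1e-9:
            Tm = np.column_stack([np.ones(ni), t])
            coef, *_ = np.linalg.lstsq(Tm, Yb, rcond=None)
            ols_slopes[i] = coef[1]
            fitted = Tm @ coef
            ssr += float(np.sum((Yb - fitted) ** 2))
            nres += max(ni - 2, 0) * R
            se2[i] = 1.0 / stt   # scaled by resvar below
    resvar = max(ssr / nres if nres > 0 else 0.25, 1e-3)
    se2 = resvar * se2
    finite = np.isfinite(se2)
    mean_se2 = float(np.mean(se2[finite])) if finite.any() else 0.0
    tau2 = np.maximum(np.var(ols_slopes, axis=0) - mean_se2, 1e-4)
    with np.errstate(invalid="ignore"):
        w = np.where(
            finite[:, None],
            tau2[None, :] / (tau2[None, :] + np.where(finite, se2, 1.0)[:, None]),
            0.0,
        )
    feats[:, :, 1] = slope_pooled[None, :] + w * (ols_slopes - slope_pooled[None, :])
    return feats, resvar


def _state_from_allocation(
    design: _Design, K: int, z: np.ndarray,
    f3: np.ndarray, resvar: float,
) -> MixtureState:
    """Build a full sampler state from an initial allocation."""
    n, R, p, d = design.n, design.R, design.p, design.d
    b = np.zeros((n, R, p))
    b[:, :, 0] = f3[:, :, 0]
    b[:, :, 1] = f3[:, :, 1]
    b = b.reshape(n, d)
    mu = np.zeros((K, d))
    Sigma = np.zeros((K, d, d))
    # pooled WITHIN-group variance: total variance would mix in the
    # between-cluster separation and start the chain with blurred clusters
    within = np.zeros(d)
    for k in range(K):
        members = b[z == k]
        if len(members):
            mu[k] = members.mean(axis=0)
        if len(members) >= 2:
            within += np.var(members, axis=0) * len(members)
    within /= max(n, 1)
    floor = np.maximum(within, 1e-3)
    for k in range(K):
        Sigma[k] = np.diag(floor)
    counts = np.bincount(z, minlength=K).astype(float)
    pi = (counts + 1.0) / (counts.sum() + K)
    beta = np.zeros((R, design.C))
    sigma2 = np.full(R, resvar)
    return MixtureState(pi=pi, mu=mu, Sigma=Sigma, beta=beta,
                        sigma2=sigma2, z=z, b=b)


def _refine_allocation(
    design: _Design, K: int, z: np.ndarray, n_rounds: int = 4
) -> np.ndarray:
    """Alternate cluster-specific slope estimation with reassignment.

    The Ward start adjusts every subject by a pooled slope, which smears
    fast-progressing clusters along disease duration; re-adjusting each
    subject's mean w by its cluster's own slope and reassigning to the
    nearest adjusted centroid undoes that bias in a few rounds.
    """
    n, R = design.n, design.R
    ybar = np.zeros((n, R))
    tbar = np.zeros(n)
    stt = np.zeros(n)
    sty = np.zeros((n, R))
    for i, (s0, m) in enumerate(zip(design.starts, design.n_i)):
        sl = slice(s0, s0 + m)
        t = design.t[sl]
        Y = design.Y[sl]
        ybar[i] = Y.mean(axis=0)
        tbar[i] = t.mean()
        tcen = t - t.mean()
        stt[i] = np.sum(tcen ** 2)
        sty[i] = tcen @ (Y - Y.mean(axis=0))
    for _ in range(n_rounds):
        slopes = np.zeros((K, R))
        for k in range(K):
            m = z == k
            denom = stt[m].sum()
            if denom > 1e-9:
                slopes[k] = sty[m].sum(axis=0) / denom
        cents = np.zeros((K, R))
        for k in range(K):
            m = z == k
            if m.any():
                cents[k] = (ybar - slopes[k] * tbar[:, None])[m].mean(axis=0)
        d2 = np.stack([
            ((ybar - slopes[k] * tbar[:, None] - cents[k]) ** 2).sum(axis=1)
            for k in range(K)
        ], axis=1)
        z_new = d2.argmin(axis=1)
        if np.array_equal(z_new, z):
            break
        z = z_new
    return z


def _initial_state(design: _Design, spec: MixtureSpec) -> MixtureState:
    """Deterministic start: Ward clustering of duration-adjusted subject
    summaries, refined by cluster-specific slope reassignment."""
    n, K = design.n, spec.K
    f3, resvar = _init_features(design)
    if K == 1 or n <= K:
        z = np.zeros(n, dtype=int)
    else:
        lk = linkage(f3[:, :, 0], method="ward")
        z = fcluster(lk, t=K, criterion="maxclust") - 1
        z = _refine_allocation(design, K, z)
    return _state_from_allocation(design, K, z, f3, resvar)


def _candidate_states(design: _Design, spec: MixtureSpec) -> list[MixtureState]:
    """Ward plus seeded k-means++ allocations for the restart pilots."""
    from scipy.cluster.vq import kmeans2

    states = [_initial_state(design, spec)]
    f3, resvar = _init_features(design)
    F = f3[:, :, 0]
    for j in range(max(spec.n_restarts - 1, 0)):
        seed_j = int(
            _stream(spec.mcmc.seed, 0, 8192 + j).integers(2 ** 31)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, z = kmeans2(F, spec.K, minit="++", seed=seed_j, iter=30)
        states.append(_state_from_allocation(design, spec.K, z, f3, resvar))
    return states


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def gibbs_fit(
    ds: CohortDataset,
    spec: MixtureSpec,
    init: MixtureState | None = None,
    init_record: dict | None = None,
) -> MCMCSamples:
    """Fit the K-cluster mixture by Gibbs sampling.

    Returns relabeled retained draws with per-draw observed-data
    deviance. Chains are bit-reproducible under ``spec.mcmc.seed``.
    """
    design = _Design(ds, spec.trend_order, spec.fixed_covariates)
    n, R, p, d, K, C = design.n, design.R, design.p, design.d, spec.K, design.C
    if d > spec.dim_cap:
        warnings.warn(
            f"random-effect dimension d={d} exceeds the configured cap "
            f"{spec.dim_cap}; covariance estimation needs cluster sizes "
            "well above d", stacklevel=2,
        )
    pr = spec.priors
    nu0 = pr.nu0 if pr.nu0 is not None else d + 2
    if nu0 <= d - 1:
        raise ParameterError(f"nu0 must exceed d-1 = {d - 1}")
    S0_inv = np.eye(d) / (pr.s0 ** 2)
    m0 = np.full(d, pr.m0)
    mc = spec.mcmc
    seed = int(mc.seed)

    if (init is None and K > 1 and spec.n_restarts > 1
            and spec.pilot_sweeps > 0):
        init, restart_record = _run_restart_pilots(ds, spec)
        init_record = {**(init_record or {}), **restart_record}

    state = init if init is not None else _initial_state(design, spec)
    pi = np.asarray(state.pi, float).copy()
    mu = np.asarray(state.mu, float).copy()
    Sigma = np.asarray(state.Sigma, float).copy()
    beta = np.asarray(state.beta, float).copy()
    sigma2 = np.asarray(state.sigma2, float).copy()
    z = np.asarray(state.z, int).copy()
    if mu.shape != (K, d) or Sigma.shape != (K, d, d) or beta.shape != (R, C):
        raise ParameterError("init state has inconsistent shapes")
    if pr.psi0 is not None:
        Psi0 = pr.psi0 * np.eye(d)
    else:
        # empirical-Bayes scale: prior mean of Sigma_k equals the diagonal
        # of the average initial covariance
        diag0 = np.maximum(
            np.mean(np.diagonal(Sigma, axis1=1, axis2=2), axis=0), 1e-4
        )
        Psi0 = (nu0 - d - 1) * np.diag(diag0)

    n_ret = (mc.n_iter - mc.burn_in) // mc.thin
    S_pi = np.empty((n_ret, K))
    S_mu = np.empty((n_ret, K, d))
    S_Sig = np.empty((n_ret, K, d, d))
    S_beta = np.empty((n_ret, R, C))
    S_s2 = np.empty((n_ret, R))
    S_z = np.empty((n_ret, n), dtype=np.int32)
    S_dev = np.empty(n_ret)
    empty_counts = np.zeros(K)

    a_post_shape = pr.a0 + 0.5 * design.N
    ridx = 0
    for sweep in range(1, mc.n_iter + 1):
        # shared factorisations: per-subject posterior precision of b given
        # its current cluster, C_i = Sigma_k^{-1} + Z_i' D^{-1} Z_i
        Sigma_inv, Sig_chol = _invert_spd(Sigma)
        A = design.precision_blocks(sigma2)
        members = [np.flatnonzero(z == k) for k in range(K)]
        Cmats = [Sigma_inv[k][None] + A[idx] if idx.size else None
                 for k, idx in enumerate(members)]

        # (1) beta | z, mu, Sigma, sigma2 (random effects integrated out).
        # The collapsed Gaussian step: conditioning on sampled b instead
        # would random-walk along the ridge between subject-constant
        # covariates (scanner field strength) and the subject intercepts.
        if C > 0:
            gflat0 = (design.G0 / sigma2[None, :, None]).reshape(n, d)
            RC = R * C
            P_beta = np.zeros((RC, RC))
            Pb4 = P_beta.reshape(R, C, R, C)
            for r in range(R):
                Pb4[r, :, r, :] = design.XtX / sigma2[r]
            rhs = np.zeros(RC)
            for k, idx in enumerate(members):
                if idx.size == 0:
                    continue
                Cinv = np.linalg.inv(Cmats[k])
                mu5 = mu[k].reshape(R, p)
                q = gflat0[idx] - A[idx] @ mu[k]
                v5 = np.linalg.solve(
                    Cmats[k], q[:, :, None]
                )[:, :, 0].reshape(idx.size, R, p)
                XTm = design.XT[idx]
                Ci5 = Cinv.reshape(idx.size, R, p, R, p)
                UCU = np.einsum("mcp,mrpsq,meq->mrcse", XTm, Ci5, XTm,
                                optimize=True)
                UCU /= sigma2[None, :, None, None, None]
                UCU /= sigma2[None, None, None, :, None]
                P_beta -= UCU.sum(axis=0).reshape(RC, RC)
                ru1 = (np.swapaxes(design.XY[idx], 1, 2)
                       - np.einsum("mcp,rp->mrc", XTm, mu5))
                ru1 /= sigma2[None, :, None]
                rcorr = np.einsum("mcp,mrp->mrc", XTm, v5)
                rcorr /= sigma2[None, :, None]
                rhs += (ru1 - rcorr).sum(axis=0).reshape(RC)
            P_beta += np.eye(RC) / pr.tau2
            Lb = np.linalg.cholesky(P_beta)
            mean = np.linalg.solve(P_beta, rhs)
            eps_b = _stream(seed, sweep, _BLOCK["beta"]).standard_normal(RC)
            beta = (mean + np.linalg.solve(Lb.T, eps_b)).reshape(R, C)

        # (2) mu_k | beta, z, Sigma, sigma2 (random effects integrated out);
        # the same collapse as for beta — conditioning on b would leave the
        # cluster means random-walking against the subject effects, which
        # is what makes the trend coefficients (slope vs quadratic) slow.
        resid = design.Y - design.X @ beta.T
        G = design.cross_products(resid)
        gflat = (G / sigma2[None, :, None]).reshape(n, d)
        for k, idx in enumerate(members):
            rng_mu = _stream(seed, sweep, _BLOCK["mu_k"] + k)
            if idx.size == 0:
                mu[k] = m0 + pr.s0 * rng_mu.standard_normal(d)
                continue
            Ak = A[idx]
            CinvA = np.linalg.solve(Cmats[k], Ak)
            prec_mu = S0_inv + (Ak - Ak @ CinvA).sum(axis=0)
            Cg = np.linalg.solve(Cmats[k], gflat[idx][:, :, None])[:, :, 0]
            rhs_mu = S0_inv @ m0 + (
                gflat[idx] - (Ak @ Cg[:, :, None])[:, :, 0]
            ).sum(axis=0)
            Lmu = np.linalg.cholesky(prec_mu)
            mu[k] = (np.linalg.solve(prec_mu, rhs_mu)
                     + np.linalg.solve(Lmu.T, rng_mu.standard_normal(d)))

        # (3) b_i | beta, mu, rest (same precision C_i as above) ------------
        eps = _stream(seed, sweep, _BLOCK["b"]).standard_normal((n, d))
        b = np.empty((n, d))
        for k, idx in enumerate(members):
            if idx.size == 0:
                continue
            P = Cmats[k]
            Lp = np.linalg.cholesky(P)
            h = (Sigma_inv[k] @ mu[k])[None, :] + gflat[idx]
            mean = np.linalg.solve(P, h[:, :, None])[:, :, 0]
            dev = np.linalg.solve(
                np.swapaxes(Lp, -1, -2), eps[idx][:, :, None]
            )[:, :, 0]
            b[idx] = mean + dev

        # (4) z_i | rest -------------------------------------------------
        loglik = np.empty((n, K))
        for k in range(K):
            delta = b - mu[k][None, :]
            w = np.linalg.solve(Sig_chol[k], delta.T)
            quad = np.sum(w ** 2, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(Sig_chol[k])))
            loglik[:, k] = -0.5 * (d * _LOG2PI + logdet + quad)
        logp = loglik + np.log(pi)[None, :]
        logp -= logp.max(axis=1, keepdims=True)
        probs = np.exp(logp)
        probs /= probs.sum(axis=1, keepdims=True)
        u = _stream(seed, sweep, _BLOCK["z"]).random(n)
        z = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1)
        z = np.minimum(z, K - 1)

        # (5) Sigma_k | b, z, mu --------------------------------------------
        for k in range(K):
            rng_k = _stream(seed, sweep, _BLOCK["sigma_k"] + k)
            idx = np.flatnonzero(z == k)
            if idx.size == 0:
                empty_counts[k] += 1.0 / mc.n_iter
                Sigma[k] = invwishart.rvs(nu0, Psi0, random_state=rng_k)
                continue
            dev_b = b[idx] - mu[k][None, :]
            scatter = dev_b.T @ dev_b
            Sigma[k] = invwishart.rvs(
                nu0 + idx.size, Psi0 + scatter, random_state=rng_k
            )

        # (6) pi | z -------------------------------------------------------
        counts = np.bincount(z, minlength=K)
        pi = _stream(seed, sweep, _BLOCK["pi"]).dirichlet(pr.alpha + counts)

        # (7) sigma2_r | b, beta --------------------------------------------
        b_mat = b.reshape(n, R, p)
        fitted_re = np.einsum("oa,ora->or", design.Tpoly, b_mat[design.subj_idx])
        resid_full = design.Y - fitted_re - design.X @ beta.T
        ssr = np.sum(resid_full ** 2, axis=0)
        g = _stream(seed, sweep, _BLOCK["sigma2"]).standard_gamma(
            a_post_shape, size=R
        )
        sigma2 = (pr.b0 + 0.5 * ssr) / g
        if not np.all(np.isfinite(sigma2)) or np.any(sigma2 <= 0):
            raise NumericalError(
                f"non-finite residual variance at sweep {sweep}: {sigma2}"
            )

        # retain -------------------------------------------------------------
        if sweep > mc.burn_in and (sweep - mc.burn_in) % mc.thin == 0:
            S_pi[ridx] = pi
            S_mu[ridx] = mu
            S_Sig[ridx] = Sigma
            S_beta[ridx] = beta
            S_s2[ridx] = sigma2
            S_z[ridx] = z
            S_dev[ridx] = _deviance(design, pi, mu, Sigma, beta, sigma2)
            ridx += 1
        if sweep % 1000 == 0:
            log.info("sweep %d / %d", sweep, mc.n_iter)

    _relabel_inplace(S_pi, S_mu, S_Sig, S_z)
    degenerate = np.flatnonzero(empty_counts > 0.5)
    if degenerate.size:
        warnings.warn(
            f"clusters empty in >50% of sweeps: {list(degenerate + 1)} "
            "(degenerate cluster)", stacklevel=2,
        )

    return MCMCSamples(
        K=K, trend_order=spec.trend_order,
        region_names=design.region_names,
        fixed_covariates=tuple(spec.fixed_covariates),
        etiv_mean=design.etiv_mean, etiv_sd=design.etiv_sd,
        cov_center=design.cov_center,
        subject_ids=design.subject_ids,
        pi=S_pi, mu=S_mu, Sigma=S_Sig, beta=S_beta, sigma2=S_s2,
        z=S_z, deviance=S_dev,
        n_iter=mc.n_iter, burn_in=mc.burn_in, thin=mc.thin, seed=seed,
        empty_fraction=empty_counts,
        init_record=init_record,
    )


def _run_restart_pilots(
    ds: CohortDataset, spec: MixtureSpec
) -> tuple[MixtureState, dict]:
    """Short pilot chains from several allocations; the lowest mean
    observed-data deviance picks the mode the main chain starts from."""
    design = _Design(ds, spec.trend_order, spec.fixed_covariates)
    cands = _candidate_states(design, spec)
    pilot_n = spec.pilot_sweeps
    best_dev, best_samples, devs = np.inf, None, []
    for j, cand in enumerate(cands):
        pilot_seed = int(_stream(spec.mcmc.seed, 0, 16384 + j).integers(2 ** 31))
        pilot_spec = replace(
            spec, n_restarts=0,
            mcmc=MCMCOptions(n_iter=pilot_n, burn_in=max(pilot_n // 2, 1),
                             thin=1, seed=pilot_seed),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps = gibbs_fit(ds, pilot_spec, init=cand)
        mdev = float(ps.deviance.mean())
        devs.append(mdev)
        if mdev < best_dev:
            best_dev, best_samples = mdev, ps
    last = best_samples
    init = MixtureState(
        pi=last.pi[-1], mu=last.mu[-1], Sigma=last.Sigma[-1],
        beta=last.beta[-1], sigma2=last.sigma2[-1],
        z=np.asarray(last.z[-1], int),
        b=np.zeros((design.n, design.d)),
    )
    record = {
        "restart_mean_deviances": devs,
        "chosen_restart": int(np.argmin(devs)),
    }
    return init, record


def _invert_spd(Sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched inverse + Cholesky of the (K, d, d) covariances."""
    chol = np.linalg.cholesky(Sigma)
    inv = np.linalg.inv(Sigma)
    return inv, chol


def _relabel_inplace(pi: np.ndarray, mu: np.ndarray,
                     Sigma: np.ndarray, z: np.ndarray) -> None:
    """Greedy relabeling: match each draw's cluster means to a running
    posterior-mean reference, then order clusters by decreasing weight."""
    S, K, d = mu.shape
    if K == 1:
        return
    ref = mu[0].copy()
    for s in range(S):
        cost = ((ref[:, None, :] - mu[s][None, :, :]) ** 2).sum(axis=2)
        rows, cols = linear_sum_assignment(cost)
        perm = cols[np.argsort(rows)]     # ref slot i <- draw cluster perm[i]
        mu[s] = mu[s][perm]
        pi[s] = pi[s][perm]
        Sigma[s] = Sigma[s][perm]
        inv = np.empty(K, dtype=int)
        inv[perm] = np.arange(K)
        z[s] = inv[z[s]]
        ref = (s * ref + mu[s]) / (s + 1.0)
    order = np.argsort(-pi.mean(axis=0), kind="stable")
    inv = np.empty(K, dtype=int)
    inv[order] = np.arange(K)
    mu[:] = mu[:, order]
    pi[:] = pi[:, order]
    Sigma[:] = Sigma[:, order]
    z[:] = inv[z]


# ---------------------------------------------------------------------------
# stepwise quadratic refinement
# ---------------------------------------------------------------------------

def fit_stepwise_quadratic(
    ds: CohortDataset,
    spec_linear: MixtureSpec,
    quad_init_var: float = 1e-2,
    mcmc_quadratic: MCMCOptions | None = None,
) -> tuple[MCMCSamples, MCMCSamples]:
    """Linear fit first, then a quadratic fit initialised at its posterior.

    The linear chain is run to completion; its posterior means seed a
    second chain in which each region gains a quadratic trend term
    (mean 0, small prior-scale variance ``quad_init_var``, no initial
    cross-covariance), capturing the atrophy plateau at long disease
    duration without optimising all trend parameters from scratch.
    """
    if spec_linear.trend_order != 1:
        raise ParameterError("spec_linear must have trend_order=1")
    lin = gibbs_fit(ds, spec_linear)

    K = spec_linear.K
    R = len(lin.region_names)
    mu_lin = lin.mu.mean(0)           # (K, 2R)
    Sig_lin = lin.Sigma.mean(0)       # (K, 2R, 2R)
    d2, d3 = 2 * R, 3 * R
    mu_q = np.zeros((K, d3))
    Sig_q = np.zeros((K, d3, d3))
    keep = np.arange(d3).reshape(R, 3)[:, :2].ravel()   # region-major embed
    for k in range(K):
        mu_q[k, keep] = mu_lin[k]
        Sig_q[k][np.ix_(keep, keep)] = Sig_lin[k]
        quad_idx = np.arange(2, d3, 3)
        Sig_q[k][quad_idx, quad_idx] = quad_init_var

    # hard allocations at the linear posterior mode seed the quadratic chain
    z_init = np.asarray(
        [np.bincount(lin.z[:, i], minlength=K).argmax()
         for i in range(lin.z.shape[1])], dtype=int,
    )
    n = len(z_init)
    init = MixtureState(
        pi=lin.pi.mean(0), mu=mu_q, Sigma=Sig_q,
        beta=lin.beta.mean(0), sigma2=lin.sigma2.mean(0),
        z=z_init, b=np.zeros((n, d3)),
    )
    mcmc_q = mcmc_quadratic if mcmc_quadratic is not None else replace(
        spec_linear.mcmc, seed=spec_linear.mcmc.seed + 1
    )
    spec_quad = replace(spec_linear, trend_order=2, mcmc=mcmc_q)
    record = {
        "mu_linear_posterior_mean": mu_lin,
        "mu_quadratic_init": mu_q,
        "Sigma_quadratic_init": Sig_q,
        "embedded_indices": keep,
    }
    quad = gibbs_fit(ds, spec_quad, init=init, init_record=record)
    return lin, quad


# ---------------------------------------------------------------------------
# posterior assignments
# ---------------------------------------------------------------------------

def _result_from_probs(
    probs: np.ndarray, design: _Design,
    ambiguity_max: float = 0.5, ambiguity_second: float = 0.3,
) -> AssignmentResult:
    probs = probs / probs.sum(axis=1, keepdims=True)
    K = probs.shape[1]
    # deterministic tie-break: argmax returns the lowest cluster index
    labels = probs.argmax(axis=1) + 1
    if K > 1:
        sorted_p = np.sort(probs, axis=1)
        ambiguous = (sorted_p[:, -1] < ambiguity_max) & (
            sorted_p[:, -2] > ambiguity_second
        )
    else:
        ambiguous = np.zeros(len(probs), dtype=bool)
    obs_labels = labels[design.subj_idx]
    med_dur = {
        k: (float(np.median(design.t[obs_labels == k]))
            if np.any(obs_labels == k) else float("nan"))
        for k in range(1, K + 1)
    }
    return AssignmentResult(
        subject_ids=design.subject_ids,
        probs=probs, labels=labels, n_visits=design.n_i,
        median_duration=med_dur, ambiguous=ambiguous,
    )


def _assign_from_model(model: MixtureModel, design: _Design) -> AssignmentResult:
    ll = _marginal_logliks(
        design, model.pi, model.mu, model.Sigma, model.beta, model.sigma2
    )
    logp = ll + np.log(model.pi)[None, :]
    logp -= logsumexp(logp, axis=1, keepdims=True)
    return _result_from_probs(np.exp(logp), design)


def posterior_assignments(
    samples: MCMCSamples,
    ds: CohortDataset,
    method: str = "point",
    draw_stride: int = 10,
) -> AssignmentResult:
    """Per-subject cluster probabilities from a fitted chain.

    ``method="point"`` (default) evaluates pi-weighted marginal
    likelihoods at the posterior-mean state; ``method="average"``
    averages the responsibilities over retained draws (every
    ``draw_stride``-th draw).
    """
    design = _Design(
        ds, samples.trend_order, tuple(samples.fixed_covariates),
        etiv_mean=samples.etiv_mean, etiv_sd=samples.etiv_sd,
        cov_center=samples.cov_center,
    )
    if tuple(design.region_names) != tuple(samples.region_names):
        raise SchemaError("dataset regions do not match fitted model")
    model = samples.posterior_mean_model()
    if method == "point":
        return _assign_from_model(model, design)
    if method != "average":
        raise ParameterError(f"unknown assignment method {method!r}")
    acc = np.zeros((design.n, samples.K))
    taken = list(range(0, samples.n_draws, max(draw_stride, 1)))
    for s in taken:
        ll = _marginal_logliks(
            design, samples.pi[s], samples.mu[s], samples.Sigma[s],
            samples.beta[s], samples.sigma2[s],
        )
        logp = ll + np.log(samples.pi[s])[None, :]
        logp -= logsumexp(logp, axis=1, keepdims=True)
        acc += np.exp(logp)
    return _result_from_probs(acc / len(taken), design)
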