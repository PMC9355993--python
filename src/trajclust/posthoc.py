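"""Post-fit analyses: fitted atrophy maps over years from onset,
hierarchical clustering of cluster mean profiles (atrophy "pathways"),
and covariance-network nodal strength.

Fitted maps are posterior medians over retained draws of the cluster
trend polynomial evaluated on a time grid from onset (default 0..8
years), with fixed effects held at reference covariates; atrophy masks
use the conservative (-1.6) and liberal (-0.5) w-value thresholds. No
spatial or temporal smoothing is applied beyond the posterior-median
summarisation (an optional 3-point temporal moving average exists but is
off by default).

Nodal strength of a region is the sum of the absolute correlations of
that region with all others, computed from the intercept or slope block
of a cluster's random-effect covariance matrix — structural (intercept)
vs longitudinal (slope) covariance networks. Cluster pairs are compared
on the posterior distribution of per-region strength differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import NumericalError, ParameterError
from .mixture import MCMCSamples

ATROPHY_THRESHOLDS = (-1.6, -0.5)   # conservative, liberal (w-units)


# ---------------------------------------------------------------------------
# fitted trajectory maps
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryMap:
    """Cluster x time x region fitted w-values with atrophy masks."""

    times: np.ndarray              # (T,) years from onset
    region_names: tuple[str, ...]
    values: np.ndarray             # (K, T, R) posterior-median fitted w
    mask_conservative: np.ndarray  # values <= -1.6
    mask_liberal: np.ndarray       # values <= -0.5

    def to_frame(self) -> pd.DataFrame:
        K, T, R = self.values.shape
        recs = []
        for k in range(K):
            for ti, t in enumerate(self.times):
                for r, name in enumerate(self.region_names):
                    recs.append({
                        "cluster": k + 1, "t_years": float(t), "region": name,
                        "value": self.values[k, ti, r],
                        "atrophic_minus1.6": bool(self.mask_conservative[k, ti, r]),
                        "atrophic_minus0.5": bool(self.mask_liberal[k, ti, r]),
                    })
        return pd.DataFrame(recs)


def fitted_map(
    samples: MCMCSamples,
    times: np.ndarray | None = None,
    reference_covariates: np.ndarray | None = None,
    thresholds: tuple[float, float] = ATROPHY_THRESHOLDS,
    temporal_smooth: bool = False,
) -> TrajectoryMap:
    """Posterior-median fitted w-values on a years-from-onset grid.

    Default grid is 0..8 years in steps of 1; a warning is emitted for
    times outside [0, 8], where the model extrapolates. Reference
    covariates default to a 1.5T scan at average head size (all zeros in
    the coded covariate space).
    """
    times = np.arange(0.0, 9.0) if times is None else np.asarray(times, float)
    if times.min() < 0.0 or times.max() > 8.0:
        warnings.warn(
            "times outside [0, 8] years extrapolate beyond the supported "
            "disease-duration span", stacklevel=2,
        )
    R = len(samples.region_names)
    p = samples.trend_order + 1
    S, K, d = samples.mu.shape
    if reference_covariates is None:
        reference_covariates = np.zeros(len(samples.fixed_covariates))
    x_ref = np.asarray(reference_covariates, float)

    Tpoly = np.column_stack([times ** a for a in range(p)])   # (T, p)
    mu = samples.mu.reshape(S, K, R, p)
    traj = np.einsum("skrp,tp->sktr", mu, Tpoly)              # (S, K, T, R)
    if samples.beta.shape[2]:
        fixed = samples.beta @ x_ref                          # (S, R)
        traj = traj + fixed[:, None, None, :]
    values = np.median(traj, axis=0)                          # (K, T, R)
    if temporal_smooth and len(times) >= 3:
        sm = values.copy()
        sm[:, 1:-1] = (values[:, :-2] + values[:, 1:-1] + values[:, 2:]) / 3.0
        values = sm
    cons, lib = thresholds
    return TrajectoryMap(
        times=times, region_names=tuple(samples.region_names),
        values=values,
        mask_conservative=values <= cons,
        mask_liberal=values <= lib,
    )


# ---------------------------------------------------------------------------
# pathway clustering of cluster mean profiles
# ---------------------------------------------------------------------------

@dataclass
class PathwayDendrogram:
    """Hierarchical grouping of cluster mean intercepts and slopes."""

    intercept_linkage: np.ndarray    # scipy linkage matrix over K clusters
    slope_linkage: np.ndarray
    intercept_groups: np.ndarray     # (K,) flat 2-group cut
    slope_groups: np.ndarray
    cluster_labels: tuple[int, ...]


def pathway_clustering(
    samples: MCMCSamples,
    metric: str = "euclidean",
    method: str = "ward",
) -> PathwayDendrogram:
    """Agglomerative clustering of the K cluster mean vectors, run
    separately on intercepts and slopes, with a 2-group cut.

    Groups clusters that share a spatial atrophy distribution (intercepts)
    or a progression pattern (slopes) — e.g. a mediotemporal vs a cortical
    atrophy pathway.
    """
    K = samples.K
    if K < 2:
        raise ParameterError("pathway clustering needs K >= 2 clusters")
    R = len(samples.region_names)
    p = samples.trend_order + 1
    mu = samples.mu.mean(0).reshape(K, R, p)
    out = {}
    for name, block in (("intercept", 0), ("slope", 1)):
        X = mu[:, :, block]
        lk = linkage(X, method=method, metric=metric)
        out[name] = (lk, fcluster(lk, t=2, criterion="maxclust"))
    return PathwayDendrogram(
        intercept_linkage=out["intercept"][0],
        slope_linkage=out["slope"][0],
        intercept_groups=out["intercept"][1],
        slope_groups=out["slope"][1],
        cluster_labels=tuple(range(1, K + 1)),
    )


# ---------------------------------------------------------------------------
# covariance networks
# ---------------------------------------------------------------------------

def _block_submatrix(Sigma: np.ndarray, block: str, n_trend: int) -> np.ndarray:
    """Extract the R x R intercept or slope block of a region-major
    (R*n_trend) x (R*n_trend) covariance matrix."""
    offset = {"intercept": 0, "slope": 1, "quad": 2}[block]
    if offset >= n_trend:
        raise ParameterError(f"covariance has no {block!r} terms")
    idx = np.arange(offset, Sigma.shape[0], n_trend)
    return Sigma[np.ix_(idx, idx)]


def nodal_strength(
    Sigma: np.ndarray,
    block: str = "slope",
    n_trend: int = 2,
    region_names: tuple[str, ...] | None = None,
    signed: bool = False,
) -> np.ndarray:
    """Per-region nodal strength of the intercept or slope covariance
    network: the sum over all other regions of the (absolute, by default)
    correlation with them.

    ``Sigma`` is a full (R*n_trend)-dimensional random-effect covariance;
    the requested block is converted to a correlation matrix first.
    """
    sub = _block_submatrix(np.asarray(Sigma, float), block, n_trend)
    v = np.diag(sub)
    if np.any(v <= 0):
        bad = np.flatnonzero(v <= 0)
        names = ([region_names[i] for i in bad] if region_names is not None
                 else list(bad))
        raise NumericalError(
            f"zero {block} variance for region(s) {names}: correlation undefined"
        )
    corr = sub / np.sqrt(np.outer(v, v))
    off = corr - np.diag(np.diag(corr))
    if not signed:
        off = np.abs(off)
    return off.sum(axis=1)


@dataclass
class NetworkComparison:
    """Posterior distribution of per-region strength differences
    (reference minus other; positive = reference stronger)."""

    block: str
    cluster_ref: int
    cluster_other: int
    region_names: tuple[str, ...]
    median_diff: np.ndarray      # (R,)
    ci_low: np.ndarray           # (R,) central 95% interval
    ci_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "region": self.region_names,
            "median_diff": self.median_diff,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "excludes_zero": (self.ci_low > 0) | (self.ci_high < 0),
        })


def compare_networks(
    samples: MCMCSamples,
    cluster_ref: int,
    cluster_other: int,
    block: str = "slope",
    ci: float = 0.95,
    signed: bool = False,
) -> NetworkComparison:
    """Pairwise cluster comparison of covariance-network nodal strength.

    For every retained draw of the two clusters' covariance matrices,
    compute per-region strength and its difference (reference minus
    other); report the posterior median and the central ``ci`` interval.
    """
    S = samples.n_draws
    if S < 50:
        warnings.warn(
            f"only {S} retained draws; credible intervals may be unreliable",
            stacklevel=2,
        )
    n_trend = samples.trend_order + 1
    R = len(samples.region_names)
    diffs = np.empty((S, R))
    kr, ko = cluster_ref - 1, cluster_other - 1
    for s in range(S):
        sr = nodal_strength(samples.Sigma[s, kr], block, n_trend,
                            samples.region_names, signed)
        so = nodal_strength(samples.Sigma[s, ko], block, n_trend,
                            samples.region_names, signed)
        diffs[s] = sr - so
    alpha = (1.0 - ci) / 2.0
    return NetworkComparison(
        block=block, cluster_ref=cluster_ref, cluster_other=cluster_other,
        region_names=tuple(samples.region_names),
        median_diff=np.median(diffs, axis=0),
        ci_low=np.quantile(diffs, alpha, axis=0),
        ci_high=np.quantile(diffs, 1.0 - alpha, axis=0),
    )
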