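"""Clustering-quality diagnostics used to compare fits across K.

Two complementary criteria, mirroring how the fits are adjudicated in
practice:

* mean observed-data deviance over retained draws (lower = better fit);
* the fraction of scalar parameter chains whose lag-1 autocorrelation is
  an outlier relative to the majority of chains (lower = better mixing).

"Outlying relative to the majority" is operationalised robustly: a chain
is flagged when its lag-1 autocorrelation exceeds
``median + 3 * MAD_n`` over all chains, where ``MAD_n`` is the
normal-consistent scaled median absolute deviation (1.4826 * MAD). Both
the multiplier and the lag are arguments.

:func:`rank_models` deliberately never auto-selects when deviance and
mixing disagree: it returns the Pareto front and leaves the final call
to the analyst.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .mixture import MCMCSamples

_MAD_SCALE = 1.4826  # normal-consistent MAD


@dataclass
class FitDiagnostics:
    """Quality summary of one fitted chain."""

    K: int
    trend_order: int
    mean_deviance: float
    autocorr_flag_fraction: float
    lag1_autocorr: np.ndarray      # one value per scalar parameter chain
    flagged: np.ndarray            # bool, same length
    chain_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_deviance):
            raise ParameterError("mean deviance must be finite")
        if not 0.0 <= self.autocorr_flag_fraction <= 1.0:
            raise ParameterError("flag fraction must lie in [0, 1]")


def lag1_autocorrelation(chains: np.ndarray) -> np.ndarray:
    """Lag-1 autocorrelation of each column of an (S, P) chain matrix.

    Constant chains have undefined autocorrelation; they are returned as
    1.0 (and should be flagged by the caller) with a warning.
    """
    x = np.asarray(chains, float)
    xc = x - x.mean(axis=0, keepdims=True)
    var = np.sum(xc ** 2, axis=0)
    cov = np.sum(xc[:-1] * xc[1:], axis=0)
    out = np.empty(x.shape[1])
    const = var <= 1e-300
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant parameter chain(s); "
            "autocorrelation undefined, chain flagged", stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(const, 1.0, cov / np.where(const, 1.0, var))
    return out


def flag_outlying_chains(
    ac: np.ndarray, mad_multiplier: float = 3.0
) -> np.ndarray:
    """Boolean mask of chains whose autocorrelation exceeds
    ``median + mad_multiplier * scaled MAD`` of all chains."""
    med = np.median(ac)
    mad = _MAD_SCALE * np.median(np.abs(ac - med))
    return ac > med + mad_multiplier * mad


def _parameter_chains(samples: MCMCSamples) -> tuple[np.ndarray, list[str]]:
    """Stack every scalar parameter chain: pi, mu, diag(Sigma), beta, sigma2."""
    S, K = samples.pi.shape
    d = samples.mu.shape[2]
    cols, names = [], []
    cols.append(samples.pi)
    names += [f"pi[{k + 1}]" for k in range(K)]
    cols.append(samples.mu.reshape(S, K * d))
    names += [f"mu[{k + 1},{j}]" for k in range(K) for j in range(d)]
    diag = np.diagonal(samples.Sigma, axis1=2, axis2=3).reshape(S, K * d)
    cols.append(diag)
    names += [f"Sigma[{k + 1},{j},{j}]" for k in range(K) for j in range(d)]
    if samples.beta.shape[2]:
        R, C = samples.beta.shape[1:]
        cols.append(samples.beta.reshape(S, R * C))
        names += [f"beta[{r},{c}]" for r in range(R) for c in range(C)]
    cols.append(samples.sigma2)
    names += [f"sigma2[{r}]" for r in range(samples.sigma2.shape[1])]
    return np.concatenate(cols, axis=1), names


def compute_diagnostics(
    samples: MCMCSamples, mad_multiplier: float = 3.0
) -> FitDiagnostics:
    """Mean deviance and outlying-autocorrelation flag fraction of a fit."""
    if samples.n_draws < 100:
        raise ParameterError(
            f"need >= 100 retained draws, got {samples.n_draws}"
        )
    chains, names = _parameter_chains(samples)
    ac = lag1_autocorrelation(chains)
    flagged = flag_outlying_chains(ac, mad_multiplier)
    # constant chains are always counted as flagged
    const = np.std(chains, axis=0) <= 1e-150
    flagged = flagged | const
    return FitDiagnostics(
        K=samples.K, trend_order=samples.trend_order,
        mean_deviance=float(samples.deviance.mean()),
        autocorr_flag_fraction=float(flagged.mean()),
        lag1_autocorr=ac, flagged=flagged, chain_names=tuple(names),
    )


@dataclass
class ModelRanking:
    """Pareto front over (mean deviance, flag fraction) plus a deviance
    ranking. ``needs_user_decision`` is True whenever the front holds
    more than one fit — the criteria disagree and a human must choose."""

    diagnostics: list[FitDiagnostics]
    pareto_indices: list[int]
    deviance_order: list[int]

    @property
    def needs_user_decision(self) -> bool:
        return len(self.pareto_indices) > 1

    def to_dict(self) -> dict:
        return {
            "fits": [
                {"K": f.K, "trend_order": f.trend_order,
                 "mean_deviance": f.mean_deviance,
                 "autocorr_flag_fraction": f.autocorr_flag_fraction}
                for f in self.diagnostics
            ],
            "pareto_indices": self.pareto_indices,
            "deviance_order": self.deviance_order,
            "needs_user_decision": self.needs_user_decision,
        }


def rank_models(diags: list[FitDiagnostics]) -> ModelRanking:
    """Pareto front over (mean_deviance, flag fraction), both minimised.

    Never auto-selects when the front has more than one element.
    """
    if len(diags) < 2:
        raise ParameterError("need at least two fits to rank")
    pts = np.array([
        (f.mean_deviance, f.autocorr_flag_fraction) for f in diags
    ])
    front = []
    for i in range(len(pts)):
        dominated = False
        for j in range(len(pts)):
            if j == i:
                continue
            if (pts[j] <= pts[i]).all() and (pts[j] < pts[i]).any():
                dominated = True
                break
        if not dominated:
            front.append(i)
    order = list(np.argsort(pts[:, 0], kind="stable"))
    return ModelRanking(
        diagnostics=list(diags),
        pareto_indices=front,
        deviance_order=[int(i) for i in order],
    )
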