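"""Normative aging models and the w-value transform.

For each region a two-level Gaussian linear mixed model is fitted to the
cognitively-unimpaired (CU) arm:

    y_ijc = beta0 + beta_age * age_ijc + u_c + u_i + e_ijc,
    u_c ~ N(0, var_cohort),  u_i ~ N(0, var_subject),  e ~ N(0, var_resid),

with cohort and subject random intercepts and a fixed linear age effect.
The marginal likelihood is maximised directly (fixed effects profiled out
by GLS; the three variance components optimised on the log-SD scale), with
an optional REML correction.

The w-transform standardises any measurement against this model:

    w = (y - [beta0 + beta_age * age + cohort offset]) / sd,

where the cohort offset is the empirical-Bayes (BLUP) prediction for a
cohort seen in training ("known" mode) and zero for unseen cohorts
("population" mode — the multi-cohort harmonisation rule for data from a
new site). The denominator matches what was subtracted: subject+residual
SD when the cohort offset is removed, the full cohort+subject+residual SD
in population mode, so that CU-like data standardise to mean 0, SD 1 in
either mode. A config switch forces the full marginal SD everywhere for
sensitivity analyses.

Negative w-values indicate atrophy relative to age- and cohort-matched
controls; -1.6 and -0.5 are the conservative and liberal atrophy
thresholds used downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .dataset import CohortDataset
from .errors import ConvergenceError, SchemaError

log = logging.getLogger(__name__)


@dataclass
class NormativeModel:
    """Per-region aging model parameters and variance components.

    ``beta0`` is the fixed intercept on the natural age scale (so the
    predicted cohort-average value at age ``a`` is
    ``beta0 + beta_age * a + cohort_offset``).
    """

    region_names: tuple[str, ...]
    beta0: np.ndarray            # (R,)
    beta_age: np.ndarray         # (R,) units / year
    cohort_ids: tuple[str, ...]
    cohort_offsets: np.ndarray   # (n_cohorts, R) BLUP offsets
    var_cohort: np.ndarray       # (R,)
    var_subject: np.ndarray      # (R,)
    var_resid: np.ndarray        # (R,)
    method: str = "ml"

    def __post_init__(self) -> None:
        R = len(self.region_names)
        for name in ("beta0", "beta_age", "var_cohort", "var_subject", "var_resid"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != (R,):
                raise SchemaError(f"{name} must have shape ({R},)")
            setattr(self, name, arr)
        self.cohort_offsets = np.asarray(self.cohort_offsets, float)
        if self.cohort_offsets.shape != (len(self.cohort_ids), R):
            raise SchemaError("cohort_offsets must be (n_cohorts, R)")

    def total_sd(self, components: str = "all") -> np.ndarray:
        """Marginal SD per region.

        ``components``: ``"all"`` = cohort+subject+residual,
        ``"subject_resid"`` = subject+residual (appropriate once a known
        cohort offset has been subtracted).
        """
        v = self.var_subject + self.var_resid
        if components == "all":
            v = v + self.var_cohort
        elif components != "subject_resid":
            raise SchemaError(f"unknown SD components {components!r}")
        return np.sqrt(v)

    def predicted_mean(
        self, age: np.ndarray, cohort: np.ndarray | None = None
    ) -> np.ndarray:
        """(n, R) predicted cohort-average values at the given ages."""
        age = np.asarray(age, float)
        mean = self.beta0[None, :] + np.outer(age, self.beta_age)
        if cohort is not None:
            idx = {c: i for i, c in enumerate(self.cohort_ids)}
            offs = np.array([self.cohort_offsets[idx[c]] for c in cohort])
            mean = mean + offs
        return mean


def _nll_region(
    log_sds: np.ndarray,
    y_blocks: list[np.ndarray],
    X_blocks: list[np.ndarray],
    same_subj: list[np.ndarray],
    reml: bool,
) -> float:
    """Negative marginal log-likelihood with fixed effects profiled by GLS."""
    vc, vs, ve = np.exp(2.0 * log_sds)
    p = X_blocks[0].shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdet = 0.0
    n_total = 0
    for y, X, B in zip(y_blocks, X_blocks, same_subj):
        m = len(y)
        V = ve * np.eye(m) + vc + vs * B
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        logdet += 2.0 * np.sum(np.log(np.diag(L)))
        rhs = np.column_stack([X, y])
        sol = np.linalg.solve(L, rhs)
        Xs, ys = sol[:, :p], sol[:, p]
        XtVX += Xs.T @ Xs
        XtVy += Xs.T @ ys
        ytVy += ys @ ys
        n_total += m
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return 1e12
    quad = ytVy - beta @ XtVy
    nll = 0.5 * (logdet + quad + n_total * np.log(2.0 * np.pi))
    if reml:
        sign, ld = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return 1e12
        nll += 0.5 * ld
    return float(nll)


def fit_normative(cu: CohortDataset, method: str = "ml") -> NormativeModel:
    """Fit one aging model per region on the CU arm.

    Parameters
    ----------
    cu
        Dataset whose visits are all CU, in raw units.
    method
        ``"ml"`` (default) or ``"reml"``.
    """
    if not (cu.visits["diagnosis"] == "CU").all():
        raise SchemaError("fit_normative expects a CU-only dataset")
    df = cu.visits
    cohorts = tuple(dict.fromkeys(df["cohort_id"]))
    if len(cohorts) < 2:
        warnings.warn(
            "only one cohort in CU data; cohort variance is unidentified",
            stacklevel=2,
        )
    singletons = [
        c for c in cohorts
        if df.loc[df["cohort_id"] == c, "subject_id"].nunique() == 1
    ]
    if singletons:
        warnings.warn(
            f"cohorts with a single subject: {singletons}; their variance "
            "contribution may hit the boundary", stacklevel=2,
        )

    age_center = float(df["age_at_scan"].mean())
    y_all = cu.values_matrix()
    R = cu.atlas.n_regions

    # per-cohort blocks with same-subject indicator matrices
    X_blocks, same_subj, cohort_rows = [], [], []
    for c in cohorts:
        rows = np.flatnonzero((df["cohort_id"] == c).to_numpy())
        cohort_rows.append(rows)
        ages = df["age_at_scan"].to_numpy(float)[rows] - age_center
        X_blocks.append(np.column_stack([np.ones_like(ages), ages]))
        subj = df["subject_id"].to_numpy()[rows]
        same_subj.append((subj[:, None] == subj[None, :]).astype(float))

    beta0 = np.empty(R)
    beta_age = np.empty(R)
    var_c = np.empty(R)
    var_s = np.empty(R)
    var_e = np.empty(R)
    offsets = np.empty((len(cohorts), R))
    reml = method == "reml"

    for r, name in enumerate(cu.atlas.region_names):
        y_blocks = [y_all[rows, r] for rows in cohort_rows]
        # moment-based start: split the pooled residual variance evenly
        resid0 = np.var(np.concatenate(y_blocks))
        s0 = 0.5 * np.log(max(resid0, 1e-8) / 3.0)
        res = minimize(
            _nll_region, x0=np.full(3, s0),
            args=(y_blocks, X_blocks, same_subj, reml),
            method="L-BFGS-B", bounds=[(-8.0, 6.0)] * 3,
            options={"maxiter": 200},
        )
        if not res.success and res.status != 1:  # 1 = maxiter, still usable
            raise ConvergenceError(
                f"normative fit failed for region {name!r}: {res.message}"
            )
        vc, vs, ve = np.exp(2.0 * res.x)
        # recover GLS fixed effects and cohort BLUPs at the optimum
        p = 2
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        chols = []
        for y, X, B in zip(y_blocks, X_blocks, same_subj):
            V = ve * np.eye(len(y)) + vc + vs * B
            L = np.linalg.cholesky(V)
            chols.append(L)
            sol = np.linalg.solve(L, np.column_stack([X, y]))
            XtVX += sol[:, :p].T @ sol[:, :p]
            XtVy += sol[:, :p].T @ sol[:, p]
        beta = np.linalg.solve(XtVX, XtVy)
        b0c, b1 = beta
        beta_age[r] = b1
        beta0[r] = b0c - b1 * age_center
        var_c[r], var_s[r], var_e[r] = vc, vs, ve
        for ci, (y, X, L) in enumerate(zip(y_blocks, X_blocks, chols)):
            resid = y - X @ beta
            z = np.linalg.solve(L, resid)
            Vinv_r = np.linalg.solve(L.T, z)
            offsets[ci, r] = vc * float(np.sum(Vinv_r))

    return NormativeModel(
        region_names=cu.atlas.region_names,
        beta0=beta0, beta_age=beta_age,
        cohort_ids=cohorts, cohort_offsets=offsets,
        var_cohort=var_c, var_subject=var_s, var_resid=var_e,
        method=method,
    )


def w_transform(
    ds: CohortDataset,
    model: NormativeModel,
    cohort_mode: str = "known",
    sd_components: str = "match",
) -> CohortDataset:
    """Standardise a dataset against a fitted normative model.

    Parameters
    ----------
    cohort_mode
        ``"known"`` subtracts the training cohort offsets (errors on a
        cohort absent from training); ``"population"`` uses the population
        mean (offset 0) — the harmonisation rule for unseen cohorts.
    sd_components
        ``"match"`` (default) pairs the SD with what was subtracted:
        subject+residual in known mode, cohort+subject+residual in
        population mode. ``"all"`` always uses the full marginal SD.
    """
    if tuple(ds.atlas.region_names) != tuple(model.region_names):
        raise SchemaError("dataset regions do not match the normative model")
    if cohort_mode not in ("known", "population"):
        raise SchemaError(f"unknown cohort_mode {cohort_mode!r}")

    ages = ds.visits["age_at_scan"].to_numpy(float)
    if cohort_mode == "known":
        unseen = sorted(
            set(ds.visits["cohort_id"]) - set(model.cohort_ids)
        )
        if unseen:
            raise SchemaError(
                f"cohorts {unseen} were not in normative training; "
                "use cohort_mode='population' to harmonise new cohorts"
            )
        mean = model.predicted_mean(ages, ds.visits["cohort_id"].to_numpy())
        comp = "subject_resid" if sd_components == "match" else "all"
    else:
        mean = model.predicted_mean(ages, None)
        comp = "all"
    if sd_components not in ("match", "all"):
        raise SchemaError(f"unknown sd_components {sd_components!r}")
    sd = model.total_sd(comp)
    w = (ds.values_matrix() - mean) / sd[None, :]
    if not np.all(np.isfinite(w)):
        raise SchemaError("w-transform produced non-finite values")
    return ds.with_values(w, unit_state="w")
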