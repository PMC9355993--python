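"""Synthetic multi-cohort longitudinal datasets with known ground truth.

Two arms are generated:

* a cognitively-unimpaired (CU) arm with a linear aging decline per
  region, cohort offsets, subject-level random intercepts and visit
  noise, across ages 50-90 — the training data for the normative model;
* an AD arm anchored at clinical onset, where each subject carries a
  latent cluster label and a subject-specific random intercept/slope
  (optionally quadratic) vector per region drawn from the cluster's
  multivariate Gaussian, plus scanner field-strength and head-size
  (eTIV) nuisance effects — the input to the mixture sampler.

Every latent draw (cohort offsets, subject intercepts, cluster labels,
random-effect vectors) is returned in a truth record so recovery tests
never re-derive latents. Generation is fully deterministic under the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, toy_atlas
from .dataset import CohortDataset
from .errors import ParameterError

_ETIV_MEAN = 1.5e6  # mm^3, log-normal centre for simulated head size
_ETIV_SD = 1.5e5


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class CUSimParams:
    """Generative parameters for the cognitively-unimpaired arm.

    ``cohort_offsets`` may be given explicitly (one vector of length R per
    cohort); if ``None`` they are drawn once per simulation from
    ``Normal(0, sd_cohort)`` and reported in the truth record.
    """

    n_subjects: int = 300
    cohort_ids: Sequence[str] = ("COH_A", "COH_B", "COH_C", "COH_D")
    cohort_offsets: np.ndarray | None = None  # (n_cohorts, R) or None
    age_range: tuple[float, float] = (50.0, 90.0)
    beta0: np.ndarray | float = 2.5          # region baseline at age 0
    beta_age: np.ndarray | float = -0.02     # units / year, decline
    sd_subject: np.ndarray | float = 0.3
    sd_cohort: np.ndarray | float = 0.2
    sd_resid: np.ndarray | float = 0.25
    visits_per_subject: tuple[int, int] = (3, 9)
    visit_spacing: tuple[float, float] = (0.8, 1.4)   # years between visits
    seed: int = 0


@dataclass
class ClusterArchetype:
    """One latent cluster: mean trajectory and random-effect covariance.

    ``mu_intercept``/``mu_slope`` (and optional ``mu_quad``) are in
    w-units; negative intercepts mean atrophy at onset, negative slopes
    mean progressing atrophy. ``Sigma`` is the (R*T)x(R*T) SPD covariance
    of the stacked subject random effects, region-major with T trend
    terms per region (T=2 linear, T=3 quadratic).
    """

    label: str
    weight: float
    mu_intercept: np.ndarray
    mu_slope: np.ndarray
    Sigma: np.ndarray
    mu_quad: np.ndarray | None = None

    @property
    def n_trend(self) -> int:
        return 2 if self.mu_quad is None else 3

    def mean_vector(self) -> np.ndarray:
        """Stacked region-major mean [int_1, slope_1(, quad_1), int_2, ...]."""
        parts = [self.mu_intercept, self.mu_slope]
        if self.mu_quad is not None:
            parts.append(self.mu_quad)
        return np.stack(parts, axis=1).ravel()


@dataclass
class ADSimParams:
    """Generative parameters for the AD arm."""

    archetypes: list[ClusterArchetype]
    n_subjects: int = 150
    cohort_ids: Sequence[str] = ("COH_A", "COH_B")
    onset_age_mean: float = 72.0
    onset_age_sd: float = 7.0
    duration_range: tuple[float, float] = (0.0, 8.0)  # first-visit duration
    visits_per_subject: tuple[int, int] = (3, 5)
    visit_spacing: tuple[float, float] = (0.4, 1.1)
    fs_offset: np.ndarray | float = 0.2    # w-unit shift for 3T scans
    etiv_coef: np.ndarray | float = 0.1    # w-units per SD of eTIV
    sd_resid: np.ndarray | float = 0.25
    seed: int = 0


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _per_region(x: np.ndarray | float, R: int, name: str, positive: bool = False) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(x, float), (R,)).copy()
    if positive and np.any(arr <= 0):
        raise ParameterError(f"{name} must be > 0 (degenerate SD)")
    return arr


def _check_spd(Sigma: np.ndarray, label: str) -> None:
    Sigma = np.asarray(Sigma, float)
    if Sigma.ndim != 2 or Sigma.shape[0] != Sigma.shape[1]:
        raise ParameterError(f"Sigma of archetype {label!r} is not square")
    if not np.allclose(Sigma, Sigma.T, atol=1e-10):
        raise ParameterError(f"Sigma of archetype {label!r} is not symmetric")
    try:
        np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise ParameterError(
            f"Sigma of archetype {label!r} is not positive definite"
        ) from exc


def _simulate_etiv(rng: np.random.Generator, n: int) -> np.ndarray:
    mu = np.log(_ETIV_MEAN) - 0.5 * np.log1p((_ETIV_SD / _ETIV_MEAN) ** 2)
    sig = np.sqrt(np.log1p((_ETIV_SD / _ETIV_MEAN) ** 2))
    return np.exp(rng.normal(mu, sig, size=n))


# ---------------------------------------------------------------------------
# CU arm
# ---------------------------------------------------------------------------

def simulate_cu(
    params: CUSimParams, atlas: RegionAtlas | None = None
) -> tuple[CohortDataset, dict]:
    """Generate the CU aging arm.

    Each visit value is
    ``beta0 + beta_age * age + cohort_offset + subject_intercept + noise``.
    Returns the dataset (unit_state ``"raw"``) and a truth record with the
    drawn cohort offsets and subject intercepts.
    """
    rng = np.random.default_rng(params.seed)
    ncoh = len(params.cohort_ids)
    if ncoh < 1 or params.n_subjects < 1:
        raise ParameterError("need at least one cohort and one subject")
    if atlas is None:
        R = np.broadcast_shapes(
            np.shape(params.beta0), np.shape(params.beta_age), (1,)
        )[0]
        atlas = toy_atlas(max(R, 1))
    R = atlas.n_regions

    beta0 = _per_region(params.beta0, R, "beta0")
    beta_age = _per_region(params.beta_age, R, "beta_age")
    sd_s = _per_region(params.sd_subject, R, "sd_subject", positive=True)
    sd_c = _per_region(params.sd_cohort, R, "sd_cohort", positive=True)
    sd_e = _per_region(params.sd_resid, R, "sd_resid", positive=True)

    if params.cohort_offsets is not None:
        offsets = np.asarray(params.cohort_offsets, float)
        if offsets.shape != (ncoh, R):
            raise ParameterError("cohort_offsets must be (n_cohorts, R)")
    else:
        offsets = rng.normal(0.0, 1.0, size=(ncoh, R)) * sd_c

    lo_age, hi_age = params.age_range
    vmin, vmax = params.visits_per_subject
    if vmin < 1 or vmax < vmin:
        raise ParameterError("invalid visits_per_subject range")

    rows: list[dict] = []
    subj_intercepts = np.empty((params.n_subjects, R))
    subj_meta = []
    for i in range(params.n_subjects):
        sid = f"CU{i + 1:04d}"
        ci = int(rng.integers(ncoh))
        u_i = rng.normal(0.0, 1.0, size=R) * sd_s
        subj_intercepts[i] = u_i
        nv = int(rng.integers(vmin, vmax + 1))
        span = np.sum(rng.uniform(*params.visit_spacing, size=max(nv - 1, 0)))
        start = rng.uniform(lo_age, max(hi_age - span, lo_age))
        gaps = rng.uniform(*params.visit_spacing, size=max(nv - 1, 0))
        ages = start + np.concatenate([[0.0], np.cumsum(gaps)])
        fs = "3T" if rng.random() < 0.5 else "1.5T"
        etiv = float(_simulate_etiv(rng, 1)[0])
        subj_meta.append((sid, params.cohort_ids[ci]))
        for age in ages:
            noise = rng.normal(0.0, 1.0, size=R) * sd_e
            y = beta0 + beta_age * age + offsets[ci] + u_i + noise
            row = {
                "subject_id": sid, "cohort_id": params.cohort_ids[ci],
                "diagnosis": "CU", "age_at_scan": float(age),
                "onset_age": np.nan, "field_strength": fs, "etiv": etiv,
            }
            row.update(dict(zip(atlas.region_names, y)))
            rows.append(row)

    ds = CohortDataset(atlas, pd.DataFrame(rows), unit_state="raw")
    truth = {
        "cohort_offsets": pd.DataFrame(
            offsets, index=list(params.cohort_ids), columns=atlas.region_names
        ),
        "subject_intercepts": pd.DataFrame(
            subj_intercepts,
            index=[m[0] for m in subj_meta],
            columns=atlas.region_names,
        ),
        "subject_cohorts": dict(subj_meta),
        "params": params,
    }
    return ds, truth


# ---------------------------------------------------------------------------
# AD arm
# ---------------------------------------------------------------------------

def simulate_ad(
    params: ADSimParams, atlas: RegionAtlas | None = None
) -> tuple[CohortDataset, dict]:
    """Generate the AD arm in w-units with latent cluster structure.

    Per subject: draw a cluster from the archetype weights, a stacked
    random-effect vector ``b ~ Normal(mu_k, Sigma_k)``, an onset age and
    an irregular visit schedule; each visit value is
    ``fs_offset*1[3T] + etiv_coef*etiv_z + b_r0 + b_r1*t (+ b_r2*t^2) + noise``
    with ``t`` the disease duration in years. Returns the dataset
    (unit_state ``"w"``) and a truth record with labels and latent vectors.
    """
    arcs = params.archetypes
    K = len(arcs)
    if K < 1:
        raise ParameterError("need at least one archetype")
    if params.n_subjects < K:
        raise ParameterError("n_subjects must be >= number of archetypes")
    weights = np.array([a.weight for a in arcs], float)
    if not np.isclose(weights.sum(), 1.0, atol=1e-8):
        raise ParameterError(f"archetype weights sum to {weights.sum()}, not 1")
    lo_d, hi_d = params.duration_range
    if not (0.0 <= lo_d <= hi_d <= 8.0):
        raise ParameterError("duration_range must be within [0, 8] years")

    R = len(np.atleast_1d(arcs[0].mu_intercept))
    if atlas is None:
        atlas = toy_atlas(R)
    if atlas.n_regions != R:
        raise ParameterError("atlas size does not match archetype dimension")
    n_trend = arcs[0].n_trend
    d = R * n_trend
    for a in arcs:
        if a.n_trend != n_trend or len(np.atleast_1d(a.mu_intercept)) != R:
            raise ParameterError("archetypes must share R and trend order")
        if np.asarray(a.Sigma).shape != (d, d):
            raise ParameterError(
                f"archetype {a.label!r}: Sigma must be {d}x{d}"
            )
        _check_spd(np.asarray(a.Sigma, float), a.label)

    fs_off = _per_region(params.fs_offset, R, "fs_offset")
    etiv_coef = _per_region(params.etiv_coef, R, "etiv_coef")
    sd_e = _per_region(params.sd_resid, R, "sd_resid", positive=True)
    vmin, vmax = params.visits_per_subject
    if vmin < 1 or vmax < vmin:
        raise ParameterError("invalid visits_per_subject range")

    rng = np.random.default_rng(params.seed)
    chols = [np.linalg.cholesky(np.asarray(a.Sigma, float)) for a in arcs]
    means = [a.mean_vector() for a in arcs]

    rows: list[dict] = []
    truth_rows: list[dict] = []
    for i in range(params.n_subjects):
        sid = f"AD{i + 1:04d}"
        coh = params.cohort_ids[int(rng.integers(len(params.cohort_ids)))]
        k = int(rng.choice(K, p=weights))
        b = means[k] + chols[k] @ rng.standard_normal(d)
        onset = rng.normal(params.onset_age_mean, params.onset_age_sd)
        nv = int(rng.integers(vmin, vmax + 1))
        t0 = rng.uniform(lo_d, hi_d)
        gaps = rng.uniform(*params.visit_spacing, size=max(nv - 1, 0))
        ts = t0 + np.concatenate([[0.0], np.cumsum(gaps)])
        fs = "3T" if rng.random() < 0.5 else "1.5T"
        etiv = float(_simulate_etiv(rng, 1)[0])
        etiv_z = (etiv - _ETIV_MEAN) / _ETIV_SD
        b_mat = b.reshape(R, n_trend)
        for t in ts:
            tv = np.array([1.0, t, t * t])[:n_trend]
            mean_w = b_mat @ tv + fs_off * (fs == "3T") + etiv_coef * etiv_z
            y = mean_w + rng.normal(0.0, 1.0, size=R) * sd_e
            row = {
                "subject_id": sid, "cohort_id": coh, "diagnosis": "AD",
                "age_at_scan": float(onset + t), "onset_age": float(onset),
                "field_strength": fs, "etiv": etiv,
            }
            row.update(dict(zip(atlas.region_names, y)))
            rows.append(row)
        trow = {"subject_id": sid, "cluster": k + 1, "cluster_label": arcs[k].label}
        trow.update({f"b_{j}": b[j] for j in range(d)})
        truth_rows.append(trow)

    ds = CohortDataset(atlas, pd.DataFrame(rows), unit_state="w")
    truth = {
        "labels": pd.DataFrame(truth_rows),
        "archetypes": arcs,
        "params": params,
    }
    return ds, truth


# ---------------------------------------------------------------------------
# qualitative presets
# ---------------------------------------------------------------------------

def _block_sigma(
    R: int,
    n_mt: int,
    sd_int: float = 0.3,
    sd_slope: float = 0.08,
    rho_within: float = 0.3,
    rho_between: float = 0.1,
    rho_int_slope: float = 0.1,
) -> np.ndarray:
    """Region-major SPD covariance with a medial-temporal/cortical block
    correlation structure shared by the presets."""
    blocks = np.array([0] * n_mt + [1] * (R - n_mt))
    corr_regions = np.where(
        blocks[:, None] == blocks[None, :], rho_within, rho_between
    )
    np.fill_diagonal(corr_regions, 1.0)
    # trend-term correlation (intercept vs slope within a region)
    corr_trend = np.array([[1.0, rho_int_slope], [rho_int_slope, 1.0]])
    corr = np.kron(corr_regions, corr_trend)
    sds = np.tile([sd_int, sd_slope], R)
    Sigma = corr * np.outer(sds, sds)
    # small ridge keeps the kron-composed correlation safely SPD
    Sigma += 1e-8 * np.eye(2 * R)
    return Sigma


def _archetype(label, weight, R, n_mt, int_mt, int_cx, slope_mt, slope_cx, Sigma):
    mu_i = np.array([int_mt] * n_mt + [int_cx] * (R - n_mt), float)
    mu_s = np.array([slope_mt] * n_mt + [slope_cx] * (R - n_mt), float)
    return ClusterArchetype(label, weight, mu_i, mu_s, Sigma)


def preset_three_patterns(R: int = 6, seed: int = 0) -> ADSimParams:
    """Three well-separated archetypes: minimal, limbic-predominant and
    cortical-predominant atrophy.

    Mean separations exceed two marginal random-effect SDs in most
    regions, the regime in which cluster recovery should be essentially
    exact. Intended for recovery and classification experiments.
    """
    if R < 4:
        raise ParameterError("need R >= 4 so medial-temporal and cortical blocks exist")
    n_mt = max(2, R // 3)
    Sigma = _block_sigma(R, n_mt, sd_int=0.3, sd_slope=0.08)
    arcs = [
        _archetype("minimal", 0.5, R, n_mt, -0.3, -0.2, -0.05, -0.05, Sigma),
        _archetype("limbic", 0.3, R, n_mt, -1.8, -0.6, -0.20, -0.10, Sigma),
        _archetype("cortical", 0.2, R, n_mt, -0.6, -1.6, -0.12, -0.30, Sigma),
    ]
    return ADSimParams(archetypes=arcs, n_subjects=150, seed=seed)


def preset_five_patterns(R: int = 8, seed: int = 0) -> ADSimParams:
    """Five archetypes echoing the qualitative atrophy-pattern taxonomy:
    minimal (MA), limbic predominant (LPA), fast limbic predominant
    (LPA+), diffuse (DA) and hippocampal sparing (HS).

    Shapes are qualitative stand-ins, not estimates of any fitted
    clusters: MA is least atrophic at onset in the medial-temporal
    block, HS is most atrophic in the cortical block but least in the
    medial-temporal block, LPA+ progresses faster than LPA, and the
    slope geometry separates the slower {MA, LPA, LPA+} group from the
    faster {DA, HS} group. Weights loosely follow the usual dominance
    of the minimal and limbic patterns while keeping every cluster
    large enough to be identifiable at a few hundred subjects.
    """
    if R < 4:
        raise ParameterError("need R >= 4 so medial-temporal and cortical blocks exist")
    n_mt = max(2, R // 3)
    Sigma = _block_sigma(R, n_mt, sd_int=0.30, sd_slope=0.08)
    arcs = [
        #            label  weight        int_mt int_cx  sl_mt  sl_cx
        _archetype("MA",   0.50, R, n_mt, -0.30, -0.20, -0.06, -0.05, Sigma),
        _archetype("LPA",  0.28, R, n_mt, -1.50, -0.50, -0.12, -0.06, Sigma),
        _archetype("LPA+", 0.10, R, n_mt, -2.40, -0.90, -0.30, -0.12, Sigma),
        _archetype("DA",   0.05, R, n_mt, -1.20, -1.30, -0.25, -0.30, Sigma),
        _archetype("HS",   0.07, R, n_mt, -0.25, -1.80, -0.15, -0.45, Sigma),
    ]
    return ADSimParams(archetypes=arcs, n_subjects=400, seed=seed)


def preset_plateau(R: int = 5, seed: int = 0, quad: float = 0.035) -> ADSimParams:
    """Single-archetype generator with a quadratic plateau.

    Atrophy declines steeply early (negative slope) and flattens with
    duration (positive quadratic term), the shape the stepwise
    linear-to-quadratic fitting strategy is designed to capture. Set
    ``quad=0.0`` for a purely linear control.
    """
    mu_i = np.full(R, -0.8)
    mu_s = np.full(R, -0.45)
    if quad == 0.0:
        # purely linear control: no quadratic term in the generator at all
        sds = np.tile([0.3, 0.08], R)
        arc = ClusterArchetype("linear", 1.0, mu_i, mu_s, np.diag(sds ** 2))
    else:
        mu_q = np.full(R, quad)
        sds = np.tile([0.3, 0.08, 0.015], R)
        arc = ClusterArchetype(
            "plateau", 1.0, mu_i, mu_s, np.diag(sds ** 2), mu_quad=mu_q
        )
    return ADSimParams(archetypes=[arc], n_subjects=100, seed=seed)
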