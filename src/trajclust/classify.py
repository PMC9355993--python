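"""Using a fitted discovery model as a classifier, and matching clusters
across independently fitted models.

A fitted mixture gives, for any new subject with one or more visits, the
closed-form marginal likelihood of their w-value trajectory under each
cluster; pi-weighted and normalised, these are posterior cluster
probabilities. Because random effects are integrated out analytically,
the classifier works cross-sectionally: a single visit constrains the
intercepts and (weakly) the slopes, so most single-visit subjects are
still assignable, with flatter probability vectors than multi-visit
subjects.

Clusters of two independently fitted models are matched by the Euclidean
distance between their concatenated posterior-mean intercept and slope
vectors, solved as an exact assignment problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .dataset import CohortDataset
from .errors import SchemaError
from .mixture import (
    AssignmentResult,
    MCMCSamples,
    MixtureModel,
    _assign_from_model,
    _Design,
)


def _as_model(model_or_samples: MixtureModel | MCMCSamples) -> MixtureModel:
    if isinstance(model_or_samples, MCMCSamples):
        return model_or_samples.posterior_mean_model()
    return model_or_samples


def classify_new(
    model_or_samples: MixtureModel | MCMCSamples,
    new_ds: CohortDataset,
) -> AssignmentResult:
    """Assign unseen subjects (single-visit included) to fitted clusters.

    ``new_ds`` must be w-transformed with the same normative model as the
    discovery data (population mode for cohorts the normative model never
    saw). eTIV is standardised with the scaling stored in the fitted
    model, not re-estimated on the new data.
    """
    model = _as_model(model_or_samples)
    if tuple(new_ds.atlas.region_names) != tuple(model.region_names):
        raise SchemaError("new dataset regions do not match the fitted model")
    design = _Design(
        new_ds, model.trend_order, tuple(model.fixed_covariates),
        etiv_mean=model.etiv_mean, etiv_sd=model.etiv_sd,
        cov_center=model.cov_center,
    )
    return _assign_from_model(model, design)


@dataclass
class ConcordanceReport:
    """Median observed w-values per cluster vs model fitted values at the
    cluster's median disease duration."""

    per_region: pd.DataFrame   # columns: cluster, region, observed, fitted, diff
    summary: pd.DataFrame      # columns: cluster, n_subjects, median_duration, mad

    @property
    def mean_abs_difference(self) -> float:
        return float(self.per_region["diff"].abs().mean())


def validation_concordance(
    model_or_samples: MixtureModel | MCMCSamples,
    assignments: AssignmentResult,
    new_ds: CohortDataset,
    reference_covariates: np.ndarray | None = None,
) -> ConcordanceReport:
    """Compare per-cluster median observed maps with model fitted values.

    For each cluster: the median observed w-value per region over all
    visits of assigned subjects, against the model's fitted value
    ``mu_r0 + mu_r1 * t_med (+ mu_r2 * t_med^2)`` at the cluster's median
    disease duration (fixed effects held at the reference covariates,
    default 1.5T and average head size). Clusters with no assigned
    subjects are reported as empty rather than raising.
    """
    model = _as_model(model_or_samples)
    R = model.n_regions
    if reference_covariates is None:
        reference_covariates = np.zeros(len(model.fixed_covariates))
    x_ref = np.asarray(reference_covariates, float)
    fixed = model.beta @ x_ref if model.beta.size else np.zeros(R)

    df = new_ds.visits
    label_of = dict(zip(assignments.subject_ids, assignments.labels))
    obs_labels = df["subject_id"].map(label_of)
    W = new_ds.values_matrix()
    mu3 = model.mu.reshape(model.K, R, model.n_trend)

    rows, srows = [], []
    for k in range(1, model.K + 1):
        mask = (obs_labels == k).to_numpy()
        n_subj = int(np.sum(assignments.labels == k))
        if not mask.any():
            srows.append({"cluster": k, "n_subjects": 0,
                          "median_duration": np.nan, "mad": np.nan})
            continue
        t_med = float(np.median(df.loc[mask, "disease_duration"]))
        tv = np.array([1.0, t_med, t_med ** 2])[: model.n_trend]
        fitted = mu3[k - 1] @ tv + fixed
        observed = np.median(W[mask], axis=0)
        for r, name in enumerate(model.region_names):
            rows.append({
                "cluster": k, "region": name,
                "observed": observed[r], "fitted": fitted[r],
                "diff": observed[r] - fitted[r],
            })
        srows.append({
            "cluster": k, "n_subjects": n_subj,
            "median_duration": t_med,
            "mad": float(np.mean(np.abs(observed - fitted))),
        })
    return ConcordanceReport(
        per_region=pd.DataFrame(rows), summary=pd.DataFrame(srows)
    )


@dataclass
class ClusterMatch:
    """Injective mapping between the clusters of two fitted models."""

    mapping: dict[int, int]        # cluster of model A -> cluster of model B
    distances: np.ndarray          # (K_a, K_b) Euclidean distances
    matched_distances: dict[int, float]

    def total_distance(self) -> float:
        return float(sum(self.matched_distances.values()))


def _intercept_slope_matrix(model: MixtureModel) -> np.ndarray:
    """(K, 2R) concatenated posterior-mean intercepts and slopes."""
    return np.concatenate(
        [model.mu_block("intercept"), model.mu_block("slope")], axis=1
    )


def match_clusters(
    model_a: MixtureModel | MCMCSamples,
    model_b: MixtureModel | MCMCSamples,
) -> ClusterMatch:
    """Optimal injective cluster matching on (intercept, slope) means.

    Solves the assignment problem exactly, minimising the total Euclidean
    distance between the concatenated intercept and slope mean vectors.
    """
    a, b = _as_model(model_a), _as_model(model_b)
    if tuple(a.region_names) != tuple(b.region_names):
        raise SchemaError("models were fitted on different atlases")
    Fa, Fb = _intercept_slope_matrix(a), _intercept_slope_matrix(b)
    dist = np.linalg.norm(Fa[:, None, :] - Fb[None, :, :], axis=2)
    if a.K <= b.K:
        rows, cols = linear_sum_assignment(dist)
    else:
        cols, rows = linear_sum_assignment(dist.T)
        order = np.argsort(rows)
        rows, cols = rows[order], cols[order]
    mapping = {int(r) + 1: int(c) + 1 for r, c in zip(rows, cols)}
    matched = {int(r) + 1: float(dist[r, c]) for r, c in zip(rows, cols)}
    return ClusterMatch(mapping=mapping, distances=dist,
                        matched_distances=matched)
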