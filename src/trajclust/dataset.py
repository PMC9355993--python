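"""Visit tables: the cohort dataset container and CSV ingest/egress.

A :class:`CohortDataset` holds one row per MRI visit with demographics,
nuisance covariates and the R-dimensional regional measurement vector in
canonical atlas order. Rows are kept sorted by ``subject_id`` then
``age_at_scan`` so that two loads of the same file are bit-identical in
memory and all samplers see subjects in a reproducible order.

Disease duration (years between clinical onset and the scan) is derived
at ingest for AD rows; visits that predate the recorded onset are
rejected because the trajectory model is defined from onset onward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .errors import (
    EmptyDatasetError,
    NegativeDurationError,
    ParseError,
    SchemaError,
)

log = logging.getLogger(__name__)

#: non-region columns every visit table must carry
SCHEMA_COLUMNS = [
    "subject_id",
    "cohort_id",
    "diagnosis",
    "age_at_scan",
    "onset_age",
    "field_strength",
    "etiv",
]

VALID_DIAGNOSES = {"CU", "AD"}
VALID_FIELD_STRENGTHS = {"1.5T", "3T"}


@dataclass(frozen=True)
class CohortDataset:
    """Validated per-visit table plus its atlas and unit state.

    ``unit_state`` is ``"raw"`` for native units (mm / mm^3) and ``"w"``
    after normative standardisation.
    """

    atlas: RegionAtlas
    visits: pd.DataFrame
    unit_state: str = "raw"

    def __post_init__(self) -> None:
        if self.unit_state not in ("raw", "w"):
            raise SchemaError(f"unknown unit_state {self.unit_state!r}")
        df = _validate_table(self.visits, self.atlas)
        object.__setattr__(self, "visits", df)

    # -- basic accessors -------------------------------------------------
    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def subject_ids(self) -> list[str]:
        return list(dict.fromkeys(self.visits["subject_id"]))

    @property
    def n_subjects(self) -> int:
        return self.visits["subject_id"].nunique()

    def values_matrix(self) -> np.ndarray:
        """(n_visits, R) measurement matrix in canonical atlas order."""
        return self.visits[list(self.atlas.region_names)].to_numpy(float)

    def subset_diagnosis(self, diagnosis: str) -> "CohortDataset":
        df = self.visits[self.visits["diagnosis"] == diagnosis]
        if df.empty:
            raise EmptyDatasetError(f"no {diagnosis} visits in dataset")
        return replace(self, visits=df.reset_index(drop=True))

    def subset_subjects(self, ids: Iterable[str]) -> "CohortDataset":
        keep = set(ids)
        df = self.visits[self.visits["subject_id"].isin(keep)]
        if df.empty:
            raise EmptyDatasetError("subject subset is empty")
        return replace(self, visits=df.reset_index(drop=True))

    def with_values(self, values: np.ndarray, unit_state: str) -> "CohortDataset":
        """Copy of the dataset with the region columns replaced."""
        values = np.asarray(values, float)
        if values.shape != (self.n_visits, self.atlas.n_regions):
            raise SchemaError("replacement values have wrong shape")
        df = self.visits.copy()
        df[list(self.atlas.region_names)] = values
        return CohortDataset(self.atlas, df, unit_state)


def _validate_table(df: pd.DataFrame, atlas: RegionAtlas) -> pd.DataFrame:
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    missing += [r for r in atlas.region_names if r not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    cols = SCHEMA_COLUMNS + list(atlas.region_names)
    df = df[cols].copy()

    bad_rows: list[str] = []
    for col in ["age_at_scan", "etiv", *atlas.region_names]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(
                f"non-numeric value in column {col!r} at rows {list(bad[:5])}"
            )
        df[col] = vals
    df["onset_age"] = pd.to_numeric(df["onset_age"], errors="coerce")

    diag_bad = ~df["diagnosis"].isin(VALID_DIAGNOSES)
    if diag_bad.any():
        bad_rows.append(f"invalid diagnosis at rows {list(df.index[diag_bad][:5])}")
    fs_bad = ~df["field_strength"].isin(VALID_FIELD_STRENGTHS)
    if fs_bad.any():
        bad_rows.append(
            f"invalid field_strength at rows {list(df.index[fs_bad][:5])}"
        )
    if (df["age_at_scan"] <= 0).any() or df["age_at_scan"].isna().any():
        bad_rows.append("age_at_scan must be positive and present")
    if (df["etiv"] <= 0).any() or df["etiv"].isna().any():
        bad_rows.append("etiv must be positive and present")

    is_ad = df["diagnosis"] == "AD"
    no_onset = is_ad & df["onset_age"].isna()
    if no_onset.any():
        bad_rows.append(
            f"AD rows lacking onset_age at rows {list(df.index[no_onset][:5])}"
        )
    nan_regions = df[list(atlas.region_names)].isna().any(axis=1)
    if nan_regions.any():
        bad_rows.append(
            f"missing region values at rows {list(df.index[nan_regions][:5])}"
            " (visits with missing regions must be dropped upstream)"
        )
    if bad_rows:
        raise SchemaError("; ".join(bad_rows))

    dur = df["age_at_scan"] - df["onset_age"]
    neg = is_ad & (dur < 0)
    if neg.any():
        raise NegativeDurationError(
            "AD visits predate the recorded onset age at rows "
            f"{list(df.index[neg][:10])}"
        )
    df["disease_duration"] = np.where(is_ad, dur, np.nan)

    df = df.sort_values(["subject_id", "age_at_scan"], kind="mergesort")
    order = ["subject_id", "cohort_id", "diagnosis", "age_at_scan",
             "onset_age", "disease_duration", "field_strength", "etiv",
             *atlas.region_names]
    return df[order].reset_index(drop=True)


def read_visits(
    path: str | Path, atlas: RegionAtlas, unit_state: str = "raw"
) -> CohortDataset:
    """Read a comma-separated visit table and validate it against ``atlas``.

    The header must contain the schema columns plus one column per atlas
    region (any column order; values are re-ordered to canonical atlas
    order). Lines starting with ``#`` are treated as comments.
    """
    df = pd.read_csv(path, comment="#", dtype={"subject_id": str, "cohort_id": str})
    return CohortDataset(atlas, df, unit_state)


def write_visits(ds: CohortDataset, path: str | Path, header_comment: str | None = None) -> None:
    """Write the visit table as CSV (canonical column and row order)."""
    cols = SCHEMA_COLUMNS + list(ds.atlas.region_names)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        ds.visits[cols].to_csv(fh, index=False)


def filter_discovery(ds: CohortDataset, min_visits: int = 3) -> CohortDataset:
    """Retain subjects with at least ``min_visits`` visits.

    Mirrors the discovery-set inclusion rule (subjects with more than two
    MRI visits, i.e. ``min_visits=3`` by default). Logs the visit-count
    histogram of the input.
    """
    counts = ds.visits.groupby("subject_id", sort=True).size()
    hist = counts.value_counts().sort_index()
    log.info("visit-count histogram: %s", hist.to_dict())
    keep = counts.index[counts >= min_visits]
    if len(keep) == 0:
        raise EmptyDatasetError(
            f"no subject has >= {min_visits} visits (max observed: {counts.max()})"
        )
    df = ds.visits[ds.visits["subject_id"].isin(set(keep))]
    return replace(ds, visits=df.reset_index(drop=True))


def average_hemispheres(
    df: pd.DataFrame, left_suffix: str = "_lh", right_suffix: str = "_rh"
) -> pd.DataFrame:
    """Average paired left/right region columns into a single column.

    Columns ``X_lh``/``X_rh`` are replaced by ``X``; unpaired columns are
    passed through unchanged. Helper for upstream tables that were not
    hemisphere-averaged.
    """
    out = df.copy()
    lefts = [c for c in df.columns if c.endswith(left_suffix)]
    for lc in lefts:
        base = lc[: -len(left_suffix)]
        rc = base + right_suffix
        if rc in df.columns:
            out[base] = (pd.to_numeric(df[lc]) + pd.to_numeric(df[rc])) / 2.0
            out = out.drop(columns=[lc, rc])
    return out
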