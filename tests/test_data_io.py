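"""Visit-table schema, ingest validation, filtering and archive round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import trajclust as tc
from trajclust.errors import (
    ArchiveIntegrityError,
    EmptyDatasetError,
    NegativeDurationError,
    ParseError,
    SchemaError,
)


def _toy_frame(atlas, rows):
    cols = ["subject_id", "cohort_id", "diagnosis", "age_at_scan",
            "onset_age", "field_strength", "etiv", *atlas.region_names]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture
def atlas2():
    return tc.toy_atlas(2)


@pytest.fixture
def toy_ds(atlas2):
    rows = [
        ("s1", "A", "CU", 70.0, None, "3T", 1.4e6, 2.5, 2.4),
        ("s1", "A", "CU", 71.0, None, "3T", 1.4e6, 2.4, 2.3),
        ("s2", "B", "AD", 68.0, 66.0, "1.5T", 1.6e6, 2.0, 1.9),
    ]
    return tc.CohortDataset(atlas2, _toy_frame(atlas2, rows))


def test_toy_table_echoes_input(toy_ds):
    assert toy_ds.n_subjects == 2
    assert toy_ds.atlas.n_regions == 2
    assert toy_ds.n_visits == 3
    dur = toy_ds.visits.loc[toy_ds.visits.diagnosis == "AD", "disease_duration"]
    assert float(dur.iloc[0]) == pytest.approx(2.0)


def test_ad_row_without_onset_rejected(atlas2):
    rows = [("s1", "A", "AD", 70.0, None, "3T", 1.5e6, 2.0, 2.0)]
    with pytest.raises(SchemaError, match="onset_age"):
        tc.CohortDataset(atlas2, _toy_frame(atlas2, rows))


def test_scan_before_onset_rejected(atlas2):
    rows = [("s1", "A", "AD", 64.0, 66.0, "3T", 1.5e6, 2.0, 2.0)]
    with pytest.raises(NegativeDurationError):
        tc.CohortDataset(atlas2, _toy_frame(atlas2, rows))


def test_non_numeric_region_value_names_column(atlas2, tmp_path):
    rows = [("s1", "A", "CU", 70.0, None, "3T", 1.5e6, "oops", 2.0)]
    _toy_frame(atlas2, rows).to_csv(tmp_path / "v.csv", index=False)
    with pytest.raises(ParseError, match="region_1"):
        tc.read_visits(tmp_path / "v.csv", atlas2)


def test_missing_column_is_schema_error(atlas2, tmp_path):
    df = pd.DataFrame({"subject_id": ["s1"], "region_1": [2.0]})
    df.to_csv(tmp_path / "v.csv", index=False)
    with pytest.raises(SchemaError, match="missing required columns"):
        tc.read_visits(tmp_path / "v.csv", atlas2)


def test_permuted_region_columns_reordered(toy_ds, tmp_path, atlas2):
    path = tmp_path / "v.csv"
    tc.write_visits(toy_ds, path)
    df = pd.read_csv(path)
    df = df[[c for c in df.columns if c not in atlas2.region_names]
            + list(atlas2.region_names)[::-1]]
    path2 = tmp_path / "perm.csv"
    df.to_csv(path2, index=False)
    again = tc.read_visits(path2, atlas2)
    np.testing.assert_array_equal(again.values_matrix(), toy_ds.values_matrix())


def test_round_trip_and_canonical_order(toy_ds, tmp_path):
    path = tmp_path / "v.csv"
    tc.write_visits(toy_ds, path)
    back = tc.read_visits(path, toy_ds.atlas)
    pd.testing.assert_frame_equal(back.visits, toy_ds.visits)
    # shuffled rows load to the identical in-memory ordering
    df = pd.read_csv(path).sample(frac=1.0, random_state=0)
    path2 = tmp_path / "shuf.csv"
    df.to_csv(path2, index=False)
    shuffled = tc.read_visits(path2, toy_ds.atlas)
    pd.testing.assert_frame_equal(shuffled.visits, toy_ds.visits)


@given(st.integers(1, 6))
def test_filter_discovery_matches_brute_force(min_visits):
    params = tc.preset_three_patterns(R=4, seed=5)
    params.n_subjects = 40
    params.visits_per_subject = (1, 6)
    ds, _ = tc.simulate_ad(params)
    counts = ds.visits.groupby("subject_id").size()
    expected = {s for s, c in counts.items() if c >= min_visits}
    if not expected:
        with pytest.raises(EmptyDatasetError):
            tc.filter_discovery(ds, min_visits)
        return
    kept = tc.filter_discovery(ds, min_visits)
    assert set(kept.subject_ids) == expected
    if min_visits == 1:
        assert kept.n_visits == ds.n_visits


def test_filter_discovery_counts():
    atlas = tc.toy_atlas(1)
    rows = []
    for sid, nv in [("a", 1), ("b", 2), ("c", 3), ("d", 5)]:
        for j in range(nv):
            rows.append((sid, "A", "CU", 70.0 + j, None, "3T", 1.5e6, 2.0))
    ds = tc.CohortDataset(atlas, _toy_frame(atlas, rows))
    assert tc.filter_discovery(ds, 3).n_subjects == 2


def test_average_hemispheres():
    df = pd.DataFrame({"hippocampus_lh": [2.0], "hippocampus_rh": [4.0],
                       "subject_id": ["s"]})
    out = tc.average_hemispheres(df)
    assert out["hippocampus"].iloc[0] == 3.0
    assert "hippocampus_lh" not in out


def test_atlas_json_round_trip(tmp_path):
    atlas = tc.desikan_atlas()
    assert atlas.n_regions == 41
    atlas.to_json(tmp_path / "a.json")
    again = tc.RegionAtlas.from_json(tmp_path / "a.json")
    assert again == atlas
    with pytest.raises(SchemaError):
        tc.RegionAtlas(("a", "a"))


def test_normative_archive_round_trip(tmp_path, normative_model):
    path = tmp_path / "norm.h5"
    tc.write_model_archive(normative_model, path)
    back, samples = tc.read_model_archive(path)
    assert samples is None
    np.testing.assert_array_equal(back.beta_age, normative_model.beta_age)
    np.testing.assert_array_equal(back.cohort_offsets,
                                  normative_model.cohort_offsets)
    assert back.cohort_ids == normative_model.cohort_ids


def test_mixture_archive_round_trip_bitexact(tmp_path, fit_small):
    path = tmp_path / "fit.h5"
    model = fit_small.posterior_mean_model()
    tc.write_model_archive(model, path, samples=fit_small)
    back, samples = tc.read_model_archive(path)
    np.testing.assert_array_equal(back.mu, model.mu)
    np.testing.assert_array_equal(samples.deviance, fit_small.deviance)
    np.testing.assert_array_equal(samples.Sigma, fit_small.Sigma)
    assert samples.subject_ids == fit_small.subject_ids


def test_truncated_archive_raises(tmp_path, fit_small):
    path = tmp_path / "fit.h5"
    tc.write_model_archive(fit_small.posterior_mean_model(), path,
                           samples=fit_small)
    blob = path.read_bytes()
    path.write_bytes(blob[: len(blob) // 2])
    with pytest.raises(ArchiveIntegrityError):
        tc.read_model_archive(path)
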