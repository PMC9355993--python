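"""Normative aging model: marginal-ML recovery, an independent mixed-model
cross-check, and the standardisation properties of the w-transform."""

import numpy as np
import pytest

import trajclust as tc
from trajclust.errors import SchemaError


def test_noise_free_limit_recovers_age_slope_exactly():
    p = tc.CUSimParams(
        n_subjects=30, sd_subject=1e-7, sd_cohort=1e-7, sd_resid=1e-7,
        beta_age=-0.02, seed=1,
    )
    ds, _ = tc.simulate_cu(p, tc.toy_atlas(2))
    model = tc.fit_normative(ds)
    np.testing.assert_allclose(model.beta_age, -0.02, atol=1e-6)


def test_parameter_recovery(cu_data, normative_model):
    _, truth = cu_data
    m = normative_model
    # slope: pooled mean within 10%, each region within 20% (per-region
    # slope SEs at n=300 make a one-draw per-region 10% band underpowered)
    assert m.beta_age.mean() == pytest.approx(-0.02, rel=0.10)
    np.testing.assert_allclose(m.beta_age, -0.02, rtol=0.20)
    np.testing.assert_allclose(np.sqrt(m.var_subject), 0.3, rtol=0.20)
    np.testing.assert_allclose(np.sqrt(m.var_resid), 0.25, rtol=0.20)
    # cohort SD pooled across regions (12 cohorts give few df per region)
    rms = np.sqrt(m.var_cohort.mean())
    assert abs(rms - 0.2) / 0.2 < 0.20


def test_subject_order_permutation_invariance(cu_data):
    ds, _ = cu_data
    model_a = tc.fit_normative(ds)
    df = ds.visits.sample(frac=1.0, random_state=5).reset_index(drop=True)
    model_b = tc.fit_normative(tc.CohortDataset(ds.atlas, df))
    np.testing.assert_allclose(model_a.beta_age, model_b.beta_age, atol=1e-10)
    np.testing.assert_allclose(model_a.var_subject, model_b.var_subject,
                               atol=1e-10)


def test_against_statsmodels_mixed_model():
    """Independent oracle: statsmodels MixedLM with a subject variance
    component nested in cohort groups, ML, on a single region."""
    import statsmodels.formula.api as smf

    p = tc.CUSimParams(n_subjects=80, cohort_ids=("A", "B", "C", "D"),
                       seed=17)
    ds, _ = tc.simulate_cu(p, tc.toy_atlas(1))
    model = tc.fit_normative(ds)

    df = ds.visits.rename(columns={"region_1": "y"})
    md = smf.mixedlm(
        "y ~ age_at_scan", df, groups="cohort_id",
        re_formula="1", vc_formula={"subject": "0 + C(subject_id)"},
    )
    fit = md.fit(reml=False, method="lbfgs")
    assert model.beta_age[0] == pytest.approx(fit.params["age_at_scan"],
                                              rel=0.02)
    assert model.var_resid[0] == pytest.approx(fit.scale, rel=0.10)
    vc_subj = float(fit.vcomp[0])
    assert model.var_subject[0] == pytest.approx(vc_subj, rel=0.15)


def test_w_zero_at_predicted_mean(normative_model):
    m = normative_model
    atlas = tc.toy_atlas(4)
    age = 72.0
    coh = m.cohort_ids[0]
    pred = m.predicted_mean(np.array([age]), np.array([coh]))[0]
    import pandas as pd
    row = {"subject_id": "x", "cohort_id": coh, "diagnosis": "CU",
           "age_at_scan": age, "onset_age": None, "field_strength": "3T",
           "etiv": 1.5e6}
    row.update(dict(zip(atlas.region_names, pred)))
    ds = tc.CohortDataset(atlas, pd.DataFrame([row]))
    w = tc.w_transform(ds, m, cohort_mode="known")
    np.testing.assert_allclose(w.values_matrix(), 0.0, atol=1e-10)
    # 1.6 SD below the prediction maps exactly to the atrophy threshold
    sd = m.total_sd("subject_resid")
    row2 = dict(row)
    row2.update(dict(zip(atlas.region_names, pred - 1.6 * sd)))
    ds2 = tc.CohortDataset(atlas, pd.DataFrame([row2]))
    w2 = tc.w_transform(ds2, m, cohort_mode="known")
    np.testing.assert_allclose(w2.values_matrix(), -1.6, atol=1e-10)


def test_unknown_cohort_errors_and_population_mode(normative_model):
    p = tc.CUSimParams(n_subjects=40, cohort_ids=("NEW",), seed=9)
    ds, _ = tc.simulate_cu(p, tc.toy_atlas(4))
    with pytest.raises(SchemaError, match="population"):
        tc.w_transform(ds, normative_model, cohort_mode="known")
    w = tc.w_transform(ds, normative_model, cohort_mode="population")
    assert np.all(np.isfinite(w.values_matrix()))


def test_training_data_self_standardises(cu_data, normative_model):
    ds, _ = cu_data
    w = tc.w_transform(ds, normative_model, cohort_mode="known")
    W = w.values_matrix()
    assert np.all(np.abs(W.mean(axis=0)) <= 0.05)
    assert np.all((W.std(axis=0) >= 0.95) & (W.std(axis=0) <= 1.05))


def test_age_effect_removed_from_cu_wvalues(cu_data, normative_model):
    ds, _ = cu_data
    w = tc.w_transform(ds, normative_model, cohort_mode="known")
    ages = w.visits["age_at_scan"].to_numpy()
    X = np.column_stack([np.ones_like(ages), ages])
    for r in range(4):
        y = w.values_matrix()[:, r]
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        se = np.sqrt(resid.var() / np.sum((ages - ages.mean()) ** 2))
        assert abs(coef[1]) < 2 * se


def test_w_monotone_in_y(normative_model):
    m = normative_model
    atlas = tc.toy_atlas(4)
    import pandas as pd
    rows = []
    for v in (1.8, 2.0, 2.2):
        row = {"subject_id": f"s{v}", "cohort_id": m.cohort_ids[0],
               "diagnosis": "CU", "age_at_scan": 70.0, "onset_age": None,
               "field_strength": "3T", "etiv": 1.5e6}
        row.update({r: v for r in atlas.region_names})
        rows.append(row)
    ds = tc.CohortDataset(atlas, pd.DataFrame(rows))
    W = tc.w_transform(ds, m, cohort_mode="known").values_matrix()
    assert np.all(np.diff(W, axis=0) > 0)


def test_reml_switch_runs():
    p = tc.CUSimParams(n_subjects=40, cohort_ids=("A", "B", "C"), seed=23)
    ds, _ = tc.simulate_cu(p, tc.toy_atlas(2))
    m = tc.fit_normative(ds, method="reml")
    assert m.method == "reml"
    assert np.all(m.var_resid > 0)
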