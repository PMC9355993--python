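"""Generator contracts: determinism, noise-free limits, moment recovery,
and the qualitative geometry of the atrophy-pattern presets."""

import numpy as np
import pytest

import trajclust as tc
from trajclust.errors import ParameterError


def test_cu_noise_free_limit_is_linear():
    params = tc.CUSimParams(
        n_subjects=10, sd_subject=1e-9, sd_cohort=1e-9, sd_resid=1e-9,
        beta0=2.5, beta_age=-0.01, seed=0,
    )
    ds, _ = tc.simulate_cu(params, tc.toy_atlas(2))
    ages = ds.visits["age_at_scan"].to_numpy()
    vals = ds.values_matrix()
    expect = np.tile(2.5 - 0.01 * ages[:, None], (1, 2))
    np.testing.assert_allclose(vals, expect, atol=1e-6)


def test_cu_zero_sd_rejected():
    with pytest.raises(ParameterError):
        tc.simulate_cu(tc.CUSimParams(n_subjects=5, sd_resid=0.0),
                       tc.toy_atlas(2))


def test_determinism_under_seed():
    p = tc.CUSimParams(n_subjects=20, seed=7)
    a, _ = tc.simulate_cu(p, tc.toy_atlas(3))
    b, _ = tc.simulate_cu(p, tc.toy_atlas(3))
    np.testing.assert_array_equal(a.values_matrix(), b.values_matrix())
    p5 = tc.preset_three_patterns(R=4, seed=5)
    c, tc1 = tc.simulate_ad(p5)
    d, tc2 = tc.simulate_ad(p5)
    np.testing.assert_array_equal(c.values_matrix(), d.values_matrix())
    assert tc1["labels"].equals(tc2["labels"])


def test_cu_subject_variance_moment_recovery():
    p = tc.CUSimParams(n_subjects=300, sd_subject=0.3, seed=13)
    _, truth = tc.simulate_cu(p, tc.toy_atlas(4))
    emp = truth["subject_intercepts"].to_numpy().var(axis=0)
    # pooled over the 4 independent regions: a 2% statistic tested at 15%
    assert np.mean(emp) == pytest.approx(0.09, rel=0.15)


def test_ad_single_archetype_noise_free_polynomial():
    R = 3
    arc = tc.ClusterArchetype(
        "x", 1.0,
        mu_intercept=np.array([-1.0, -0.5, -2.0]),
        mu_slope=np.array([-0.2, -0.1, -0.3]),
        Sigma=1e-18 * np.eye(2 * R),
    )
    p = tc.ADSimParams(archetypes=[arc], n_subjects=8, sd_resid=1e-9,
                       fs_offset=0.0, etiv_coef=0.0, seed=2)
    ds, _ = tc.simulate_ad(p)
    t = ds.visits["disease_duration"].to_numpy()
    expect = arc.mu_intercept[None, :] + np.outer(t, arc.mu_slope)
    np.testing.assert_allclose(ds.values_matrix(), expect, atol=1e-6)


def test_ad_weight_counts_within_binomial_bound():
    p = tc.preset_three_patterns(R=4, seed=11)
    p.archetypes[0].weight, p.archetypes[1].weight = 0.6, 0.4
    p.archetypes = p.archetypes[:2]
    p.n_subjects = 1000
    _, truth = tc.simulate_ad(p)
    n1 = int((truth["labels"]["cluster"] == 1).sum())
    # central 99% binomial interval for n=1000, p=0.6
    sd = np.sqrt(1000 * 0.6 * 0.4)
    assert abs(n1 - 600) <= 2.58 * sd


def test_quadratic_archetype_concave_increments():
    p = tc.preset_plateau(R=3, seed=1, quad=0.02)
    arc = p.archetypes[0]
    t = np.arange(0.0, 8.0)
    traj = arc.mu_intercept[0] + arc.mu_slope[0] * t + arc.mu_quad[0] * t ** 2
    incr = np.diff(traj)
    assert np.all(np.diff(incr) > 0)  # positive quad flattens the decline
    # and a negative quadratic term gives decreasing increments (concave)
    traj2 = arc.mu_intercept[0] + arc.mu_slope[0] * t - 0.02 * t ** 2
    assert np.all(np.diff(np.diff(traj2)) < 0)


def test_non_spd_sigma_rejected():
    R = 2
    bad = np.array([[1.0, 2.0, 0, 0], [2.0, 1.0, 0, 0],
                    [0, 0, 1.0, 0], [0, 0, 0, 1.0]])
    arc = tc.ClusterArchetype("x", 1.0, np.zeros(R), np.zeros(R), bad)
    with pytest.raises(ParameterError, match="positive definite"):
        tc.simulate_ad(tc.ADSimParams(archetypes=[arc], n_subjects=4))


@pytest.mark.parametrize("preset,K", [
    (tc.preset_three_patterns, 3), (tc.preset_five_patterns, 5),
])
def test_preset_invariants(preset, K):
    p = preset(R=6, seed=0)
    assert len(p.archetypes) == K
    assert np.isclose(sum(a.weight for a in p.archetypes), 1.0)
    for a in p.archetypes:
        np.linalg.cholesky(a.Sigma)
    with pytest.raises(ParameterError):
        preset(R=3, seed=0)


def test_preset_five_qualitative_ordering():
    p = tc.preset_five_patterns(R=8, seed=0)
    arcs = {a.label: a for a in p.archetypes}
    n_mt = max(2, 8 // 3)
    # MA less atrophic at onset than LPA+ in the medial-temporal block
    assert arcs["MA"].mu_intercept[0] > arcs["LPA+"].mu_intercept[0]
    # HS most atrophic in the cortical block, least in the MT block
    for lab in ("MA", "LPA", "LPA+", "DA"):
        assert arcs["HS"].mu_intercept[n_mt] < arcs[lab].mu_intercept[n_mt]
        assert arcs["HS"].mu_intercept[0] > arcs[lab].mu_intercept[0]
    # LPA+ progresses faster than LPA everywhere
    assert np.all(arcs["LPA+"].mu_slope < arcs["LPA"].mu_slope)


def test_preset_sample_means_recover_archetypes():
    p = tc.preset_five_patterns(R=6, seed=21)
    p.n_subjects = 500
    _, truth = tc.simulate_ad(p)
    lab = truth["labels"]
    d = 12
    for k, arc in enumerate(p.archetypes, start=1):
        members = lab[lab["cluster"] == k]
        b = members[[f"b_{j}" for j in range(d)]].to_numpy()
        emp_int = b.reshape(len(b), 6, 2)[:, :, 0].mean(axis=0)
        # mean absolute deviation across regions within 0.1 w-units
        assert np.mean(np.abs(emp_int - arc.mu_intercept)) < 0.1


def test_visit_schedule_within_duration_design():
    p = tc.preset_three_patterns(R=4, seed=3)
    p.duration_range = (0.0, 5.0)
    ds, _ = tc.simulate_ad(p)
    first = ds.visits.groupby("subject_id")["disease_duration"].min()
    assert (first >= 0).all() and (first <= 5.0).all()
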