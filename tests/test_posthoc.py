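"""Fitted atrophy maps, pathway dendrograms and covariance-network
nodal strength."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

import trajclust as tc
from trajclust.errors import NumericalError, ParameterError
from trajclust.posthoc import nodal_strength


def test_map_at_onset_equals_intercept_summaries(fit_small):
    tm = tc.fitted_map(fit_small, times=np.array([0.0]))
    S, K, d = fit_small.mu.shape
    R = len(fit_small.region_names)
    mu_int = fit_small.mu.reshape(S, K, R, 2)[:, :, :, 0]
    fixed = fit_small.beta @ np.zeros(2)
    expected = np.median(mu_int + fixed[:, None, :], axis=0)
    np.testing.assert_allclose(tm.values[:, 0, :], expected, atol=1e-12)


def test_single_draw_median_is_that_draw(fit_small):
    one = dataclasses.replace(
        fit_small, pi=fit_small.pi[:1], mu=fit_small.mu[:1],
        Sigma=fit_small.Sigma[:1], beta=fit_small.beta[:1],
        sigma2=fit_small.sigma2[:1], z=fit_small.z[:1],
        deviance=fit_small.deviance[:1],
    )
    tm = tc.fitted_map(one, times=np.array([0.0, 2.0]))
    R = len(one.region_names)
    mu3 = one.mu[0].reshape(3, R, 2)
    expect_t2 = mu3[:, :, 0] + 2.0 * mu3[:, :, 1]
    np.testing.assert_allclose(tm.values[:, 1, :], expect_t2, atol=1e-12)


def test_threshold_mask_semantics(fit_small):
    tm = tc.fitted_map(fit_small)
    v = tm.values
    np.testing.assert_array_equal(tm.mask_conservative, v <= -1.6)
    np.testing.assert_array_equal(tm.mask_liberal, v <= -0.5)
    # -1.7 is atrophic under both thresholds, -1.5 only under the liberal one
    assert (-1.7 <= -1.6) and not (-1.5 <= -1.6) and (-1.5 <= -0.5)


def test_map_warns_outside_supported_span(fit_small):
    with pytest.warns(UserWarning, match="extrapolate"):
        tc.fitted_map(fit_small, times=np.array([0.0, 10.0]))


def test_pathway_identical_clusters_merge_first(fit_small):
    twin = dataclasses.replace(fit_small, mu=fit_small.mu.copy())
    twin.mu[:, 1] = twin.mu[:, 0]   # make clusters 1 and 2 identical
    dend = tc.pathway_clustering(twin)
    assert set(dend.slope_linkage[0, :2]) == {0.0, 1.0}
    assert dend.slope_groups[0] == dend.slope_groups[1]
    assert dend.slope_groups[2] != dend.slope_groups[0]


def test_pathway_invariant_to_region_order(fit_small):
    dend = tc.pathway_clustering(fit_small)
    R = len(fit_small.region_names)
    perm = np.random.default_rng(1).permutation(R)
    S, K, d = fit_small.mu.shape
    mu5 = fit_small.mu.reshape(S, K, R, 2)[:, :, perm, :].reshape(S, K, d)
    shuffled = dataclasses.replace(
        fit_small, mu=mu5,
        region_names=tuple(np.array(fit_small.region_names)[perm]),
    )
    dend2 = tc.pathway_clustering(shuffled)
    np.testing.assert_allclose(dend.slope_linkage[:, 2],
                               dend2.slope_linkage[:, 2], atol=1e-12)


def test_pathway_requires_multiple_clusters(fit_small):
    one = dataclasses.replace(
        fit_small, K=1, pi=fit_small.pi[:, :1], mu=fit_small.mu[:, :1],
        Sigma=fit_small.Sigma[:, :1],
    )
    with pytest.raises(ParameterError):
        tc.pathway_clustering(one)


def test_nodal_strength_diagonal_is_zero():
    Sigma = np.diag([0.1, 0.01, 0.2, 0.02])
    np.testing.assert_allclose(
        nodal_strength(Sigma, "intercept", 2), 0.0, atol=1e-15
    )


def test_nodal_strength_uniform_half_correlation():
    R = 3
    corr = np.full((R, R), 0.5)
    np.fill_diagonal(corr, 1.0)
    # embed as the intercept block of a trend-2 covariance
    Sigma = np.zeros((2 * R, 2 * R))
    idx = np.arange(0, 2 * R, 2)
    Sigma[np.ix_(idx, idx)] = corr
    Sigma[np.ix_(idx + 1, idx + 1)] = np.eye(R)
    np.testing.assert_allclose(nodal_strength(Sigma, "intercept", 2), 1.0)


def test_nodal_strength_zero_variance_errors():
    Sigma = np.diag([0.1, 0.01, 0.0, 0.02])
    with pytest.raises(NumericalError, match="region"):
        nodal_strength(Sigma, "intercept", 2, region_names=("a", "b"))


@given(st.integers(0, 1000))
def test_nodal_strength_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    R = 8
    A = rng.standard_normal((2 * R, 2 * R))
    Sigma = A @ A.T + 2 * R * np.eye(2 * R)
    for block, off in (("intercept", 0), ("slope", 1)):
        got = nodal_strength(Sigma, block, 2)
        idx = np.arange(off, 2 * R, 2)
        sub = Sigma[np.ix_(idx, idx)]
        brute = np.zeros(R)
        for r in range(R):
            for s in range(R):
                if s != r:
                    brute[r] += abs(
                        sub[r, s] / np.sqrt(sub[r, r] * sub[s, s])
                    )
        np.testing.assert_allclose(got, brute, atol=1e-12)


def test_network_self_comparison_is_zero(fit_small):
    cmp_ = tc.compare_networks(fit_small, 1, 1, "slope")
    np.testing.assert_array_equal(cmp_.median_diff, 0.0)
    np.testing.assert_array_equal(cmp_.ci_low, 0.0)


def test_network_comparison_antisymmetric(fit_small):
    ab = tc.compare_networks(fit_small, 1, 2, "slope")
    ba = tc.compare_networks(fit_small, 2, 1, "slope")
    np.testing.assert_allclose(ab.median_diff, -ba.median_diff, atol=1e-12)


def test_constructed_contrast_detected():
    """A reference cluster whose off-diagonal correlations are uniformly
    doubled must show positive strength differences excluding zero."""
    rng = np.random.default_rng(7)
    R, S = 6, 500
    base_corr = np.full((R, R), 0.2)
    np.fill_diagonal(base_corr, 1.0)
    strong_corr = np.full((R, R), 0.4)
    np.fill_diagonal(strong_corr, 1.0)
    d = 2 * R
    Sig = np.zeros((S, 2, d, d))
    idx = np.arange(0, d, 2)
    for s in range(S):
        noise = 0.01 * rng.standard_normal((R, R))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        Sig[s, 0][np.ix_(idx, idx)] = strong_corr + noise
        Sig[s, 1][np.ix_(idx, idx)] = base_corr + noise
        Sig[s, :, idx + 1, idx + 1] = 1.0
    samples = tc.MCMCSamples(
        K=2, trend_order=1,
        region_names=tuple(f"r{i}" for i in range(R)),
        fixed_covariates=(), etiv_mean=0.0, etiv_sd=1.0,
        cov_center=np.empty(0), subject_ids=("s1",),
        pi=np.full((S, 2), 0.5), mu=np.zeros((S, 2, d)), Sigma=Sig,
        beta=np.zeros((S, R, 0)), sigma2=np.ones((S, R)),
        z=np.zeros((S, 1), dtype=int), deviance=np.zeros(S),
        n_iter=S, burn_in=0, thin=1, seed=0,
    )
    cmp_ = tc.compare_networks(samples, 1, 2, "intercept")
    assert np.all(cmp_.median_diff > 0)
    assert np.all(cmp_.ci_low > 0)


def test_few_draws_warn(fit_small):
    short = dataclasses.replace(
        fit_small, pi=fit_small.pi[:20], mu=fit_small.mu[:20],
        Sigma=fit_small.Sigma[:20], beta=fit_small.beta[:20],
        sigma2=fit_small.sigma2[:20], z=fit_small.z[:20],
        deviance=fit_small.deviance[:20],
    )
    with pytest.warns(UserWarning, match="draws"):
        tc.compare_networks(short, 1, 2, "slope")
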