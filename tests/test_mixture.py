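"""Sampler contracts: determinism, exchangeability, simplex/SPD invariants,
closed-form marginal likelihood identities, and stepwise initialisation."""

import numpy as np
import pandas as pd
import pytest

import trajclust as tc
from trajclust.mixture import _Design, _marginal_logliks, marginal_cluster_loglik


def _tiny_spec(K, seed, n_iter=300):
    return tc.MixtureSpec(
        K=K, n_restarts=0,
        mcmc=tc.MCMCOptions(n_iter=n_iter, burn_in=n_iter // 2, thin=1,
                            seed=seed),
    )


@pytest.fixture(scope="module")
def tiny_ad():
    p = tc.preset_three_patterns(R=4, seed=4)
    p.n_subjects = 24
    ds, truth = tc.simulate_ad(p)
    return ds, truth


def test_fixed_seed_chains_bit_identical(tiny_ad):
    ds, _ = tiny_ad
    spec = _tiny_spec(2, seed=5)
    a = tc.gibbs_fit(ds, spec)
    b = tc.gibbs_fit(ds, spec)
    np.testing.assert_array_equal(a.mu, b.mu)
    np.testing.assert_array_equal(a.Sigma, b.Sigma)
    np.testing.assert_array_equal(a.deviance, b.deviance)
    np.testing.assert_array_equal(a.z, b.z)


def test_subject_order_exchangeability(tiny_ad):
    ds, _ = tiny_ad
    spec = _tiny_spec(2, seed=5)
    a = tc.gibbs_fit(ds, spec)
    df = ds.visits.sample(frac=1.0, random_state=11).reset_index(drop=True)
    b = tc.gibbs_fit(tc.CohortDataset(ds.atlas, df, "w"), spec)
    np.testing.assert_array_equal(a.mu, b.mu)
    np.testing.assert_array_equal(a.pi, b.pi)


def test_draws_on_simplex_and_spd(fit_small):
    s = fit_small
    np.testing.assert_allclose(s.pi.sum(axis=1), 1.0, atol=1e-12)
    for draw in s.Sigma:
        np.linalg.cholesky(draw)   # SPD for every retained draw
    assert np.all(s.sigma2 > 0)
    assert s.n_draws == (500 - 250) // 1


def test_retained_draw_count_honours_thinning(tiny_ad):
    ds, _ = tiny_ad
    spec = tc.MixtureSpec(
        K=1, mcmc=tc.MCMCOptions(n_iter=200, burn_in=80, thin=3, seed=0),
    )
    s = tc.gibbs_fit(ds, spec)
    assert s.n_draws == (200 - 80) // 3


def _toy_model(Sigma_scale=1.0):
    R = 2
    Sigma = np.array([
        [0.09, 0.01, 0.02, 0.0],
        [0.01, 0.0064, 0.0, 0.001],
        [0.02, 0.0, 0.09, 0.01],
        [0.0, 0.001, 0.01, 0.0064],
    ]) * Sigma_scale
    return tc.MixtureModel(
        K=1, trend_order=1, region_names=("a", "b"),
        fixed_covariates=("field_strength", "etiv"),
        etiv_mean=1.5e6, etiv_sd=1.5e5, cov_center=np.array([0.5, 0.0]),
        pi=np.array([1.0]), mu=np.array([[-1.0, -0.2, -0.5, -0.1]]),
        Sigma=Sigma[None], beta=np.array([[0.2, 0.1], [0.15, 0.05]]),
        sigma2=np.array([0.06, 0.05]),
    )


def test_marginal_reduces_to_independent_normals_when_sigma_vanishes():
    model = _toy_model(Sigma_scale=1e-14)
    y = np.array([[-1.2, -0.7]])
    t = np.array([2.0])
    x = np.array([0.5, 0.4])
    got = marginal_cluster_loglik(model, y, t, x, 0)
    mu3 = model.mu[0].reshape(2, 2)
    mean = mu3[:, 0] + mu3[:, 1] * 2.0 + model.beta @ x
    expected = sum(
        -0.5 * (np.log(2 * np.pi * model.sigma2[r])
                + (y[0, r] - mean[r]) ** 2 / model.sigma2[r])
        for r in range(2)
    )
    assert got == pytest.approx(expected, rel=1e-9)


def test_duplicated_visit_changes_marginal():
    model = _toy_model()
    y = np.array([[-1.2, -0.7], [-1.4, -0.9]])
    t = np.array([1.0, 3.0])
    x = np.array([0.5, 0.4])
    single = marginal_cluster_loglik(model, y, t, x, 0)
    dup = marginal_cluster_loglik(
        model, np.vstack([y, y[-1:]]), np.r_[t, t[-1]], x, 0
    )
    assert dup != pytest.approx(single)


def test_batched_marginal_matches_dense_per_subject(tiny_ad):
    """The Woodbury/batched path and the dense observation-space path are
    independent implementations of the same Gaussian marginal."""
    ds, _ = tiny_ad
    spec = _tiny_spec(2, seed=5)
    s = tc.gibbs_fit(ds, spec)
    model = s.posterior_mean_model()
    design = _Design(ds, 1, model.fixed_covariates,
                     etiv_mean=model.etiv_mean, etiv_sd=model.etiv_sd,
                     cov_center=model.cov_center)
    batched = _marginal_logliks(design, model.pi, model.mu, model.Sigma,
                                model.beta, model.sigma2)
    for i in (0, 5, len(design.subject_ids) - 1):
        sl = slice(design.starts[i], design.starts[i] + design.n_i[i])
        for k in range(model.K):
            dense = marginal_cluster_loglik(
                model, design.Y[sl], design.t[sl], design.X[sl], k,
            )
            assert batched[i, k] == pytest.approx(dense, rel=1e-9)


def test_identical_clusters_give_symmetric_probabilities(tiny_ad):
    ds, _ = tiny_ad
    spec = _tiny_spec(2, seed=5)
    s = tc.gibbs_fit(ds, spec)
    model = s.posterior_mean_model()
    model.mu[1] = model.mu[0]
    model.Sigma[1] = model.Sigma[0]
    model.pi = np.array([0.5, 0.5])
    res = tc.classify_new(model, ds)
    np.testing.assert_allclose(res.probs, 0.5, atol=1e-12)


def test_subject_at_cluster_mean_with_tiny_noise_is_certain():
    p = tc.preset_three_patterns(R=4, seed=6)
    arcs = p.archetypes
    model = tc.MixtureModel(
        K=3, trend_order=1, region_names=tuple(f"region_{i+1}" for i in range(4)),
        fixed_covariates=(), etiv_mean=1.5e6, etiv_sd=1.5e5,
        cov_center=np.empty(0),
        pi=np.array([a.weight for a in arcs]),
        mu=np.array([a.mean_vector() for a in arcs]),
        Sigma=np.array([a.Sigma for a in arcs]),
        beta=np.empty((4, 0)), sigma2=np.full(4, 1e-6),
    )
    t = np.array([0.0, 1.0, 2.0])
    arc = arcs[1]
    y = arc.mu_intercept[None, :] + np.outer(t, arc.mu_slope)
    lls = [marginal_cluster_loglik(model, y, t, None, k) for k in range(3)]
    lls = np.array(lls)
    probs = np.exp(lls - lls.max()) * model.pi
    probs /= probs.sum()
    assert probs[1] > 0.999


def test_k1_probabilities_identically_one(tiny_ad):
    ds, _ = tiny_ad
    s = tc.gibbs_fit(ds, _tiny_spec(1, seed=3, n_iter=200))
    res = tc.posterior_assignments(s, ds)
    np.testing.assert_allclose(res.probs, 1.0, atol=1e-15)
    assert set(res.labels) == {1}


def test_single_visit_subjects_are_fitable():
    p = tc.preset_three_patterns(R=4, seed=8)
    p.n_subjects = 20
    p.visits_per_subject = (1, 3)
    ds, _ = tc.simulate_ad(p)
    assert (ds.visits.groupby("subject_id").size() == 1).any()
    s = tc.gibbs_fit(ds, _tiny_spec(2, seed=1, n_iter=200))
    assert np.all(np.isfinite(s.deviance))


def test_stepwise_quadratic_initialisation_record(tiny_ad):
    ds, _ = tiny_ad
    spec = _tiny_spec(1, seed=7, n_iter=200)
    lin, quad = tc.fit_stepwise_quadratic(ds, spec)
    rec = quad.init_record
    np.testing.assert_array_equal(
        rec["mu_quadratic_init"][:, rec["embedded_indices"]],
        rec["mu_linear_posterior_mean"],
    )
    np.testing.assert_array_equal(rec["mu_linear_posterior_mean"],
                                  lin.mu.mean(0))
    quad_idx = np.arange(2, quad.mu.shape[2], 3)
    assert np.all(rec["mu_quadratic_init"][:, quad_idx] == 0.0)


def test_average_assignment_option_close_to_point(fit_small, ad_small):
    ds, _ = ad_small
    pt = tc.posterior_assignments(fit_small, ds, method="point")
    av = tc.posterior_assignments(fit_small, ds, method="average",
                                  draw_stride=25)
    assert np.mean(pt.labels == av.labels) >= 0.9
    np.testing.assert_allclose(av.probs.sum(axis=1), 1.0, atol=1e-12)
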