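"""Shared fixtures: small synthetic datasets and fitted chains.

Expensive fits are session-scoped and shared across test modules; every
fixture is fully deterministic under hard-coded seeds.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import trajclust as tc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def atlas4():
    return tc.toy_atlas(4)


@pytest.fixture(scope="session")
def ad_small():
    """30-subject, 4-region, 3-cluster AD dataset with truth labels."""
    params = tc.preset_three_patterns(R=4, seed=1)
    params.n_subjects = 30
    return tc.simulate_ad(params)


@pytest.fixture(scope="session")
def fit_small(ad_small):
    """Small 3-cluster fit shared by diagnostics / posthoc / classify tests."""
    ds, _ = ad_small
    spec = tc.MixtureSpec(
        K=3, n_restarts=2, pilot_sweeps=100,
        mcmc=tc.MCMCOptions(n_iter=500, burn_in=250, thin=1, seed=9),
    )
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return tc.gibbs_fit(ds, spec)


@pytest.fixture(scope="session")
def cu_data():
    """CU arm with known parameters over 12 cohorts (normative tests)."""
    params = tc.CUSimParams(
        n_subjects=300,
        cohort_ids=tuple(f"C{i:02d}" for i in range(12)),
        seed=3,
    )
    return tc.simulate_cu(params, tc.toy_atlas(4))


@pytest.fixture(scope="session")
def normative_model(cu_data):
    ds, _ = cu_data
    return tc.fit_normative(ds)


@pytest.fixture(scope="session")
def three_cluster_fit():
    """Discovery-scale 3-cluster recovery fit (n=150, R=6, 4000 sweeps).

    Shared by the cluster-recovery and single-visit-classification
    acceptance tests.
    """
    params = tc.preset_three_patterns(R=6, seed=7)
    ds, truth = tc.simulate_ad(params)
    spec = tc.MixtureSpec(
        K=3,
        mcmc=tc.MCMCOptions(n_iter=4000, burn_in=2000, thin=2, seed=11),
    )
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        samples = tc.gibbs_fit(ds, spec)
    return ds, truth, samples
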