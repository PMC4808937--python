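"""Shared fixtures: small synthetic studies and fitted models.

Session-scoped fits are shared across test modules to keep the suite fast;
tests must treat them as read-only.
"""

import numpy as np
import pytest

import emglmm as eg


@pytest.fixture(scope="session")
def medium_spec():
    """A compact design with one term of each kind (7 covariates per muscle)."""
    return eg.DesignSpec(
        main_effects=("intercept", "elevation", "move_up", "affected", "chemo", "spadi_pain"),
        affected_interactions=("spadi_pain",),
        affected_only=("exercise_now",),
    )


@pytest.fixture(scope="session")
def balanced_covariates():
    """Prevalences pushed toward 0.5 so tiny studies stay full rank."""
    return eg.CovariateModel(p_exercise_now=0.5, p_physio_now=0.5, p_exercise_6m=0.5)


@pytest.fixture(scope="session")
def medium_truth(medium_spec):
    return eg.default_truth(medium_spec)


@pytest.fixture(scope="session")
def small_study(medium_spec, balanced_covariates):
    """12 patients, series of 4 elevations, compact design."""
    cfg = eg.SyntheticConfig(
        n_patients=12,
        max_elevation=40,
        design=medium_spec,
        covariates=balanced_covariates,
        seed=20,
    )
    return eg.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_fits(small_study, medium_spec):
    """ML fits of all three ladder variants on the small study."""
    return {
        v: eg.fit(small_study, medium_spec, v, eg.FitOptions(seed=0))
        for v in ("model3", "model4", "model6")
    }


@pytest.fixture(scope="session")
def default_study():
    """A 30-patient study under the full default design and truth."""
    cfg = eg.SyntheticConfig(n_patients=30, max_elevation=80, seed=21)
    return eg.simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
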