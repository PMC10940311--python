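import numpy as np
import pytest

from mirtide import CohortConfig, generate_cohort, fit_stepwise, split_train_test
from mirtide.shapley import stepwise_importance

# moderately sized forests for test-scale cohorts; library defaults are the
# full-cohort grid-search winners and are exercised separately
DESK_FOREST = {
    "ctl": {"n_estimators": 60, "max_features": "sqrt"},
    "dysfunction": {"n_estimators": 60, "max_depth": 12, "max_features": 0.5},
    "exclusion": {"n_estimators": 60, "max_depth": 12, "max_features": 0.5},
}


@pytest.fixture(scope="session")
def small_cohort():
    """A cohort with planted signal, shared across read-only tests."""
    return generate_cohort(CohortConfig(n_samples=500, n_mirnas=120, seed=11))


@pytest.fixture(scope="session")
def fitted_forest(small_cohort):
    """A fitted forest stepwise model plus its splits (read-only)."""
    c = small_cohort
    x_tr, y_tr, x_te, y_te = split_train_test(c.expression, c.labels, seed=11)
    model = fit_stepwise(x_tr, y_tr, family="forest", hyperparams=DESK_FOREST, seed=11)
    return {"model": model, "x_tr": x_tr, "y_tr": y_tr, "x_te": x_te, "y_te": y_te}


@pytest.fixture(scope="session")
def forest_importance(fitted_forest):
    f = fitted_forest
    return stepwise_importance(f["model"], f["x_te"], f["x_tr"])


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
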