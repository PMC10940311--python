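import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Ridge
from sklearn.metrics import mean_squared_error
from sklearn.model_selection import KFold, ParameterGrid

from mirtide import (
    CohortConfig,
    fit_direct_baseline,
    fit_stepwise,
    generate_cohort,
    grid_search_cv,
    predict_stepwise,
    split_train_test,
)
from mirtide.stepwise import ctl_scores, load_model, save_model

from _oracles import manual_grid_search


def test_routing_invariant_on_every_prediction(fitted_forest):
    f = fitted_forest
    pred = predict_stepwise(f["model"], f["x_te"])
    ctl = pred["predicted_ctl"].to_numpy()
    tide = pred["predicted_tide"].to_numpy()
    assert np.array_equal(tide[ctl], pred["predicted_dysfunction"].to_numpy()[ctl])
    assert np.array_equal(tide[~ctl], pred["predicted_exclusion"].to_numpy()[~ctl])
    # per-sample brute check on a random subset
    rng = np.random.default_rng(0)
    for i in rng.choice(len(pred), size=50, replace=True):
        row = pred.iloc[i]
        assert row["predicted_tide"] in (row["predicted_dysfunction"], row["predicted_exclusion"])


def test_ctl_override_routes_through_true_labels(fitted_forest):
    f = fitted_forest
    truth = f["y_te"]["ctl_level"].to_numpy()
    pred = predict_stepwise(f["model"], f["x_te"], ctl_override=truth)
    assert np.array_equal(pred["predicted_ctl"].to_numpy(), truth)
    routed = np.where(truth, pred["predicted_dysfunction"], pred["predicted_exclusion"])
    assert np.array_equal(pred["predicted_tide"].to_numpy(), routed)


def test_single_ctl_class_is_rejected(small_cohort):
    x = small_cohort.expression.iloc[:50]
    y = small_cohort.labels.iloc[:50].copy()
    y["ctl_level"] = True
    with pytest.raises(ValueError, match="single CTL class"):
        fit_stepwise(x, y)


def test_misaligned_ids_and_missing_values_are_rejected(small_cohort):
    x = small_cohort.expression.iloc[:50]
    y = small_cohort.labels.iloc[10:60]
    with pytest.raises(ValueError, match="same sample IDs"):
        fit_stepwise(x, y)
    x_nan = small_cohort.expression.iloc[:50].copy()
    x_nan.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing values"):
        fit_stepwise(x_nan, small_cohort.labels.iloc[:50])


def test_missing_feature_columns_error_extra_columns_warn(fitted_forest):
    f = fitted_forest
    with pytest.raises(ValueError, match="missing"):
        predict_stepwise(f["model"], f["x_te"].iloc[:, :-5])
    extra = f["x_te"].copy()
    extra["not_a_mirna"] = 1.0
    with pytest.warns(UserWarning, match="ignoring"):
        predict_stepwise(f["model"], extra)


def test_simple_family_standardizer_uses_training_statistics(small_cohort):
    c = small_cohort
    x_tr, y_tr, _, _ = split_train_test(c.expression, c.labels, seed=0)
    model = fit_stepwise(x_tr, y_tr, family="simple", seed=0)
    means = np.array([model.standardizer["mean"][f] for f in model.feature_names])
    assert np.allclose(means, x_tr[model.feature_names].mean(axis=0), atol=1e-12)
    sds = np.array([model.standardizer["sd"][f] for f in model.feature_names])
    assert np.allclose(sds, x_tr[model.feature_names].std(axis=0, ddof=0), atol=1e-12)


def test_forest_family_has_no_standardizer(fitted_forest):
    assert fitted_forest["model"].standardizer is None


def test_fits_are_deterministic_under_fixed_seed(small_cohort):
    c = small_cohort
    x_tr, y_tr, x_te, _ = split_train_test(c.expression, c.labels, seed=1)
    hp = {"dysfunction": {"n_estimators": 20, "max_depth": 8},
          "exclusion": {"n_estimators": 20, "max_depth": 8},
          "ctl": {"n_estimators": 20}}
    a = fit_stepwise(x_tr, y_tr, hyperparams=hp, seed=5)
    b = fit_stepwise(x_tr, y_tr, hyperparams=hp, seed=5)
    pd.testing.assert_frame_equal(predict_stepwise(a, x_te), predict_stepwise(b, x_te))
    direct_a = fit_direct_baseline(x_tr, y_tr, hyperparams={"n_estimators": 20, "max_depth": 8}, seed=5)
    direct_b = fit_direct_baseline(x_tr, y_tr, hyperparams={"n_estimators": 20, "max_depth": 8}, seed=5)
    assert np.array_equal(direct_a.predict(x_te.to_numpy()), direct_b.predict(x_te.to_numpy()))


def test_noiseless_simple_model_with_oracle_routing_recovers_scores_exactly():
    """With no label noise, OLS regressors recover the generative model and
    true-label routing drives the end-to-end error to numerical zero."""
    cohort = generate_cohort(
        CohortConfig(n_samples=800, n_mirnas=100, noise_sd=0.0, seed=13)
    )
    x_tr, y_tr, x_te, y_te = split_train_test(cohort.expression, cohort.labels, seed=13)
    model = fit_stepwise(x_tr, y_tr, family="simple", seed=13)
    pred = predict_stepwise(model, x_te, ctl_override=y_te["ctl_level"].to_numpy())
    mse = float(np.mean((pred["predicted_tide"].to_numpy() - y_te["tide_score"].to_numpy()) ** 2))
    assert mse < 1e-9


def test_split_is_disjoint_exhaustive_and_stratified(small_cohort):
    c = small_cohort
    x_tr, y_tr, x_te, y_te = split_train_test(c.expression, c.labels, test_fraction=0.2, seed=3)
    assert len(x_tr) + len(x_te) == len(c.expression)
    assert not set(x_tr.index) & set(x_te.index)
    assert abs(len(x_te) - 0.2 * len(c.expression)) <= 1
    overall = c.labels["ctl_level"].mean()
    assert abs(y_te["ctl_level"].sum() - overall * len(y_te)) <= 1
    # same seed => same partition
    x_tr2, _, _, _ = split_train_test(c.expression, c.labels, test_fraction=0.2, seed=3)
    assert list(x_tr.index) == list(x_tr2.index)
    with pytest.raises(ValueError):
        split_train_test(c.expression, c.labels, test_fraction=1.5)


def test_grid_search_matches_hand_rolled_cv_loop(rng):
    x = rng.standard_normal((60, 8))
    y = x[:, 0] * 2.0 - x[:, 1] + 0.3 * rng.standard_normal(60)
    grid = {"alpha": [0.1, 10.0]}
    best, table = grid_search_cv(
        Ridge(), grid, x, y, folds=5, scoring="neg_mean_squared_error", seed=7
    )
    cv = KFold(n_splits=5, shuffle=True, random_state=7)
    oracle_best, oracle_means = manual_grid_search(
        Ridge,
        list(ParameterGrid(grid)),
        x,
        y,
        cv,
        lambda est, xs, ys: -mean_squared_error(ys, est.predict(xs)),
    )
    assert best == oracle_best
    assert np.allclose(sorted(table["mean_cv_score"]), sorted(oracle_means), atol=1e-10)


def test_grid_search_single_point_and_errors(rng):
    x = rng.standard_normal((30, 4))
    y = rng.standard_normal(30)
    best, table = grid_search_cv(Ridge(), {"alpha": [1.0]}, x, y, folds=3)
    assert best == {"alpha": 1.0}
    assert len(table) == 1
    with pytest.raises(ValueError, match="empty"):
        grid_search_cv(Ridge(), {}, x, y, folds=3)
    with pytest.raises(ValueError, match="folds"):
        grid_search_cv(Ridge(), {"alpha": [1.0]}, x[:2], y[:2], folds=5)


def test_grid_search_is_deterministic(rng):
    x = rng.standard_normal((50, 5))
    y = rng.standard_normal(50)
    a = grid_search_cv(Ridge(), {"alpha": [0.1, 1.0, 10.0]}, x, y, folds=5, seed=3)
    b = grid_search_cv(Ridge(), {"alpha": [0.1, 1.0, 10.0]}, x, y, folds=5, seed=3)
    assert a[0] == b[0]
    assert np.array_equal(a[1]["mean_cv_score"], b[1]["mean_cv_score"])


def test_model_bundle_round_trips_through_disk(fitted_forest, tmp_path):
    f = fitted_forest
    save_model(f["model"], tmp_path / "bundle")
    back = load_model(tmp_path / "bundle")
    assert back.feature_names == f["model"].feature_names
    pd.testing.assert_frame_equal(
        predict_stepwise(back, f["x_te"]), predict_stepwise(f["model"], f["x_te"])
    )
    assert (tmp_path / "bundle" / "manifest.json").exists()


def test_ctl_scores_are_probabilities(fitted_forest):
    s = ctl_scores(fitted_forest["model"], fitted_forest["x_te"])
    assert ((s >= 0) & (s <= 1)).all()
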