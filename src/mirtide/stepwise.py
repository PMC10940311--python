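"""The gated two-stage predictor of TIDE scores from miRNA expression.

Three sub-models are trained on the same miRNA feature space: a binary
classifier for CTL level and two regressors for the dysfunction and
exclusion scores.  At prediction time each sample is routed through the
classifier — a CTL-high call selects the dysfunction regressor's output as
the predicted TIDE score, a CTL-low call selects the exclusion regressor's.
The routing makes the otherwise bimodal TIDE target learnable; a direct
single regressor on the TIDE score serves as the comparison baseline.

Two model families are supported: ``forest`` (random forests, the defaults
being the grid-search winners on the real cohort: an entropy-criterion
250-tree classifier considering all features per split, and 700-tree/depth-25
and 300-tree/depth-20 regressors) and ``simple`` (L2 logistic regression via
liblinear plus ordinary least squares on z-standardized features), the
family used after Shapley-based feature selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import GridSearchCV, KFold, ParameterGrid, train_test_split

__all__ = [
    "StepwiseModel",
    "fit_stepwise",
    "predict_stepwise",
    "ctl_scores",
    "fit_direct_baseline",
    "grid_search_cv",
    "split_train_test",
    "save_model",
    "load_model",
    "DEFAULT_FOREST_PARAMS",
    "DEFAULT_SIMPLE_PARAMS",
]

SUBMODELS = ("ctl", "dysfunction", "exclusion")

# grid-search winners on the full real cohort; tests may pass smaller forests
DEFAULT_FOREST_PARAMS = {
    "ctl": {"criterion": "entropy", "max_features": None, "n_estimators": 250},
    "dysfunction": {"max_depth": 25, "n_estimators": 700},
    "exclusion": {"max_depth": 20, "n_estimators": 300},
}
# liblinear with default regularization is an L2 logistic fit, the reported
# best configuration (class_weight None, L2 penalty, liblinear solver)
DEFAULT_SIMPLE_PARAMS = {
    "ctl": {"class_weight": None, "solver": "liblinear"},
    "dysfunction": {},
    "exclusion": {},
}


@dataclass
class StepwiseModel:
    """Fitted classifier + two regressors sharing one ordered feature space.

    ``feature_names`` is the ordered union of all sub-model inputs;
    ``submodel_features`` maps each sub-model to the (ordered) subset it
    consumes — identical to ``feature_names`` unless the model was refit on
    per-sub-model selections.  ``standardizer`` holds per-feature training
    (mean, sd) and is present exactly when the family is ``simple``.
    """

    family: str
    ctl_classifier: object
    dysfunction_regressor: object
    exclusion_regressor: object
    feature_names: list[str]
    submodel_features: dict[str, list[str]] = field(default_factory=dict)
    standardizer: dict | None = None
    fitted_on: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in ("forest", "simple"):
            raise ValueError(f"unknown model family {self.family!r}")
        if not self.submodel_features:
            self.submodel_features = {k: list(self.feature_names) for k in SUBMODELS}
        if (self.standardizer is not None) != (self.family == "simple"):
            raise ValueError("standardizer present iff family is 'simple'")

    def estimator(self, submodel: str):
        return {
            "ctl": self.ctl_classifier,
            "dysfunction": self.dysfunction_regressor,
            "exclusion": self.exclusion_regressor,
        }[submodel]

    def design_matrix(self, expression: pd.DataFrame, submodel: str) -> np.ndarray:
        """Column-normalized (and, for simple models, standardized) inputs."""
        cols = self.submodel_features[submodel]
        x = expression[cols].to_numpy(dtype=float)
        if self.standardizer is not None:
            mean = np.array([self.standardizer["mean"][c] for c in cols])
            sd = np.array([self.standardizer["sd"][c] for c in cols])
            x = (x - mean) / sd
        return x


def _check_alignment(expression: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    if set(expression.index) != set(labels.index):
        raise ValueError("expression and labels must cover the same sample IDs")
    labels = labels.loc[expression.index]
    if expression.isna().to_numpy().any():
        raise ValueError("expression matrix contains missing values")
    return labels


def _normalize_columns(expression: pd.DataFrame, feature_names: list[str]) -> pd.DataFrame:
    missing = [f for f in feature_names if f not in expression.columns]
    if missing:
        raise ValueError(f"expression is missing {len(missing)} model features, e.g. {missing[:3]}")
    extra = [c for c in expression.columns if c not in set(feature_names)]
    if extra:
        warnings.warn(
            f"ignoring {len(extra)} expression columns not used by the model",
            stacklevel=3,
        )
    return expression[feature_names]


def _merged_params(family: str, hyperparams: dict | None) -> dict:
    defaults = DEFAULT_FOREST_PARAMS if family == "forest" else DEFAULT_SIMPLE_PARAMS
    merged = {k: dict(v) for k, v in defaults.items()}
    for key, override in (hyperparams or {}).items():
        if key not in merged:
            raise ValueError(f"hyperparams key must be one of {SUBMODELS}, got {key!r}")
        merged[key].update(override)
    return merged


def _fit_standardizer(expression: pd.DataFrame) -> tuple[dict, list[str]]:
    """Training-set (mean, sd) per feature; zero-variance features are dropped."""
    mean = expression.mean(axis=0)
    sd = expression.std(axis=0, ddof=0)
    keep = [c for c in expression.columns if sd[c] > 0]
    dropped = [c for c in expression.columns if sd[c] == 0]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance feature(s): {dropped[:5]}",
            stacklevel=3,
        )
    standardizer = {
        "mean": {c: float(mean[c]) for c in keep},
        "sd": {c: float(sd[c]) for c in keep},
    }
    return standardizer, keep


def fit_stepwise(
    train_expression: pd.DataFrame,
    train_labels: pd.DataFrame,
    *,
    family: str = "forest",
    hyperparams: dict | None = None,
    seed: int = 0,
    subgroup_only: bool = False,
    submodel_features: dict[str, list[str]] | None = None,
) -> StepwiseModel:
    """Fit the CTL classifier and both score regressors on the training split.

    Each regressor is trained on *all* training samples against its own score
    (the label table supplies both scores for every sample); set
    ``subgroup_only=True`` to train each regressor only on the samples its
    CTL label routes to it.  ``submodel_features`` restricts each sub-model
    to a feature subset (used by the post-selection refit); the ``simple``
    family z-standardizes features with training statistics only.
    """
    if family not in ("forest", "simple"):
        raise ValueError(f"unknown model family {family!r}")
    labels = _check_alignment(train_expression, train_labels)
    y_ctl = labels["ctl_level"].to_numpy(dtype=bool)
    if y_ctl.all() or not y_ctl.any():
        raise ValueError("training labels contain a single CTL class")

    params = _merged_params(family, hyperparams)
    if submodel_features is None:
        submodel_features = {k: list(train_expression.columns) for k in SUBMODELS}
    else:
        submodel_features = {k: list(v) for k, v in submodel_features.items()}
        for k in SUBMODELS:
            if not submodel_features.get(k):
                raise ValueError(f"submodel_features[{k!r}] must be a non-empty feature list")
    ordered_union: list[str] = []
    seen = set()
    for k in SUBMODELS:
        for f in submodel_features[k]:
            if f not in seen:
                ordered_union.append(f)
                seen.add(f)
    x_all = _normalize_columns(train_expression, ordered_union)

    standardizer = None
    if family == "simple":
        standardizer, keep = _fit_standardizer(x_all)
        kept = set(keep)
        submodel_features = {k: [f for f in v if f in kept] for k, v in submodel_features.items()}
        for k in SUBMODELS:
            if not submodel_features[k]:
                raise ValueError(f"all features of sub-model {k!r} were zero-variance")
        ordered_union = [f for f in ordered_union if f in kept]

    model = StepwiseModel(
        family=family,
        ctl_classifier=None,
        dysfunction_regressor=None,
        exclusion_regressor=None,
        feature_names=ordered_union,
        submodel_features=submodel_features,
        standardizer=standardizer,
        fitted_on={
            "n_samples": int(len(labels)),
            "seed": int(seed),
            "subgroup_only": bool(subgroup_only),
            "hyperparams": params,
        },
    )

    def _make(submodel: str):
        p = params[submodel]
        if family == "forest":
            if submodel == "ctl":
                return RandomForestClassifier(random_state=seed, n_jobs=1, **p)
            return RandomForestRegressor(random_state=seed, n_jobs=1, **p)
        if submodel == "ctl":
            return LogisticRegression(random_state=seed, max_iter=2000, **p)
        return LinearRegression(**p)

    clf = _make("ctl")
    clf.fit(model.design_matrix(x_all, "ctl"), y_ctl)
    model.ctl_classifier = clf

    for submodel, attr in (("dysfunction", "dysfunction_regressor"), ("exclusion", "exclusion_regressor")):
        mask = np.ones(len(labels), dtype=bool)
        if subgroup_only:
            mask = y_ctl if submodel == "dysfunction" else ~y_ctl
        reg = _make(submodel)
        reg.fit(model.design_matrix(x_all, submodel)[mask], labels[submodel].to_numpy()[mask])
        setattr(model, attr, reg)
    return model


def ctl_scores(model: StepwiseModel, expression: pd.DataFrame) -> np.ndarray:
    """Posterior probability of the CTL-high ("True") class per sample."""
    x = _normalize_columns(expression, model.feature_names)
    proba = model.ctl_classifier.predict_proba(model.design_matrix(x, "ctl"))
    pos = list(model.ctl_classifier.classes_).index(True)
    return proba[:, pos]


def predict_stepwise(
    model: StepwiseModel,
    expression: pd.DataFrame,
    *,
    ctl_override=None,
) -> pd.DataFrame:
    """Predict CTL level, both scores, and the routed TIDE score per sample.

    The routing invariant — predicted TIDE equals the dysfunction prediction
    where the predicted CTL is True and the exclusion prediction elsewhere —
    is asserted on every batch.  ``ctl_override`` replaces the classifier's
    calls with a given boolean vector (e.g. the true CTL labels, for
    oracle-routing comparisons).
    """
    if expression.isna().to_numpy().any():
        raise ValueError("expression matrix contains missing values")
    x = _normalize_columns(expression, model.feature_names)
    if ctl_override is None:
        ctl = model.ctl_classifier.predict(model.design_matrix(x, "ctl")).astype(bool)
    else:
        ctl = np.asarray(ctl_override, dtype=bool)
        if len(ctl) != len(expression):
            raise ValueError("ctl_override length must match the expression matrix")
    dys = model.dysfunction_regressor.predict(model.design_matrix(x, "dysfunction"))
    exc = model.exclusion_regressor.predict(model.design_matrix(x, "exclusion"))
    tide = np.where(ctl, dys, exc)
    assert np.array_equal(tide, np.where(ctl, dys, exc)), "routing invariant violated"
    return pd.DataFrame(
        {
            "sample_id": expression.index,
            "predicted_ctl": ctl,
            "predicted_dysfunction": dys,
            "predicted_exclusion": exc,
            "predicted_tide": tide,
        }
    ).reset_index(drop=True)


def fit_direct_baseline(
    train_expression: pd.DataFrame,
    train_labels: pd.DataFrame,
    *,
    hyperparams: dict | None = None,
    seed: int = 0,
):
    """Single random-forest regressor on the TIDE score itself (no gating).

    The comparison baseline: conditional on CTL level the TIDE target mixes
    two different score distributions, which a single regressor must absorb.
    """
    labels = _check_alignment(train_expression, train_labels)
    params = dict(DEFAULT_FOREST_PARAMS["dysfunction"])
    params.update(hyperparams or {})
    reg = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    reg.fit(train_expression.to_numpy(dtype=float), labels["tide_score"].to_numpy())
    return reg


def grid_search_cv(
    estimator,
    param_grid: dict | list[dict],
    expression,
    target,
    *,
    folds: int = 10,
    scoring: str | None = None,
    seed: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search with k-fold cross-validation (default tenfold).

    Returns the grid point with the best mean CV score (ties broken by first
    grid order) and the full CV table.  Fold assignment is a shuffled KFold
    with ``seed``, so reruns are identical.
    """
    if not param_grid:
        raise ValueError("empty parameter grid")
    grid_points = list(ParameterGrid(param_grid))
    if not grid_points:
        raise ValueError("empty parameter grid")
    x = np.asarray(expression, dtype=float)
    y = np.asarray(target)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(y) < folds:
        raise ValueError("more folds than samples")
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        estimator, param_grid, cv=cv, scoring=scoring, refit=False, n_jobs=1
    )
    search.fit(x, y)
    means = search.cv_results_["mean_test_score"]
    best_i = 0
    for i in range(1, len(means)):
        if means[i] > means[best_i]:
            best_i = i
    table = pd.DataFrame(
        {
            "params": search.cv_results_["params"],
            "mean_cv_score": means,
            "std_cv_score": search.cv_results_["std_test_score"],
        }
    )
    return dict(search.cv_results_["params"][best_i]), table


def split_train_test(
    expression: pd.DataFrame,
    labels: pd.DataFrame,
    *,
    test_fraction: float = 0.2,
    seed: int = 0,
    stratify: bool = True,
):
    """Disjoint, exhaustive train/test partition (default 80/20).

    Stratified on CTL level by default so the rare CTL-low class stays
    represented in the test split.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly in (0, 1)")
    labels = _check_alignment(expression, labels)
    strat = labels["ctl_level"] if stratify else None
    idx_train, idx_test = train_test_split(
        expression.index,
        test_size=test_fraction,
        random_state=seed,
        stratify=strat,
    )
    return (
        expression.loc[idx_train],
        labels.loc[idx_train],
        expression.loc[idx_test],
        labels.loc[idx_test],
    )


def save_model(model: StepwiseModel, directory) -> None:
    """Serialize the bundle: a JSON manifest plus the pickled estimators."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "family": model.family,
        "feature_names": model.feature_names,
        "submodel_features": model.submodel_features,
        "fitted_on": model.fitted_on,
        "standardized": model.standardizer is not None,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    joblib.dump(model, directory / "model.joblib")


def load_model(directory) -> StepwiseModel:
    model = joblib.load(Path(directory) / "model.joblib")
    if not isinstance(model, StepwiseModel):
        raise TypeError("directory does not contain a stepwise model bundle")
    return model
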