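"""Shapley-value feature attribution for the stepwise sub-models.

Tree-ensemble sub-models get exact path-dependent tree attributions (the
training covers stored in each tree define the background); simple
sub-models get the closed-form linear attribution ``coef·(x − E[x])`` with
the training set as background — on the log-odds margin for the logistic
classifier, recorded in the table's ``output_space`` metadata.  Every route
satisfies local accuracy: per-sample attributions sum to the model output
minus the expected value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.tree import BaseDecisionTree

from ._treeshap import tree_shap, forest_shap

__all__ = [
    "shap_values",
    "compute_shap_importance",
    "stepwise_importance",
    "tree_shap",
    "forest_shap",
]


def _positive_class_index(classifier) -> int:
    classes = list(classifier.classes_)
    if True in classes:
        return classes.index(True)
    return len(classes) - 1


def shap_values(estimator, evaluation: np.ndarray, background: np.ndarray | None = None):
    """Per-sample, per-feature Shapley attributions for one fitted sub-model.

    Returns ``(phi, expected_value, output_space)``.  ``output_space`` is
    "probability" (tree classifiers, positive class), "margin" (logistic) or
    "raw" (regressors).
    """
    x = np.asarray(evaluation, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("evaluation set must be a non-empty 2-D matrix")
    n_features = getattr(estimator, "n_features_in_", None)
    if n_features is not None and x.shape[1] != n_features:
        raise ValueError(
            f"evaluation has {x.shape[1]} features but the model expects {n_features}"
        )

    if isinstance(estimator, RandomForestClassifier):
        phi, base = forest_shap(estimator, x, _positive_class_index(estimator))
        return phi, base, "probability"
    if isinstance(estimator, RandomForestRegressor):
        phi, base = forest_shap(estimator, x)
        return phi, base, "raw"
    if isinstance(estimator, BaseDecisionTree):
        if hasattr(estimator, "classes_"):
            phi, base = tree_shap(estimator, x, _positive_class_index(estimator))
            return phi, base, "probability"
        phi, base = tree_shap(estimator, x)
        return phi, base, "raw"
    if isinstance(estimator, (LinearRegression, LogisticRegression)):
        if background is None:
            raise ValueError("linear attribution needs a background matrix")
        bg_mean = np.asarray(background, dtype=float).mean(axis=0)
        coef = np.ravel(estimator.coef_)
        phi = coef * (x - bg_mean)
        if isinstance(estimator, LogisticRegression):
            base = float(coef @ bg_mean + float(np.ravel(estimator.intercept_)[0]))
            return phi, base, "margin"
        base = float(coef @ bg_mean + estimator.intercept_)
        return phi, base, "raw"
    raise TypeError(f"no Shapley attribution route for {type(estimator).__name__}")


def _importance_frame(phi: np.ndarray, features, sub_model: str) -> pd.DataFrame:
    mean_abs = np.abs(phi).mean(axis=0)
    table = pd.DataFrame(
        {"sub_model": sub_model, "feature": list(features), "mean_abs_shap": mean_abs}
    )
    table = table.sort_values(
        ["mean_abs_shap", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def compute_shap_importance(
    estimator,
    evaluation: pd.DataFrame,
    background: pd.DataFrame | None = None,
    *,
    sub_model: str = "model",
) -> pd.DataFrame:
    """Mean absolute Shapley value per feature, ranked descending.

    ``evaluation`` columns are the feature names (must match the model's
    input width); ties in importance are broken by feature-name order.  The
    attributed output space is recorded in ``table.attrs["output_space"]``.
    """
    phi, base, space = shap_values(
        estimator,
        evaluation.to_numpy(dtype=float),
        None if background is None else background.to_numpy(dtype=float),
    )
    table = _importance_frame(phi, evaluation.columns, sub_model)
    table.attrs["output_space"] = space
    table.attrs["expected_value"] = base
    return table


def stepwise_importance(
    model,
    evaluation: pd.DataFrame,
    background: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Importance tables for all three sub-models of a stepwise bundle.

    The evaluation (held-out by convention) and background matrices are
    given in the bundle's full feature space; each sub-model is attributed
    on its own feature subset.  Returns one concatenated table with a
    ``sub_model`` column; per-table output spaces are kept in
    ``attrs["output_space"]``.
    """
    tables = []
    spaces = {}
    for sub in ("ctl", "dysfunction", "exclusion"):
        cols = model.submodel_features[sub]
        x_eval = pd.DataFrame(
            model.design_matrix(evaluation, sub), columns=cols, index=evaluation.index
        )
        bg = None
        if background is not None:
            bg = pd.DataFrame(
                model.design_matrix(background, sub), columns=cols, index=background.index
            )
        table = compute_shap_importance(
            model.estimator(sub), x_eval, bg, sub_model=sub
        )
        spaces[sub] = table.attrs["output_space"]
        tables.append(table)
    out = pd.concat(tables, ignore_index=True)
    out.attrs["output_space"] = spaces
    return out
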