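"""Informative-miRNA selection by mean |Shapley| thresholding and the
simple-model refit on the selected features.

Selection is per-sub-model at an inclusive threshold ("0.01 or higher"),
so the stricter 0.02 selection is always nested inside the 0.01 one.  The
refit swaps the tree ensembles for an L2 logistic classifier and ordinary
least-squares regressors on z-standardized selected features.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .stepwise import SUBMODELS, StepwiseModel, fit_stepwise

__all__ = ["select_informative", "select_per_submodel", "refit_with_informative"]


def select_informative(table: pd.DataFrame, tau: float) -> set[str]:
    """Features whose mean absolute Shapley value is >= ``tau`` (inclusive).

    ``table`` must cover a single sub-model (use :func:`select_per_submodel`
    for a concatenated table).  An empty selection is legal but warned
    about, and blocks any refit.
    """
    if tau <= 0:
        raise ValueError("selection threshold must be positive")
    if table.empty:
        raise ValueError("importance table is empty")
    if "sub_model" in table.columns and table["sub_model"].nunique() > 1:
        raise ValueError("table covers several sub-models; use select_per_submodel")
    selected = set(table.loc[table["mean_abs_shap"] >= tau, "feature"])
    if not selected:
        warnings.warn(f"no feature reaches mean |Shapley| >= {tau}", stacklevel=2)
    return selected


def select_per_submodel(table: pd.DataFrame, tau: float) -> dict[str, set[str]]:
    """Per-sub-model inclusive-threshold selection on a concatenated table."""
    out = {}
    for sub, group in table.groupby("sub_model", sort=False):
        out[sub] = select_informative(group, tau)
    return out


def refit_with_informative(
    train_expression: pd.DataFrame,
    train_labels: pd.DataFrame,
    selected: dict[str, set[str]],
    *,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> StepwiseModel:
    """Refit the stepwise model with simple learners on the selected features.

    ``selected`` maps each sub-model (ctl / dysfunction / exclusion) to its
    informative feature set; each must be non-empty.  Features are
    z-standardized with training statistics; zero-variance features are
    dropped with a warning inside the fit.
    """
    for sub in SUBMODELS:
        if not selected.get(sub):
            raise ValueError(f"empty informative-feature selection for sub-model {sub!r}")
    submodel_features = {
        sub: sorted(selected[sub], key=list(train_expression.columns).index)
        for sub in SUBMODELS
    }
    return fit_stepwise(
        train_expression,
        train_labels,
        family="simple",
        hyperparams=hyperparams,
        seed=seed,
        submodel_features=submodel_features,
    )
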