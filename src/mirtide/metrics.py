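"""Evaluation battery: F1 / balanced accuracy / ROC-AUC for the CTL stage,
MSE / Pearson correlation for the regressors and the routed prediction.

F1 = 2·(recall·precision)/(recall+precision) for the positive (CTL-high)
class; balanced accuracy = (sensitivity+specificity)/2; ROC-AUC follows the
Mann-Whitney rank construction with midrank tie handling; MSE = (1/N)·Σ(fᵢ−yᵢ)².
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.metrics import (
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

__all__ = [
    "ClassificationMetrics",
    "RegressionMetrics",
    "classification_metrics",
    "regression_metrics",
    "evaluate_pipeline",
]


@dataclass(frozen=True)
class ClassificationMetrics:
    precision: float
    recall: float
    f1: float
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    roc_auc: float
    positive_class: str = "True"

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RegressionMetrics:
    n: int
    mse: float
    pcc: float

    def as_dict(self) -> dict:
        return asdict(self)


def classification_metrics(truth, predicted, scores, *, average: str = "binary") -> ClassificationMetrics:
    """Score a binary CTL-level prediction.

    Parameters
    ----------
    truth, predicted : boolean vectors
    scores : real vector
        Score for the positive ("True" = CTL-high) class, used for ROC-AUC.
    average : "binary" or "macro"
        F1 averaging; "binary" (positive-class F1) is the default.
    """
    y = np.asarray(truth, dtype=bool)
    yhat = np.asarray(predicted, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if not (len(y) == len(yhat) == len(s)):
        raise ValueError("truth, predicted and scores must have equal length")
    if len(y) == 0:
        raise ValueError("empty input")
    if y.all() or not y.any():
        raise ValueError("ROC-AUC undefined: truth contains a single class")

    tn, fp, fn, tp = confusion_matrix(y, yhat, labels=[False, True]).ravel()
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    return ClassificationMetrics(
        precision=float(precision_score(y, yhat, zero_division=0)),
        recall=float(recall_score(y, yhat, zero_division=0)),
        f1=float(f1_score(y, yhat, average=average, zero_division=0)),
        sensitivity=float(sensitivity),
        specificity=float(specificity),
        balanced_accuracy=float((sensitivity + specificity) / 2.0),
        roc_auc=float(roc_auc_score(y, s)),
    )


def regression_metrics(actual, predicted, *, include_pcc: bool = True) -> RegressionMetrics:
    """MSE and Pearson correlation between actual and predicted scores.

    A zero-variance vector makes the correlation undefined and raises;
    pass ``include_pcc=False`` for MSE-only evaluation of such inputs
    (``pcc`` is then reported as NaN).
    """
    y = np.asarray(actual, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if len(y) != len(f):
        raise ValueError("length mismatch")
    if len(y) == 0:
        raise ValueError("empty input")
    mse = float(np.mean((f - y) ** 2))
    if not include_pcc:
        return RegressionMetrics(n=len(y), mse=mse, pcc=float("nan"))
    if len(y) < 2:
        raise ValueError("Pearson correlation needs at least 2 samples")
    if np.std(y) == 0 or np.std(f) == 0:
        raise ValueError("Pearson correlation undefined for a zero-variance vector")
    pcc = float(pearsonr(y, f).statistic)
    return RegressionMetrics(n=len(y), mse=mse, pcc=pcc)


def evaluate_pipeline(model, expression: pd.DataFrame, labels: pd.DataFrame) -> dict:
    """Full held-out report for a fitted stepwise model.

    Emits the CTL-stage classification metrics, each regressor's metrics on
    all test samples (each against its own score), the same metrics on the
    routed subsets for transparency, and the end-to-end routed TIDE
    prediction metrics.
    """
    from .stepwise import predict_stepwise, ctl_scores

    pred = predict_stepwise(model, expression)
    pred = pred.set_index("sample_id").loc[labels.index]
    scores = ctl_scores(model, expression)

    report: dict = {
        "ctl": classification_metrics(
            labels["ctl_level"], pred["predicted_ctl"], scores
        ).as_dict(),
        "dysfunction": regression_metrics(
            labels["dysfunction"], pred["predicted_dysfunction"]
        ).as_dict(),
        "exclusion": regression_metrics(
            labels["exclusion"], pred["predicted_exclusion"]
        ).as_dict(),
        "stepwise_tide": regression_metrics(
            labels["tide_score"], pred["predicted_tide"]
        ).as_dict(),
    }
    for name, mask in (
        ("dysfunction_routed", pred["predicted_ctl"].to_numpy()),
        ("exclusion_routed", ~pred["predicted_ctl"].to_numpy()),
    ):
        col = name.split("_")[0]
        if mask.sum() >= 2 and labels.loc[mask, col].std() > 0:
            report[name] = regression_metrics(
                labels.loc[mask, col], pred.loc[mask, f"predicted_{col}"]
            ).as_dict()
        else:
            report[name] = None
    return report
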