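"""Tab-delimited readers/writers for the package's table dialects.

All files are UTF-8 TSV with '.' decimal.  The expression dialect is
sample-by-feature with the sample ID in the first column and a header row of
miRNA IDs; the label dialect carries per-sample CTL level (True/False),
dysfunction, exclusion, assembled TIDE score and responder call.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

LABEL_COLUMNS = ["ctl_level", "dysfunction", "exclusion", "tide_score", "responder"]


def write_expression(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index_label="sample_id")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, sep="\t", index_label="sample_id")


def read_labels(path) -> pd.DataFrame:
    labels = pd.read_csv(path, sep="\t", index_col="sample_id")
    for col in ("ctl_level", "responder"):
        if col in labels.columns and labels[col].dtype != bool:
            labels[col] = labels[col].astype(str).str.strip() == "True"
    return labels


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_importance(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_importance(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_predictions(predictions: pd.DataFrame, path) -> None:
    predictions.to_csv(path, sep="\t", index=False)


def write_feature_list(features, path) -> None:
    Path(path).write_text("".join(f"{f}\n" for f in features))


def read_feature_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
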