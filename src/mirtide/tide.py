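"""Label-side TIDE logic and gene-expression preprocessing utilities.

TIDE (Tumor Immune Dysfunction and Exclusion) scores each tumor sample with a
CTL-level call plus two continuous evasion scores.  The routing rule and the
responder sign convention implemented here are consumed downstream as the
prediction target; TIDE's internal gene-signature scoring is an external
black box whose outputs arrive as a label table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "assemble_tide_score",
    "responder_call",
    "normalize_gene_expression",
    "collapse_duplicate_symbols",
    "filter_samples",
]


def assemble_tide_score(ctl_level, dysfunction, exclusion):
    """Route dysfunction/exclusion scores into a TIDE score.

    A CTL-high sample's TIDE score is its dysfunction score; a CTL-low
    sample's is its exclusion score.  Accepts scalars or array-likes
    (broadcast elementwise).

    Parameters
    ----------
    ctl_level : bool or array-like of bool
        True = CTL-high.
    dysfunction, exclusion : float or array-like of float
        The two evasion scores; must be finite.

    Returns
    -------
    float or ndarray
        The routed TIDE score(s).
    """
    ctl = np.asarray(ctl_level, dtype=bool)
    dys = np.asarray(dysfunction, dtype=float)
    exc = np.asarray(exclusion, dtype=float)
    if not (np.all(np.isfinite(dys)) and np.all(np.isfinite(exc))):
        raise ValueError("dysfunction and exclusion scores must be finite")
    out = np.where(ctl, dys, exc)
    if out.ndim == 0:
        return float(out)
    return out


def responder_call(tide_score):
    """Call ICB responder status from a TIDE score.

    Negative score => responder (True); positive => non-responder.  A score
    of exactly 0 is classed non-responder (the strict-less-than convention
    keeps the call deterministic at the boundary).
    """
    score = np.asarray(tide_score, dtype=float)
    if not np.all(np.isfinite(score)):
        raise ValueError("TIDE score must be finite")
    out = score < 0
    if out.ndim == 0:
        return bool(out)
    return out


def normalize_gene_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each gene on its across-sample mean.

    Standard preprocessing for log2(FPKM+1) gene-by-sample matrices before
    signature scoring: subtract the per-gene average so every gene row has
    mean 0.  Idempotent.
    """
    if matrix.empty:
        raise ValueError("cannot normalize an empty expression matrix")
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains non-finite values")
    return matrix.sub(matrix.mean(axis=1), axis=0)


def collapse_duplicate_symbols(matrix: pd.DataFrame) -> pd.DataFrame:
    """Average rows sharing a gene symbol into a single row per symbol.

    Ensembl-to-symbol mapping leaves duplicate symbols; each duplicate group
    is replaced by its per-sample arithmetic mean.  Row order is stable by
    first occurrence of each symbol.
    """
    if not matrix.index.has_duplicates:
        return matrix.copy()
    first_order = matrix.index.drop_duplicates(keep="first")
    collapsed = matrix.groupby(level=0, sort=False).mean()
    return collapsed.loc[first_order]


def filter_samples(
    labels: pd.DataFrame,
    metadata: pd.DataFrame,
    *,
    exclude_if_true: tuple[str, ...] = ("prior_therapy", "non_solid_tumor"),
) -> pd.DataFrame:
    """Drop samples flagged in a boolean metadata table.

    Cohort curation (e.g. removing prior-therapy cases and non-solid tumors)
    is a metadata lookup: any sample whose row in ``metadata`` is True in one
    of the ``exclude_if_true`` columns (when present) is removed from the
    label table.
    """
    keep = pd.Series(True, index=labels.index)
    meta = metadata.reindex(labels.index)
    for col in exclude_if_true:
        if col in meta.columns:
            keep &= ~meta[col].fillna(False).astype(bool)
    return labels.loc[keep]
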