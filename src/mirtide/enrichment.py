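"""Target-gene intersection and over-representation analysis (ORA).

Informative miRNAs are characterized by their predicted target genes: a
gene counts as a target when it appears in the unscored prediction source
(TargetScan-style) *and* in the scored source (miRDB-style, prediction
scores on [50, 100]) with score >= 80 — both thresholds inclusive.  The
pooled target list is then tested for over-representation in gene sets
(GMT) with the one-sided hypergeometric (Fisher exact) upper tail and
Benjamini–Hochberg adjustment; sets with adjusted P < 0.05 are significant.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_target_table",
    "write_target_table",
    "intersect_targets",
    "union_targets",
    "ora_test",
]

ADJUSTMENT_METHOD = "benjamini-hochberg"


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: one set per line — name, description, members."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (needs name, description, >=1 gene): {line!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *members]) for name, members in gene_sets.items()
    ]
    Path(path).write_text("".join(f"{line}\n" for line in lines))


def read_target_table(path, *, scored: bool) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    expected = {"mirna", "gene"} | ({"score"} if scored else set())
    missing = expected - set(table.columns)
    if missing:
        raise ValueError(f"target table is missing columns {sorted(missing)}")
    return table


def write_target_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def _validate_table(table: pd.DataFrame, *, scored: bool, name: str) -> None:
    if table.duplicated(subset=["mirna", "gene"]).any():
        raise ValueError(f"{name} target table has duplicate (mirna, gene) pairs")
    if scored:
        if table["score"].isna().any():
            raise ValueError("scored target table has missing scores")
        if ((table["score"] < 0) | (table["score"] > 100)).any():
            raise ValueError("prediction scores must lie in [0, 100]")


def intersect_targets(
    scored: pd.DataFrame,
    unscored: pd.DataFrame,
    score_threshold: float = 80.0,
) -> dict[str, set[str]]:
    """High-confidence targets per miRNA: in both sources, score >= threshold.

    The threshold is inclusive ("80 or higher"); raising it can only shrink
    each gene set.
    """
    if not 0.0 <= score_threshold <= 100.0:
        raise ValueError("score_threshold must lie in [0, 100]")
    _validate_table(scored, scored=True, name="scored")
    _validate_table(unscored, scored=False, name="unscored")
    confident = scored.loc[scored["score"] >= score_threshold, ["mirna", "gene"]]
    merged = confident.merge(unscored[["mirna", "gene"]], on=["mirna", "gene"])
    out: dict[str, set[str]] = {m: set() for m in scored["mirna"].unique()}
    for mirna, group in merged.groupby("mirna"):
        out[str(mirna)] = set(group["gene"])
    return out


def union_targets(per_mirna: dict[str, set[str]], mirnas=None) -> set[str]:
    """Pooled target set across a miRNA list (default: all)."""
    keys = per_mirna.keys() if mirnas is None else mirnas
    return set().union(*(per_mirna.get(m, set()) for m in keys)) if keys else set()


def ora_test(
    query,
    gene_sets: dict[str, list[str]],
    universe=None,
    *,
    significance: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each gene set.

    For a universe of M genes, a set of K and a query of n with overlap k,
    the p-value is the upper tail P(X >= k) of Hypergeometric(M, K, n);
    adjusted p-values are Benjamini–Hochberg across all tested sets.  The
    universe defaults to the union of all supplied set members; query genes
    outside the universe are dropped with a warning.  Rows are sorted by
    adjusted p ascending, ties by set name.
    """
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    query = set(query)
    if not query:
        raise ValueError("empty query gene list")
    if universe is None:
        universe = set().union(*gene_sets.values())
    else:
        universe = set(universe)
    if not universe:
        raise ValueError("empty background universe")
    outside = query - universe
    if outside:
        warnings.warn(
            f"dropping {len(outside)} query gene(s) outside the universe", stacklevel=2
        )
        query &= universe
    if not query:
        raise ValueError("no query gene lies in the background universe")

    M, n = len(universe), len(query)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        K = len(members)
        k = len(query & members)
        p = float(hypergeom.sf(k - 1, M, K, n))
        rows.append((name, k, n, K, M, min(p, 1.0)))
    result = pd.DataFrame(
        rows, columns=["set_name", "overlap", "query_size", "set_size", "universe_size", "p_value"]
    )
    result["adjusted_p"] = false_discovery_control(result["p_value"].to_numpy(), method="bh")
    result["significant"] = result["adjusted_p"] < significance
    result = result.sort_values(
        ["adjusted_p", "set_name"], kind="mergesort", ignore_index=True
    )
    return result
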