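"""Synthetic tumor cohorts with planted informative miRNAs.

The generator emulates the statistical structure the stepwise analysis
assumes: a sample-by-miRNA matrix on a log2(RPM+1)-like scale, a binary CTL
(cytotoxic T-lymphocyte) level driven by a small planted miRNA set through a
logistic model with strong class imbalance, continuous dysfunction and
exclusion scores linear in their own planted sets plus Gaussian noise, and a
TIDE score assembled by the CTL routing rule.  The recorded ground truth
(planted indices, generative coefficients, the feature moments used for
standardization) suffices to recompute the noiseless scores exactly, which
is what every downstream recovery test leans on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import io
from .tide import assemble_tide_score, responder_call

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "noiseless_scores",
    "generate_target_resources",
]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror the real cohort the analysis targets: 1,881 miRNA
    features per sample and a strongly CTL-high-skewed class balance
    (``ctl_high_fraction=0.9``, the imbalance implied by a near-perfect F1
    alongside a much lower balanced accuracy).  ``effect_size`` is the
    standardized coefficient magnitude of each planted feature.
    """

    n_samples: int = 2000
    n_mirnas: int = 1881
    n_informative_ctl: int = 5
    n_informative_dys: int = 5
    n_informative_exc: int = 5
    effect_size: float = 1.0
    ctl_high_fraction: float = 0.9
    noise_sd: float = 0.25
    seed: int = 0
    n_tumor_types: int = 1
    allow_overlap: bool = False

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_mirnas <= 0 or self.n_tumor_types <= 0:
            raise ValueError("n_samples, n_mirnas and n_tumor_types must be positive")
        for name in ("n_informative_ctl", "n_informative_dys", "n_informative_exc"):
            k = getattr(self, name)
            if k < 0 or k > self.n_mirnas:
                raise ValueError(f"{name} must lie in [0, n_mirnas]")
        if not self.allow_overlap:
            total = self.n_informative_ctl + self.n_informative_dys + self.n_informative_exc
            if total > self.n_mirnas:
                raise ValueError("disjoint planted sets need n_mirnas >= sum of set sizes")
        if not 0.0 < self.ctl_high_fraction < 1.0:
            raise ValueError("ctl_high_fraction must lie strictly in (0, 1)")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be non-negative")


@dataclass
class SyntheticCohort:
    """A generated cohort: expression matrix, TIDE-style labels, ground truth."""

    expression: pd.DataFrame
    labels: pd.DataFrame
    truth: dict = field(repr=False)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def n_mirnas(self) -> int:
        return self.expression.shape[1]


def _planted_sets(rng: np.random.Generator, config: CohortConfig):
    sizes = (config.n_informative_ctl, config.n_informative_dys, config.n_informative_exc)
    if config.allow_overlap:
        return tuple(np.sort(rng.choice(config.n_mirnas, size=k, replace=False)) for k in sizes)
    pool = rng.permutation(config.n_mirnas)
    sets, start = [], 0
    for k in sizes:
        sets.append(np.sort(pool[start : start + k]))
        start += k
    return tuple(sets)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort under ``config``; identical seeds give identical cohorts.

    Expression marginals are lognormal RPM counts transformed to
    log2(RPM+1).  CTL level is Bernoulli under a logistic model whose
    intercept is calibrated so the realized mean CTL-high probability equals
    ``ctl_high_fraction``.  Dysfunction/exclusion are linear in standardized
    planted features plus N(0, noise_sd²) noise; the TIDE score follows the
    routing rule and the responder call is the sign rule.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n, m = config.n_samples, config.n_mirnas
    # lognormal RPM marginals -> log2(RPM+1), matching the scale of real data
    log_mean = rng.normal(2.0, 1.5, size=m)
    log_sd = rng.uniform(0.4, 1.2, size=m)
    rpm = np.exp(log_mean + log_sd * rng.standard_normal((n, m)))
    x = np.log2(np.maximum(rpm, 0.0) + 1.0)

    if config.n_tumor_types > 1:
        blocks = rng.integers(config.n_tumor_types, size=n)
        shifts = rng.normal(0.0, 0.3, size=(config.n_tumor_types, m))
        x = np.maximum(x + shifts[blocks], 0.0)
    else:
        blocks = np.zeros(n, dtype=int)

    feature_names = [f"hsa-mir-s{j + 1:04d}" for j in range(m)]
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]

    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / sd_safe

    ctl_idx, dys_idx, exc_idx = _planted_sets(rng, config)
    coefs = {}
    for key, idx in (("ctl", ctl_idx), ("dysfunction", dys_idx), ("exclusion", exc_idx)):
        signs = rng.choice([-1.0, 1.0], size=len(idx))
        coefs[key] = signs * config.effect_size

    eta = z[:, ctl_idx] @ coefs["ctl"] if len(ctl_idx) else np.zeros(n)

    def _prevalence_gap(b0):
        return np.mean(1.0 / (1.0 + np.exp(-(b0 + eta)))) - config.ctl_high_fraction

    intercept = brentq(_prevalence_gap, -60.0, 60.0, xtol=1e-12)
    p_high = 1.0 / (1.0 + np.exp(-(intercept + eta)))
    ctl_level = rng.random(n) < p_high

    dys_signal = z[:, dys_idx] @ coefs["dysfunction"] if len(dys_idx) else np.zeros(n)
    exc_signal = z[:, exc_idx] @ coefs["exclusion"] if len(exc_idx) else np.zeros(n)
    dysfunction = dys_signal + config.noise_sd * rng.standard_normal(n)
    exclusion = exc_signal + config.noise_sd * rng.standard_normal(n)

    tide = assemble_tide_score(ctl_level, dysfunction, exclusion)
    labels = pd.DataFrame(
        {
            "ctl_level": ctl_level,
            "dysfunction": dysfunction,
            "exclusion": exclusion,
            "tide_score": tide,
            "responder": responder_call(tide),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    expression = pd.DataFrame(x, index=labels.index, columns=feature_names)

    planted_union = np.union1d(np.union1d(ctl_idx, dys_idx), exc_idx).astype(int)
    truth = {
        "ctl": {
            "indices": [int(j) for j in ctl_idx],
            "features": [feature_names[j] for j in ctl_idx],
            "coefficients": [float(c) for c in coefs["ctl"]],
            "intercept": float(intercept),
        },
        "dysfunction": {
            "indices": [int(j) for j in dys_idx],
            "features": [feature_names[j] for j in dys_idx],
            "coefficients": [float(c) for c in coefs["dysfunction"]],
        },
        "exclusion": {
            "indices": [int(j) for j in exc_idx],
            "features": [feature_names[j] for j in exc_idx],
            "coefficients": [float(c) for c in coefs["exclusion"]],
        },
        "standardization": {
            feature_names[j]: {"mean": float(mu[j]), "sd": float(sd_safe[j])}
            for j in planted_union
        },
        "tumor_type": [int(b) for b in blocks],
        "effect_size": float(config.effect_size),
        "noise_sd": float(config.noise_sd),
        "seed": int(config.seed),
    }
    return SyntheticCohort(expression=expression, labels=labels, truth=truth)


def noiseless_scores(cohort: SyntheticCohort) -> pd.DataFrame:
    """Recompute the noise-free dysfunction/exclusion scores from the truth record."""
    truth = cohort.truth
    out = {}
    for key, col in (("dysfunction", "dysfunction"), ("exclusion", "exclusion")):
        rec = truth[key]
        score = np.zeros(cohort.n_samples)
        for feat, coef in zip(rec["features"], rec["coefficients"]):
            stats = truth["standardization"][feat]
            zcol = (cohort.expression[feat].to_numpy() - stats["mean"]) / stats["sd"]
            score += coef * zcol
        out[col] = score
    return pd.DataFrame(out, index=cohort.expression.index)


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write expression/labels/truth as TSV+JSON; round-trips to full precision."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "labels": directory / "labels.tsv",
        "truth": directory / "truth.json",
    }
    io.write_expression(cohort.expression, paths["expression"])
    io.write_labels(cohort.labels, paths["labels"])
    io.write_json(cohort.truth, paths["truth"])
    return paths


def read_cohort(directory) -> SyntheticCohort:
    directory = Path(directory)
    return SyntheticCohort(
        expression=io.read_expression(directory / "expression.tsv"),
        labels=io.read_labels(directory / "labels.tsv"),
        truth=io.read_json(directory / "truth.json"),
    )


def generate_target_resources(
    cohort: SyntheticCohort,
    *,
    n_genes: int = 400,
    targets_per_mirna: int = 30,
    n_gene_sets: int = 25,
    gene_set_size: int = 40,
    seed: int = 0,
):
    """Synthetic miRNA→gene target tables and a gene-set collection.

    Produces a scored table (prediction scores uniform on [50, 100], the
    range a target-prediction database reports), an unscored table from a
    second pseudo-source with partial overlap, and gene sets in which the
    first few sets are deliberately concentrated on targets of the planted
    miRNAs — so over-representation analysis on a correct selection has
    something to find.  All outputs are plain DataFrames/dicts; the GMT/TSV
    serialization lives with the consumers.
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE{j + 1:04d}" for j in range(n_genes)]
    mirnas = list(cohort.expression.columns)

    planted = sorted(
        set(cohort.truth["ctl"]["features"])
        | set(cohort.truth["dysfunction"]["features"])
        | set(cohort.truth["exclusion"]["features"])
    )

    scored_rows, unscored_rows = [], []
    high_conf: dict[str, list[str]] = {}
    for mir in mirnas:
        k = min(targets_per_mirna, n_genes)
        targets = rng.choice(n_genes, size=k, replace=False)
        scores = rng.uniform(50.0, 100.0, size=k)
        kept = []
        for g, s in zip(targets, scores):
            scored_rows.append((mir, genes[g], round(float(s), 1)))
            if s >= 80.0:
                kept.append(genes[g])
        # second source recovers most targets plus a few of its own
        n_shared = int(round(0.8 * k))
        shared = rng.choice(targets, size=n_shared, replace=False)
        extra = rng.choice(n_genes, size=max(k - n_shared, 0), replace=False)
        for g in np.concatenate([shared, extra]):
            unscored_rows.append((mir, genes[int(g)]))
        high_conf[mir] = sorted(set(kept))

    scored = pd.DataFrame(scored_rows, columns=["mirna", "gene", "score"]).drop_duplicates(
        subset=["mirna", "gene"]
    )
    unscored = pd.DataFrame(unscored_rows, columns=["mirna", "gene"]).drop_duplicates()

    planted_targets = sorted({g for mir in planted for g in high_conf.get(mir, [])})
    gene_sets: dict[str, list[str]] = {}
    for i in range(n_gene_sets):
        name = f"PATHWAY_{i + 1:03d}"
        if i < 3 and planted_targets:
            # enriched sets: majority drawn from planted-miRNA targets
            n_core = min(int(0.7 * gene_set_size), len(planted_targets))
            core = rng.choice(len(planted_targets), size=n_core, replace=False)
            rest = rng.choice(n_genes, size=gene_set_size - n_core, replace=False)
            members = {planted_targets[j] for j in core} | {genes[int(g)] for g in rest}
        else:
            members = {genes[int(g)] for g in rng.choice(n_genes, size=gene_set_size, replace=False)}
        gene_sets[name] = sorted(members)

    return scored, unscored, gene_sets
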