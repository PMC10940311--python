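# mirtide

Stepwise machine-learning prediction of tumor immune-checkpoint-blockade
(ICB) response scores from miRNA expression profiles, with exact
Shapley-value feature selection and target-gene enrichment analysis.

## The problem

The TIDE (Tumor Immune Dysfunction and Exclusion) framework summarizes a
tumor's likely ICB response in a single score derived from its
transcriptome: each sample carries a binary cytotoxic-T-lymphocyte (CTL)
infiltration call and two continuous evasion scores — *dysfunction* (T cells
present but inactive) and *exclusion* (T cells kept out).  The TIDE score is
the dysfunction score when CTL is high and the exclusion score when CTL is
low; a negative score predicts a responder.

`mirtide` asks whether this score can be predicted from **miRNA** expression
(log₂(RPM+1) values) alone.  Predicting the TIDE score *y* directly with a
single regressor fails, because conditional on the CTL level the target
mixes two different score distributions.  The package therefore fits a gated
two-stage model:

```
ĉ = C(x)                       CTL classifier (random forest)
ŷ = f_dys(x)   if ĉ = True     dysfunction regressor (random forest)
ŷ = f_exc(x)   if ĉ = False    exclusion regressor (random forest)
```

Informative miRNAs are then identified per sub-model by mean absolute
Shapley value (features with mean |φ| ≥ 0.01, or ≥ 0.02 for a stricter set),
and the model is refit with simple learners (L2 logistic regression, OLS) on
the selected features.  The selected miRNAs' predicted target genes — the
intersection of an unscored prediction source with a scored source at
prediction score ≥ 80 — are characterized by hypergeometric
over-representation analysis against GMT gene sets with Benjamini–Hochberg
correction.

Because the real cohorts behind this analysis (TCGA / PCAWG expression plus
TIDE web-service output) require downloads, the package ships a synthetic
cohort generator that plants known informative miRNAs driving the CTL level
and both scores, so every stage — routing, recovery, selection, refit,
enrichment — is testable against ground truth.

The Shapley engine is implemented in this package (numba-accelerated,
exact path-dependent tree attribution plus closed-form linear/logistic
attribution) and is verified in the test suite against brute-force coalition
enumeration; attributions satisfy local accuracy to machine precision.

## Worked example

```python
from mirtide import (CohortConfig, generate_cohort, split_train_test,
                     fit_stepwise, fit_direct_baseline, evaluate_pipeline)
from mirtide.shapley import stepwise_importance
from mirtide.selection import select_per_submodel

cohort = generate_cohort(CohortConfig(n_samples=2000, n_mirnas=200, seed=1))
x_tr, y_tr, x_te, y_te = split_train_test(cohort.expression, cohort.labels, seed=1)
model = fit_stepwise(x_tr, y_tr, hyperparams={...moderate forest sizes...}, seed=1)
report = evaluate_pipeline(model, x_te, y_te)
```

prints, for the 60-tree desk-scale forests used in the test suite:

```
CTL classifier : AUC=0.7068  F1=0.9488  bal.acc=0.5000
dysfunction    : MSE=1.0020  PCC=0.9237
exclusion      : MSE=0.9166  PCC=0.9313
stepwise TIDE  : MSE=1.7652  PCC=0.8243
direct TIDE    : MSE=1.9550
top CTL miRNAs : hsa-mir-s0010*, hsa-mir-s0143*, hsa-mir-s0013*, hsa-mir-s0029*, hsa-mir-s0006*
selected (SHAP 0.01): {'ctl': 5, 'dysfunction': 5, 'exclusion': 5}
```

Reading these numbers: the routed stepwise model beats the direct
single-regressor baseline (MSE 1.77 vs 1.96) because each regressor learns a
clean target; the CTL stage shows the signature of a 90%-CTL-high cohort —
high F1 for the majority class alongside a much lower balanced accuracy; and
all five planted CTL-informative miRNAs (starred) occupy the top Shapley
ranks, so the SHAP ≥ 0.01 selection recovers exactly the planted sets.
Score scales are those of the synthetic generator (score SD ≈ 2), so MSE
values are not comparable across datasets — the stepwise-vs-direct contrast
and the recovery counts are the portable results.

## Command line

The same pipeline is scriptable end to end:

```bash
mirtide simulate --out data --n-samples 600 --n-mirnas 200 --seed 7
mirtide train    --expression data/expression.tsv --labels data/labels.tsv --out model --seed 7
mirtide explain  --model model --data data/expression.tsv --samples model/test_samples.txt --out importance.tsv
mirtide select   --importance importance.tsv --tau 0.01 --out-dir .
mirtide refit    --expression data/expression.tsv --labels data/labels.tsv --selected-dir . --out model_simple --seed 7
mirtide evaluate --model model --expression data/expression.tsv --labels data/labels.tsv \
                 --samples model/test_samples.txt --out report.json
mirtide targets  --scored data/targets_scored.tsv --unscored data/targets_unscored.tsv \
                 --mirnas selected_union.txt --out target_genes.txt
mirtide enrich   --query target_genes.txt --gmt data/gene_sets.gmt --out enrichment.tsv
```

or in one shot: `mirtide run-all --workdir out --seed 7`.  All outputs are
tab-delimited text or JSON and byte-identical across reruns with the same
seed.

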