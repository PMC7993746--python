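# mpscore

Construction, application and evaluation of **molecular prognostic score
(mPS)** systems for tumor expression cohorts with overall-survival follow-up
— the kind of weighted binary gene signature used to stratify clear cell
renal cell carcinoma (ccRCC) patients into prognostic groups before
treatment decisions.

An mPS panel assigns each gene a favorable expression state and a positive
weight; a patient's score is

    mPS = Σ_g  GeneScore_g · weight_g,     GeneScore_g ∈ {0, 1}

where `GeneScore_g = 1` when the gene's expression falls on the favorable
side of its cohort-median cutoff (direction set by the gene's median-split
hazard ratio), so higher mPS predicts longer overall survival. The package
ships the published 21-gene ccRCC panel (total weight 74.616, strata
low < 22 ≤ median < 30 ≤ high) and implements the whole construction
pipeline that produces such panels:

1. **survival screen** — per-gene median split, log-rank test, Cox hazard
   ratio with Wald CI;
2. **differential expression** — empirical-Bayes moderated t (limma-style
   variance shrinkage), Benjamini–Hochberg adjustment, adj. p < 0.05 and
   |log2FC| > 2;
3. **feature selection** — random-forest impurity importance (500 trees,
   depth 10, stratified 10-fold CV) on binarized Gene-Scores against 3-year
   vital status;
4. **weights** — a fixed feed-forward net (inputs → 4 ReLU → 2 ReLU →
   2 softmax, Adam, lr 0.001, 1000 epochs, cross-entropy); each gene's
   weight is the L1 norm of its first-layer row;
5. **evaluation** — Kaplan–Meier / log-rank by stratum, univariate →
   multivariate Cox with the p < 0.05 carry-forward rule, Harrell's
   C-index, a points-based nomogram for 3-/5-year OS with bootstrap
   calibration.

A synthetic-cohort generator with planted ground truth (DE shifts,
median-split hazard effects, Weibull survival, tuned censoring, dichotomized
clinical covariates) makes every stage testable by parameter recovery; see
`docs/methods.md` for the model and its limits.

## Worked example

Score a cohort with the bundled panel (`examples/01_score_published_panel.py`):

```python
import numpy as np, pandas as pd
from mpscore import ExpressionMatrix, load_published_panel, score_cohort

panel = load_published_panel()                      # 21 genes, max mPS 74.616
rng = np.random.default_rng(0)
samples = [f"patient{i:02d}" for i in range(8)]
values = pd.DataFrame(rng.normal(0, 1, (21, 8)), index=panel.symbols, columns=samples)
expr = ExpressionMatrix(values, pd.Series("tumor", index=samples))
print(score_cohort(expr, panel).round(3))
```

```
              mps stratum
sample_id
patient00  39.197    high
patient01  35.495    high
patient02  25.416  median
patient03  50.006    high
patient04  27.955  median
patient05  42.919    high
patient06  28.267  median
patient07  49.209    high
```

Each mPS sums the weights of the genes seen in their favorable state
relative to the cohort median; the strata are the published 22/30 cutoffs,
with higher scores predicting longer survival. The other example scripts
build a panel end to end on a synthetic cohort and validate it on a held-out
cohort (`03`, printing a held-out log-rank p ≈ 3e-16 and C-index ≈ 0.67 for
the default configuration) and run the Cox/nomogram/calibration workflow
(`04`).

The same stages are available from the shell:

```sh
mpscore run-all --out run --seed 13            # simulate → screen → build-panel → score → evaluate
mpscore score --expression expr.tsv --panel panel.tsv --strata 22,30 --out out
```

Every stage writes a manifest (seed, config hash, record counts) and reruns
byte-identically under the same configuration.

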