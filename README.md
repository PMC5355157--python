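# progsig

Prognostic gene-signature discovery from multi-study expression data
and survival cohorts.

Clinical transcriptomics studies often follow one recipe: find genes
robustly deregulated in tumors across several independent case-control
datasets, keep the ones whose expression predicts relapse-free
survival, inspect their co-expression architecture, and distil a small
weighted gene panel whose per-patient score stratifies risk.  `progsig`
implements that recipe end-to-end as a tested, reusable library with a
thin command line, plus seeded synthetic-data generators so every stage
can be validated against planted ground truth without downloading any
cohort.

The pipeline stages:

1. **DE consensus** — per-study Welch t-tests on log2 expression,
   BH-adjusted, thresholded on fold change ≥ 1.5 and q < 0.01; a
   feature survives only if every study calls the same direction.
2. **Survival screen** — per gene, patients split at median
   expression; log-rank p and the Cox hazard ratio HR = exp(β) of high
   vs low, with Bonferroni control α/m over the m genes tested
   (m = 795 gives the familiar 6.3e-05 bound).
3. **Co-expression network** — signed graph with edges where Spearman
   |ρ| ≥ 0.6 (Bonferroni-adjusted p ≤ 0.05); positive-edge communities
   and *negative bridge* genes — genes outside a community with ≥ 3
   negative edges into it, candidate antagonists of its program.
4. **Stability selection** — k random 300-of-393 training draws;
   forward-conditional Cox (score-test entry, conditional-LR removal)
   on each; genes selected in more than half the splits form the
   signature; forced-entry refits give per-split coefficients whose
   average β̄_g is the gene's weight.
5. **Score validation** — prognostic score
   `score_i = Σ_g β̄_g · x_{g,i}`, dichotomized at the training
   cutpoint (test sets) or cohort median (external cohorts);
   Kaplan-Meier/log-rank comparison, per-test-set HR forest,
   multivariate forced-entry Cox against clinical covariates, and
   subtype-stratified analysis.

The survival kernel (Kaplan-Meier, log-rank, Efron-corrected Cox
Newton-Raphson, stepwise selection) is self-contained and
cross-checked in the test suite against brute-force oracles and
lifelines.

## Worked example

```python
import numpy as np
import pandas as pd
import progsig as ps

# a 393-patient cohort with a planted 12-gene signature among 100 genes
rng = np.random.default_rng(0)
feature_ids = [f"g{i:04d}" for i in range(100)]
pids = [f"P{i:04d}" for i in range(393)]
mat = ps.ExpressionMatrix(
    pd.DataFrame(rng.normal(8, 1, (100, 393)), index=feature_ids, columns=pids),
    pd.Series("unlabeled", index=pids),
)
genes = mat.feature_ids[:12]
betas = [m * (1 if i % 2 == 0 else -1)
         for i, m in enumerate(np.linspace(0.4, 0.7, 12))]
cohort = ps.simulate_survival(mat, genes, betas, censor_rate=0.3, seed=1)

model = ps.PrognosticSignature(mat, cohort)
res = model.fit(k=20, n_train=300, seed=2)
print(res.summary().head(4).round(3))
forest = res.evaluate_test_sets()
print("fraction of test-set CIs crossing HR=1:", forest.fraction_crossing_1)
```

Output:

```
       selection_freq  beta_mean  beta_sd_across_splits     hr
gene
g0000             1.0      0.452                  0.042  1.571
g0001             1.0     -0.577                  0.039  0.562
g0002             1.0      0.558                  0.048  1.747
g0003             1.0     -0.431                  0.029  0.650
fraction of test-set CIs crossing HR=1: 0.0
```

The planted genes are selected in all 20 resamples
(`selection_freq = 1.0`); the averaged coefficients `beta_mean` track
the planted log-hazards (g0000 was planted at +0.4, g0001 at −0.43,
g0002 at +0.45, g0003 at −0.48 — each recovered within two standard
errors), `hr` is their exponential, and in every held-out 93-patient
test set the high-score group's hazard-ratio confidence interval
excludes 1 — the score separates risk groups out of sample.

The same pipeline is scriptable from the shell:

```sh
progsig simulate case-control --n-features 1000 --n-tumor 40 --n-normal 40 \
        --seed 1 --out-prefix study1
progsig de --expression study1.expression.tsv --classes study1.classes.tsv \
        --out study1.de.tsv
progsig select --expression expr.tsv --survival surv.tsv \
        --k 60 --train 300 --seed 1 --out signature.json
progsig validate --expression tcga_like.tsv --survival tcga_like_surv.tsv \
        --signature signature.json
```

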