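# Methods

`progsig` implements a prognostic gene-signature discovery pipeline of
the kind used in breast-cancer transcriptomics: several case-control
expression studies are combined into a direction-consistent
differentially-expressed (DE) gene set; each gene is screened for
association with relapse-free survival by a median-split Kaplan-Meier /
log-rank analysis; the genetic architecture of the survival-associated
genes is examined through a signed Spearman co-expression network; a
compact weighted-Cox signature is then selected by resampling stability
selection and validated by score-based risk stratification.  Because
the public cohorts this kind of study draws on cannot be bundled, a
synthetic-data module generates cohorts with planted ground truth that
emulate the relevant structure, and every stage is tested against that
truth.

## Survival kernel

Kaplan-Meier estimation, the two-group log-rank test, Cox
proportional-hazards fitting and forward-conditional stepwise selection
are implemented in `progsig.survival` as a self-contained kernel.

**Cox fitting.** Newton-Raphson on the partial likelihood with Efron's
tie correction (Breslow available for replicating software that
defaults to it; at the tie rates our generators produce the two agree
to ~1e-10).  Risk-set sums are accumulated by cumulative sums over
tie groups; convergence is `max |Δβ| < 1e-7` within 100 iterations
with step-halving whenever a step would decrease the likelihood.
Standard errors come from the inverse observed information.  Monotone
likelihoods (perfect separation) are flagged `converged=False` via an
`|β| > 20` guard rather than silently returning a boundary estimate.
The implementation is cross-checked in the test suite against an
independent brute-force partial-likelihood maximizer and against
lifelines' `CoxPHFitter`; the log-rank statistic is verified to equal
the Rao score test of a binary Cox covariate on tie-free data.

**Ties and censoring convention.** At equal times, events precede
censorings: a patient censored at *t* is still at risk for an event at
*t*.

**Stepwise selection.** Entry uses the Rao (efficient) score test of
each excluded candidate given the current model — the statistic is
`U_j² / I_jj·A` with the candidate's information residualised on the
included covariates, computed from one gradient/Hessian evaluation over
the stacked design.  Removal re-tests every included covariate by a
conditional likelihood-ratio test (exact refit without the covariate).
Defaults `p_enter = 0.05`, `p_remove = 0.10` mirror the conventions of
the statistical packages this procedure originates from; they are
configurable.  A cycling guard stops the procedure if the selected set
revisits a previous state.

## Differential expression and consensus

Per study, a Welch two-sample t-test on log2 values with BH adjustment
(via `statsmodels`) across features; a feature is `up`/`down` when its
linear fold change `2^|Δ|` is at least 1.5 **and** its BH q is below
0.01, else `ns`.  A web-tool-driven original pipeline would typically
use a moderated t; the Welch test is a dependency-light equivalent with
the same operating characteristics at the sample sizes involved, and
the consensus counts on real data would differ accordingly.  The
consensus keeps a feature only when every study calls the same non-ns
direction (universe = intersection of the studies' feature ids); this
makes the consensus permutation-invariant in study order and monotone —
adding a study can only shrink the set.  Probe-to-gene collapse keeps,
per gene, the probe with the largest cross-study mean |log2fc| and
drops genes whose probes disagree in consensus direction (the collapse
rule is a determinism choice; published pipelines rarely state theirs).

## Survival screen

Each gene's cohort is split at the median (ties to the low group, so
the low group can be larger), compared by log-rank, and the hazard
ratio of high vs low estimated by univariate Cox on the group
indicator.  Family-wise error is controlled by Bonferroni over the
genes actually tested — screening 795 features at α = 0.05 gives the
6.3e-05 threshold, and the denominator is reported in the screen
metadata.  Constant genes are skipped, not imputed.  Gene-set
enrichment is a flat one-sided hypergeometric over-representation test
against user-supplied GMT sets with BH across sets; no ontology
hierarchy is used.

## Co-expression network

All-pairs Spearman correlation (average ranks; p from the t
approximation `t = ρ√((n−2)/(1−ρ²))`), edges where `|ρ| ≥ 0.6` and the
Bonferroni-adjusted p over the n(n−1)/2 unordered pairs is ≤ 0.05.
"Cliques" are operationalised as connected components of the
positive-edge subgraph (communities of size ≥ 5 by default), optionally
refined by greedy modularity — exact maximum-clique search is NP-hard
and not what co-expression figures actually depict.  Negative bridges
to a community are genes outside it with at least `bridge_min = 3`
negative edges into it, ranked by negative degree then mean |ρ|.
Graphs export to GraphML (lossless round trip) or edge-list TSV for
external visualisation.

## Stability selection and the prognostic score

`k` random draws of `n_train` patients (default 60 draws of 300 from a
393-patient cohort, leaving 93-patient test sets) form the resampling
plan.  Forward-conditional Cox selection runs on each training set over
the candidate genes; genes selected in **strictly more than half** of
the (successful) splits form the signature.  Forced-entry Cox refits of
the signature on each training set give per-split coefficients; their
average `β̄_g` is the gene's weight.  The prognostic score of patient
*i* is exactly `Σ_g β̄_g · x_{g,i}`; expression enters on the scale
supplied (no internal standardisation, matching the direct use of
expression values; an external cohort on another scale should use
`refit_betas`).  The model cutpoint is the mean over splits of the
median training score, where training scores are computed with the
final averaged weights (the per-split weights would give an equivalent
cutpoint up to noise; the averaged-weight convention keeps the cutpoint
on the same scale as the deployed score).

**Validation.** Each test set is scored, dichotomized at the
transferred cutpoint, and summarised by log-rank p and the Cox HR of
high vs low with its 95% CI; the forest summary is the fraction of CIs
spanning 1.  Independent cohorts are dichotomized at their own median
(two equal halves), optionally after re-estimating the weights on that
cohort by forced-entry Cox.  Multivariate validation is a single
forced-entry Cox fit of the score group plus clinical covariates, with
ordered categoricals reference-coded against their first level (stage
I / grade 1) and complete-case handling of missing rows.  Subtype
stratification supports both a global median cut and a within-subtype
median cut as a sensitivity check against unequal group sizes.

**A caution on in-cohort forests.** Averaging per-split coefficients
over many overlapping training sets places every patient in most of
the fitting data (300/393 ≈ 76% per split), so even a signature of
pure-noise genes acquires a small in-sample association with outcome:
in our null experiments ~18% of test-set CIs excluded HR = 1 when the
weights were fitted on the evaluated cohort, versus the nominal ~5%
when fitted on an independent cohort.  Test-set forests from this
design therefore overstate transferability; the independent-cohort
validation is the meaningful check.

## Synthetic-data generators

All generators are pure functions of their arguments including the
seed (`numpy` `default_rng`).

* **Case-control studies** (`simulate_case_control`): per-feature
  baselines uniform on [6, 12] log2 units (typical microarray
  intensities), Gaussian noise (default sd 0.3, a realistic residual
  sd for log2 microarray data).  DE features number
  `floor(n·de_fraction)` with the seed rounding the remainder; signs
  split ~50/50; planted |log2fc| is drawn from
  [effect, 1.25·effect] so every planted effect clears the stated
  minimum while avoiding a degenerate single effect size.
* **Multi-study panels** (`simulate_multistudy`): one shared truth,
  per-study additive per-feature Gaussian baseline shifts (batch
  effect, default sd 0.5) — the simplest mechanism that makes
  cross-study consensus non-trivial.  The default study design mirrors
  a four-study case-control panel with tumor/normal sizes
  40/7, 42/143, 5/5 and 72/36.
* **Correlated blocks** (`simulate_correlated_blocks`): one-factor
  model per block (`√ρ·f + √(1−ρ)·e`), giving exact population
  correlation ρ within blocks and independence across; negative hubs
  load on a target block's factor with weight `hub_rho/√ρ` (hence the
  constraint `|hub_rho| ≤ √ρ`) and are recorded as background in the
  truth.  Planted hubs are mutually positively correlated — as real
  antagonist gene sets are — so they can form their own small
  community.
* **Survival** (`simulate_survival`): Weibull proportional hazards,
  `S(t|x) = exp(−(t/scale)^shape · e^η)` with `η = Σβ_g x_g` centered
  across the cohort (shifts only rescale the time axis).  Censoring is
  independent exponential with the rate solved by Brent's method so the
  expected censored fraction matches `censor_rate` given the drawn
  event times — an approximation to real administrative censoring,
  documented as such.  Default censoring 0.3, a typical fraction for
  relapse-free-survival cohorts.

**What the generators do not emulate:** library-size and probe
saturation effects, heavy-tailed or count-valued expression
distributions, copy-number or mutation structure, correlated censoring,
and cohort heterogeneity beyond additive batch shifts.  Passing tests
therefore demonstrate the statistical machinery is correct and
calibrated under Gaussian/log2 and proportional-hazards assumptions,
not that any particular real cohort satisfies those assumptions.

## Numerical and design choices

* Log2 scale throughout; fold change = `2^(mean difference)`.  The
  distributional assumptions of typical source data are unstated in
  practice; Gaussian-on-log2 is our choice and is flagged here.
* Bonferroni for edge-wise network p-values and the survival screen;
  BH for DE and enrichment — matching the error rate each stage needs
  (family-wise for discovery claims, FDR for ranked candidate lists).
* Median ties go to the low group; the groups are equal-sized for even
  n without ties.
* Stepwise failure of an entire split drops it from the selection
  denominator (logged); a gene whose forced-entry refit fails in more
  than 20% of splits is dropped from the signature with a warning.
* Constant covariates, missing values, all-censored inputs, empty
  candidate sets and collinear dummy expansions raise immediately with
  named offenders; nothing is silently imputed.

## Problem sizes in the test and acceptance runs

The suite exercises the pipeline at the scale of the emulated study
design — 393-patient cohorts with 300/93 train/test resampling, up to
100 candidate genes, 60 resamples for forests and 20 for stability
selection, 200-replicate family-wise-error and 1000-replicate log-rank
calibration runs, and correlation networks of ~100 genes over 500-800
samples.  These sizes give Monte-Carlo error small enough for the
stated tolerances while keeping the full suite fast enough to run
routinely.

## Known limitations

* No time-varying covariates, stratified baselines, left truncation or
  competing risks in the Cox kernel.
* No penalized-regression (lasso/elastic-net) alternative to stepwise
  selection; no cross-validation of the selection thresholds.
* Expected false inclusions in stability selection scale with the
  number of null candidates times `p_enter`; with ~90 null candidates
  at `p_enter = 0.05`, three to four stably-selected false genes are
  expected because the heavily overlapping training sets (76% shared
  patients) make chance conditional associations persistent across
  splits.  Tightening `p_enter` or lowering the training fraction
  decorrelates the splits at some cost in power.
* Enrichment is flat-set only; no GO hierarchy handling.
* The pipeline consumes molecular subtype labels; it never computes
  them.
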