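"""Prognostic-score computation and validation.

The score of patient *i* is exactly ``sum_g beta_mean_g * x_{g,i}``;
dichotomization uses the model's transferred cutpoint on the resampled
test sets and the cohort median on independent external cohorts.
Validation covers per-test-set KM/log-rank and hazard-ratio forest
statistics, external-cohort scoring (optionally with cohort-refit
betas), multivariate forced-entry Cox with clinical covariates, and
molecular-subtype-stratified survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SurvivalCohort
from .signature import SignatureModel, SplitPlan
from .survival import CoxFit, KMCurve, cox_fit, km_estimate, logrank_test

__all__ = [
    "prognostic_score",
    "evaluate_test_sets",
    "validate_external",
    "multivariate_validate",
    "subtype_stratified",
    "ForestTable",
    "ScoreReport",
]

log = logging.getLogger(__name__)


def prognostic_score(matrix: ExpressionMatrix, model: SignatureModel) -> pd.Series:
    """Weighted expression sum per patient, ordered as the matrix columns."""
    missing = [g for g in model.genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"signature genes missing from matrix: {missing}")
    X = matrix.values.loc[model.genes]
    if not np.issubdtype(X.to_numpy().dtype, np.number):
        raise ValueError("expression values must be numeric")
    scores = model.beta_mean.loc[model.genes].to_numpy() @ X.to_numpy()
    return pd.Series(scores, index=matrix.sample_ids, name="prognostic_score")


@dataclass
class ForestTable:
    """Per-test-set hazard-ratio statistics for a forest plot.

    ``rows`` has one row per resample (split, hr, ci_low, ci_high,
    logrank_p, group sizes, flagged); ``fraction_crossing_1`` is the
    share of unflagged rows whose CI spans HR = 1.
    """

    rows: pd.DataFrame

    @property
    def fraction_crossing_1(self) -> float:
        ok = self.rows[~self.rows["flagged"]]
        if len(ok) == 0:
            return np.nan
        return float(((ok["ci_low"] <= 1) & (ok["ci_high"] >= 1)).mean())

    @property
    def n_evaluable(self) -> int:
        return int((~self.rows["flagged"]).sum())


def evaluate_test_sets(
    matrix: ExpressionMatrix,
    cohort: SurvivalCohort,
    model: SignatureModel,
    plan: SplitPlan,
) -> ForestTable:
    """Score each test set, dichotomize at the model cutpoint, test.

    High risk = score > cutpoint (the transferred mean-of-training-
    medians cutpoint).  Rows where the cutpoint leaves a group empty
    are flagged and excluded from the summary fraction.
    """
    scores_all = prognostic_score(matrix, model).to_numpy()
    time = cohort.time.to_numpy()
    event = cohort.event.to_numpy()
    rows = []
    for s, te in enumerate(plan.test_indices):
        sc = scores_all[te]
        high = sc > model.cutpoint
        row = {
            "split": s,
            "n_high": int(high.sum()),
            "n_low": int((~high).sum()),
            "hr": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "logrank_p": np.nan,
            "flagged": False,
        }
        if high.all() or not high.any():
            row["flagged"] = True
            log.warning("split %d: cutpoint left one group empty; excluded", s)
            rows.append(row)
            continue
        try:
            lr = logrank_test(time[te], event[te], np.where(high, "high", "low"))
            fit = cox_fit(
                pd.DataFrame({"high": high.astype(float)}), time[te], event[te]
            )
        except ValueError as exc:
            row["flagged"] = True
            log.warning("split %d: evaluation failed (%s); excluded", s, exc)
            rows.append(row)
            continue
        ci = fit.ci95
        row.update(
            hr=float(fit.hr.iloc[0]),
            ci_low=float(ci["lower"].iloc[0]),
            ci_high=float(ci["upper"].iloc[0]),
            logrank_p=lr.p,
        )
        rows.append(row)
    return ForestTable(pd.DataFrame(rows).set_index("split"))


@dataclass
class ScoreReport:
    """Scored, dichotomized cohort with its survival comparison."""

    scores: pd.Series
    group: pd.Series  # "low" / "high"
    cutpoint: float
    km_low: KMCurve
    km_high: KMCurve
    logrank_chi2: float
    logrank_p: float
    cox: CoxFit

    @property
    def hr(self) -> float:
        return float(self.cox.hr.iloc[0])

    @property
    def ci95(self) -> tuple[float, float]:
        ci = self.cox.ci95
        return float(ci["lower"].iloc[0]), float(ci["upper"].iloc[0])


def validate_external(
    matrix: ExpressionMatrix,
    cohort: SurvivalCohort,
    model: SignatureModel,
    refit_betas: bool = False,
) -> ScoreReport:
    """Score an independent cohort and compare low vs high risk.

    With ``refit_betas`` the per-gene weights are re-estimated on this
    cohort by forced-entry Cox before scoring (the transfer procedure
    used when an external cohort is on a different expression scale).
    Dichotomization is at the cohort median score (two equal-sized
    groups), not the transferred cutpoint.
    """
    time = cohort.time.to_numpy()
    event = cohort.event.to_numpy()
    if refit_betas:
        X = matrix.values.loc[model.genes].T
        refit = cox_fit(X, time, event)
        model = SignatureModel(
            genes=model.genes,
            beta_mean=refit.beta,
            beta_per_split=pd.DataFrame([refit.beta.to_dict()]),
            cutpoint=model.cutpoint,
            meta={**model.meta, "refit": True},
        )
    scores = prognostic_score(matrix, model)
    cut = float(scores.median())
    group = pd.Series(np.where(scores > cut, "high", "low"), index=scores.index)
    lr = logrank_test(time, event, group.to_numpy())
    fit = cox_fit(
        pd.DataFrame({"high": (group == "high").astype(float).to_numpy()}), time, event
    )
    return ScoreReport(
        scores=scores,
        group=group,
        cutpoint=cut,
        km_low=km_estimate(time[group == "low"], event[group == "low"]),
        km_high=km_estimate(time[group == "high"], event[group == "high"]),
        logrank_chi2=lr.chi2,
        logrank_p=lr.p,
        cox=fit,
    )


def _design_from_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Expand categoricals to reference-coded dummies (first level ref)."""
    cols = {}
    for name in covariates.columns:
        col = covariates[name]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            cat = col.astype("category")
            levels = list(cat.cat.categories)
            for lev in levels[1:]:
                cols[f"{name}[{lev}]"] = (cat == lev).astype(float)
        else:
            cols[name] = col.astype(float)
    return pd.DataFrame(cols, index=covariates.index)


def _name_collinear(X: pd.DataFrame) -> list[str]:
    """Columns that do not increase the design rank (QR sweep)."""
    arr = X.to_numpy()
    bad, basis = [], np.empty((arr.shape[0], 0))
    for j, name in enumerate(X.columns):
        cand = np.hstack([basis, arr[:, [j]]])
        if np.linalg.matrix_rank(cand) > basis.shape[1]:
            basis = cand
        else:
            bad.append(name)
    return bad


def multivariate_validate(
    scores: pd.Series,
    cohort_covariates: pd.DataFrame,
    time,
    event,
    score_cut: str | float = "median",
) -> pd.DataFrame:
    """Forced-entry multivariate Cox: score group + clinical covariates.

    The prognostic score enters as a high-vs-low group indicator (cut at
    the cohort median by default, or a supplied numeric cutpoint);
    ordered categoricals expand to dummies against their first level
    (e.g. stage I).  Rows with missing values are dropped complete-case
    (counted and logged).  Collinear dummy columns raise with the
    offending names.  Returns the per-covariate HR/CI/p summary table.
    """
    scores = pd.Series(scores)
    cov = cohort_covariates.loc[scores.index]
    time = pd.Series(np.asarray(time, dtype=float), index=scores.index)
    event = pd.Series(np.asarray(event), index=scores.index)
    complete = ~cov.isna().any(axis=1) & scores.notna()
    n_drop = int((~complete).sum())
    if n_drop:
        log.info("multivariate_validate: dropped %d incomplete-case patients", n_drop)
    scores, cov = scores[complete], cov[complete]
    time, event = time[complete], event[complete]
    cut = float(scores.median()) if score_cut == "median" else float(score_cut)
    design = _design_from_covariates(cov)
    design.insert(0, "score_high", (scores > cut).astype(float))
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError(
            f"collinear covariate columns: {_name_collinear(design)}"
        )
    fit = cox_fit(design, time.to_numpy(), event.to_numpy())
    return fit.summary()


def subtype_stratified(
    scores: pd.Series,
    subtype_labels: pd.Series,
    time,
    event,
    mode: str = "global-cut",
) -> pd.DataFrame:
    """Per-subtype low/high score comparison.

    ``global-cut`` dichotomizes at the whole-cohort median score and
    then stratifies by subtype; ``within-subtype`` recomputes the median
    inside each subtype (the sensitivity check against unequal group
    sizes).  Subtypes leaving fewer than 2 patients in either group are
    skipped with a warning.
    """
    if mode not in ("global-cut", "within-subtype"):
        raise ValueError(f"unknown mode {mode!r}")
    scores = pd.Series(scores)
    subtype_labels = pd.Series(subtype_labels).loc[scores.index]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    global_cut = float(scores.median())
    rows = []
    for st in sorted(subtype_labels.dropna().unique()):
        mask = (subtype_labels == st).to_numpy()
        sc = scores.to_numpy()[mask]
        cut = global_cut if mode == "global-cut" else float(np.median(sc))
        high = sc > cut
        row = {
            "subtype": st,
            "n": int(mask.sum()),
            "n_low": int((~high).sum()),
            "n_high": int(high.sum()),
            "logrank_chi2": np.nan,
            "logrank_p": np.nan,
            "skipped": False,
        }
        if high.sum() < 2 or (~high).sum() < 2 or event[mask].sum() == 0:
            row["skipped"] = True
            log.warning("subtype %s skipped: too few patients or no events", st)
        else:
            lr = logrank_test(
                time[mask], event[mask], np.where(high, "high", "low")
            )
            row["logrank_chi2"], row["logrank_p"] = lr.chi2, lr.p
        rows.append(row)
    return pd.DataFrame(rows).set_index("subtype")
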