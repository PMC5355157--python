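"""Stability selection of a weighted Cox prognostic signature.

The procedure mirrors a resampling training/test design: ``k`` random
draws of ``n_train`` patients form training sets (the complements are
the test sets); forward-conditional Cox selection runs on every
training set over the candidate genes; genes selected in more than a
stated fraction of the splits form the signature; forced-entry Cox
refits on each training set give per-split coefficients whose average
is the gene's weight.  The per-patient prognostic score is the weighted
expression sum, and the model's cutpoint is the mean of the per-split
training-score medians.

The model-facing surface is :class:`PrognosticSignature` (built from an
expression matrix and a survival cohort) whose :meth:`fit` returns a
:class:`SignatureResults` carrying the fitted :class:`SignatureModel`
plus scoring, test-set evaluation and validation methods.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SurvivalCohort
from .survival import cox_fit, cox_forward_conditional

__all__ = [
    "SplitPlan",
    "SignatureModel",
    "make_splits",
    "select_signature",
    "fit_signature_betas",
    "PrognosticSignature",
    "SignatureResults",
]

log = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    """k resamples of a cohort into disjoint train/test index sets."""

    k: int
    n_patients: int
    n_train: int
    train_indices: list[np.ndarray]
    test_indices: list[np.ndarray]
    seed: int

    def __post_init__(self) -> None:
        for tr, te in zip(self.train_indices, self.test_indices):
            if len(tr) != self.n_train:
                raise ValueError("train size not constant across resamples")
            if set(tr) & set(te):
                raise ValueError("train/test overlap")
            if len(tr) + len(te) != self.n_patients:
                raise ValueError("train + test must cover the cohort")


def make_splits(n_patients: int, n_train: int, k: int, seed: int = 0) -> SplitPlan:
    """Draw ``k`` uniform without-replacement training sets of ``n_train``."""
    if not 0 < n_train < n_patients:
        raise ValueError("require 0 < n_train < n_patients")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    train, test = [], []
    everyone = np.arange(n_patients)
    for _ in range(k):
        tr = np.sort(rng.choice(n_patients, size=n_train, replace=False))
        te = np.setdiff1d(everyone, tr)
        train.append(tr)
        test.append(te)
    return SplitPlan(k, n_patients, n_train, train, test, seed)


@dataclass
class SignatureModel:
    """A fitted weighted-Cox prognostic signature.

    ``beta_mean`` (log-hazard per expression unit) are the per-gene
    averages of the per-split forced-entry Cox coefficients; ``cutpoint``
    is the mean of the per-split training-score medians and dichotomizes
    scores into low/high risk.
    """

    genes: list[str]
    beta_mean: pd.Series
    beta_per_split: pd.DataFrame
    cutpoint: float
    selection_freq: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.selection_freq is not None:
            thr = self.meta.get("freq_threshold")
            if thr is not None:
                bad = [
                    g for g in self.genes if self.selection_freq.get(g, 0.0) <= thr
                ]
                if bad:
                    raise ValueError(f"genes below frequency threshold: {bad}")

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "genes": self.genes,
            "beta_mean": self.beta_mean.to_dict(),
            "beta_per_split": self.beta_per_split.to_dict(orient="list"),
            "cutpoint": self.cutpoint,
            "selection_freq": None
            if self.selection_freq is None
            else self.selection_freq.to_dict(),
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "SignatureModel":
        if "\n" not in source and source.endswith(".json"):
            with open(source) as fh:
                payload = json.load(fh)
        else:
            payload = json.loads(source)
        genes = payload["genes"]
        return cls(
            genes=genes,
            beta_mean=pd.Series(payload["beta_mean"]).loc[genes],
            beta_per_split=pd.DataFrame(payload["beta_per_split"])[genes],
            cutpoint=payload["cutpoint"],
            selection_freq=None
            if payload.get("selection_freq") is None
            else pd.Series(payload["selection_freq"]),
            meta=payload.get("meta", {}),
        )


def select_signature(
    matrix: ExpressionMatrix,
    cohort: SurvivalCohort,
    candidates: list[str],
    plan: SplitPlan,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    freq_threshold: float = 0.5,
) -> tuple[list[str], pd.Series, list[list[str]]]:
    """Stepwise selection on every training split; frequency tally.

    Returns (genes, selection_freq, per_split_selected).  A gene enters
    the signature when its selection frequency is strictly greater than
    ``freq_threshold`` ("more than half" at the 0.5 default).  Splits
    whose stepwise fails entirely are dropped from the denominator with
    a warning.
    """
    missing = [g for g in candidates if g not in matrix.values.index]
    if missing:
        raise ValueError(f"candidates absent from matrix: {missing[:5]}")
    X_all = matrix.values.loc[candidates].T  # patients x genes
    time = cohort.time.to_numpy()
    event = cohort.event.to_numpy()
    per_split: list[list[str]] = []
    n_ok = 0
    counts = pd.Series(0.0, index=candidates)
    for s, tr in enumerate(plan.train_indices):
        try:
            trace, _ = cox_forward_conditional(
                X_all.iloc[tr], time[tr], event[tr], p_enter=p_enter, p_remove=p_remove
            )
        except Exception as exc:  # noqa: BLE001 - degraded split, not fatal
            log.warning("split %d stepwise failed (%s); dropped from denominator", s, exc)
            per_split.append([])
            continue
        per_split.append(list(trace.selected))
        counts[trace.selected] += 1
        n_ok += 1
    if n_ok == 0:
        raise RuntimeError("stepwise selection failed on every split")
    freq = counts / n_ok
    genes = [g for g in candidates if freq[g] > freq_threshold]
    genes.sort(key=lambda g: (-freq[g], g))
    return genes, freq, per_split


def fit_signature_betas(
    matrix: ExpressionMatrix,
    cohort: SurvivalCohort,
    genes: list[str],
    plan: SplitPlan,
    selection_freq: pd.Series | None = None,
    meta: dict | None = None,
) -> SignatureModel:
    """Forced-entry Cox per training split; average betas; set cutpoint.

    Per split the selected genes are refit jointly (forced entry) on the
    training patients.  ``beta_mean`` is the column mean over splits.
    Training scores (using the averaged betas) give a per-split median
    cutpoint whose mean is the model cutpoint.  A gene failing in more
    than 20% of splits is dropped with a warning and the model refit
    without it.
    """
    if not genes:
        raise ValueError("no genes to fit")
    X_all = matrix.values.loc[genes].T
    time = cohort.time.to_numpy()
    event = cohort.event.to_numpy()
    betas = np.full((plan.k, len(genes)), np.nan)
    for s, tr in enumerate(plan.train_indices):
        try:
            fit = cox_fit(X_all.iloc[tr], time[tr], event[tr])
            betas[s] = fit.beta.to_numpy()
        except ValueError as exc:
            log.warning("split %d forced-entry fit failed: %s", s, exc)
    fail_frac = np.isnan(betas).mean(axis=0)
    bad = [g for g, f in zip(genes, fail_frac) if f > 0.2]
    if bad:
        log.warning("dropping genes failing in >20%% of splits: %s", bad)
        keep = [g for g in genes if g not in bad]
        return fit_signature_betas(matrix, cohort, keep, plan, selection_freq, meta)
    beta_per_split = pd.DataFrame(betas, columns=genes)
    beta_mean = beta_per_split.mean(axis=0, skipna=True)
    scores_all = beta_mean.to_numpy() @ matrix.values.loc[genes].to_numpy()
    cutpoints = [float(np.median(scores_all[tr])) for tr in plan.train_indices]
    model_meta = {"seed": plan.seed, "k": plan.k, "n_train": plan.n_train}
    if meta:
        model_meta.update(meta)
    return SignatureModel(
        genes=genes,
        beta_mean=beta_mean,
        beta_per_split=beta_per_split,
        cutpoint=float(np.mean(cutpoints)),
        selection_freq=selection_freq,
        meta=model_meta,
    )


class PrognosticSignature:
    """Model object: a prognostic signature to be fitted on a cohort.

    Parameters
    ----------
    expression : ExpressionMatrix
        Genes x patients; columns must match the cohort's patients.
    cohort : SurvivalCohort
        Outcomes (and optional clinical covariates) for those patients.
    candidates : list of str, optional
        Candidate gene panel for selection; defaults to every gene in
        the matrix.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        cohort: SurvivalCohort,
        candidates: list[str] | None = None,
    ) -> None:
        if expression.sample_ids != cohort.patient_ids:
            raise ValueError("expression columns must match cohort patients")
        self.expression = expression
        self.cohort = cohort
        self.candidates = candidates or expression.feature_ids

    @classmethod
    def from_dataframes(
        cls, expression: pd.DataFrame, survival: pd.DataFrame, candidates=None
    ) -> "PrognosticSignature":
        """Build from plain DataFrames (expression genes x patients;
        survival with columns ``time`` and ``event`` indexed by patient)."""
        pids = list(survival.index)
        classes = pd.Series("unlabeled", index=pids)
        mat = ExpressionMatrix(expression.loc[:, pids], classes)
        extra = [c for c in survival.columns if c not in ("time", "event")]
        cohort = SurvivalCohort(
            survival["time"],
            survival["event"],
            mat,
            survival[extra] if extra else None,
        )
        return cls(mat, cohort, candidates)

    def fit(
        self,
        k: int = 60,
        n_train: int | None = None,
        plan: SplitPlan | None = None,
        seed: int = 0,
        p_enter: float = 0.05,
        p_remove: float = 0.10,
        freq_threshold: float = 0.5,
    ) -> "SignatureResults":
        """Run the full stability-selection + averaging procedure."""
        n = self.cohort.n_patients
        if plan is None:
            if n_train is None:
                n_train = max(1, int(round(0.75 * n)))
            plan = make_splits(n, n_train, k, seed)
        genes, freq, per_split = select_signature(
            self.expression,
            self.cohort,
            self.candidates,
            plan,
            p_enter=p_enter,
            p_remove=p_remove,
            freq_threshold=freq_threshold,
        )
        if not genes:
            raise RuntimeError(
                "stability selection returned an empty signature; "
                "no candidate cleared the frequency threshold"
            )
        model = fit_signature_betas(
            self.expression,
            self.cohort,
            genes,
            plan,
            selection_freq=freq,
            meta={
                "p_enter": p_enter,
                "p_remove": p_remove,
                "freq_threshold": freq_threshold,
            },
        )
        return SignatureResults(self, model, plan, per_split)


class SignatureResults:
    """Fitted signature: estimates, uncertainties and evaluation hooks."""

    def __init__(
        self,
        parent: PrognosticSignature,
        model: SignatureModel,
        plan: SplitPlan,
        per_split_selected: list[list[str]] | None = None,
    ) -> None:
        self.model = model
        self.plan = plan
        self.expression = parent.expression
        self.cohort = parent.cohort
        self.per_split_selected = per_split_selected or []

    @property
    def genes(self) -> list[str]:
        return self.model.genes

    @property
    def cutpoint(self) -> float:
        return self.model.cutpoint

    def score(self, matrix: ExpressionMatrix | None = None) -> pd.Series:
        from .validate import prognostic_score

        return prognostic_score(matrix or self.expression, self.model)

    def evaluate_test_sets(self):
        from .validate import evaluate_test_sets

        return evaluate_test_sets(self.expression, self.cohort, self.model, self.plan)

    def validate_external(self, matrix, cohort, refit_betas: bool = False):
        from .validate import validate_external

        return validate_external(matrix, cohort, self.model, refit_betas=refit_betas)

    def summary(self) -> pd.DataFrame:
        """Per-gene table: selection frequency, averaged beta, spread, HR."""
        m = self.model
        sd = m.beta_per_split.std(axis=0, ddof=1)
        tab = pd.DataFrame(
            {
                "selection_freq": None
                if m.selection_freq is None
                else m.selection_freq.loc[m.genes],
                "beta_mean": m.beta_mean,
                "beta_sd_across_splits": sd,
                "hr": np.exp(m.beta_mean),
            }
        )
        tab.index.name = "gene"
        return tab

    def plot_forest(self, ax=None):
        from .plotting import plot_forest

        return plot_forest(self.evaluate_test_sets(), ax=ax)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<SignatureResults: {len(self.genes)} genes, k={self.plan.k}, "
            f"cutpoint={self.cutpoint:.3f}>"
        )
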