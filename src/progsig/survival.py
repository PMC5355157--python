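"""Survival-statistics kernel.

Implements the four primitives every downstream stage leans on:

* Kaplan-Meier product-limit estimation (:func:`km_estimate`)
* the two-group log-rank test (:func:`logrank_test`)
* Cox proportional-hazards fitting by Newton-Raphson on the
  Efron-tie-corrected partial likelihood (:func:`cox_fit`)
* forward-conditional stepwise covariate selection for the Cox model:
  entry by Rao score test, removal by conditional likelihood-ratio test
  (:func:`cox_forward_conditional`)

Conventions: at tied times, events precede censorings (a patient
censored at t is still at risk for an event at t).  Breslow tie
handling is available as an option; Efron is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "CoxFit",
    "StepwiseTrace",
    "LogrankResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_score_tests",
    "cox_forward_conditional",
]


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit survival curve.

    ``event_times`` lists the distinct times with at least one event;
    ``survival`` is S(t) just after each such time; ``at_risk`` is the
    number at risk just before it; ``n_events`` the events at it.
    S(0) = 1 implicitly.  ``all_censored`` flags degenerate input with
    no events (flat curve).
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    all_censored: bool = False

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def _check_surv(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if np.any(time <= 0):
        raise ValueError("times must be strictly positive")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicator must be 0/1")
    return time, event.astype(int)


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    Times with only censorings contribute no step.  All-censored input
    yields a flat curve flagged ``all_censored`` (with a warning) rather
    than an error.
    """
    time, event = _check_surv(time, event)
    if event.sum() == 0:
        warnings.warn("all observations censored; Kaplan-Meier curve is flat")
        return KMCurve(
            np.empty(0), np.empty(0), np.empty(0, dtype=int), np.empty(0, dtype=int),
            all_censored=True,
        )
    t_sorted = np.sort(time)
    uniq = np.unique(time[event == 1])
    # at risk just before t: censored-at-t patients still count (events first)
    at_risk = len(time) - np.searchsorted(t_sorted, uniq, side="left")
    d = np.array([int(((time == t) & (event == 1)).sum()) for t in uniq])
    surv = np.cumprod(1.0 - d / at_risk)
    return KMCurve(uniq, surv, at_risk.astype(int), d)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

@dataclass
class LogrankResult:
    chi2: float
    p: float
    observed: float
    expected: float
    variance: float

    def __iter__(self):  # allow  chi2, p = logrank_test(...)
        return iter((self.chi2, self.p))


def logrank_test(time, event, group) -> LogrankResult:
    """Two-group log-rank test.

    chi2 = (O1 - E1)^2 / V with the hypergeometric variance summed over
    distinct event times; p from a 1-df chi-square.  Exactly two
    non-empty groups are required.
    """
    time, event = _check_surv(time, event)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError(f"log-rank test requires exactly 2 groups, got {len(labels)}")
    if event.sum() == 0:
        raise ValueError("no events in either group")
    g1 = group == labels[0]
    t_all = np.sort(time)
    t_g1 = np.sort(time[g1])
    uniq = np.unique(time[event == 1])
    n = len(time) - np.searchsorted(t_all, uniq, side="left")
    n1 = g1.sum() - np.searchsorted(t_g1, uniq, side="left")
    d = np.array([int(((time == t) & (event == 1)).sum()) for t in uniq])
    d1 = np.array([int(((time == t) & (event == 1) & g1).sum()) for t in uniq])
    O1 = d1.sum()
    E1 = float(np.sum(d * n1 / n))
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    V = float(np.nansum(np.where(n > 1, v, 0.0)))
    if V <= 0:
        return LogrankResult(0.0, 1.0, float(O1), E1, V)
    chi2 = (O1 - E1) ** 2 / V
    return LogrankResult(float(chi2), float(stats.chi2.sf(chi2, 1)), float(O1), E1, V)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def _cox_loglik(X, time, event, beta, ties="efron", want_hess=True, want_grad=True):
    """Partial log-likelihood, gradient and observed information.

    Risk-set sums S0, S1, S2 are accumulated by cumulative sums over
    tie groups in decreasing-time order; Efron's correction downweights
    the tied-event contribution within each group.  Groups with a
    single event (the common case) are handled in one vectorised batch,
    tied groups in a short loop.  Returns (loglik, grad, info) with
    info = -Hessian; grad/info are None unless requested.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.mean()  # partial likelihood invariant to shifts
    w = np.exp(eta)
    order = np.argsort(-time, kind="stable")
    Xs, ts, es, ws, etas = X[order], time[order], event[order], w[order], eta[order]

    # tie-group boundaries in descending-time order
    new_grp = np.empty(n, dtype=bool)
    new_grp[0] = True
    new_grp[1:] = ts[1:] != ts[:-1]
    starts = np.flatnonzero(new_grp)
    ends = np.append(starts[1:], n)
    G = len(starts)

    wX = ws[:, None] * Xs
    c0 = np.cumsum(ws)
    C1 = np.cumsum(wX, axis=0)
    S0g = c0[ends - 1]                      # (G,)
    S1g = C1[ends - 1]                      # (G, p)
    if want_hess:
        outer = wX[:, :, None] * Xs[:, None, :]      # (n, p, p)
        S2g = np.cumsum(np.add.reduceat(outer, starts, axis=0), axis=0)  # (G, p, p)

    ev = es == 1
    ll = float(etas[ev].sum())
    grad = Xs[ev].sum(axis=0) if want_grad else None
    info = np.zeros((p, p)) if want_hess else None

    d_g = np.add.reduceat(ev.astype(np.int64), starts)
    single = d_g == 1
    multi = np.flatnonzero(d_g > 1)

    if single.any():
        denom = S0g[single]
        ll -= float(np.log(denom).sum())
        if want_grad or want_hess:
            Z = S1g[single] / denom[:, None]
            if want_grad:
                grad -= Z.sum(axis=0)
            if want_hess:
                info += np.einsum("g,gij->ij", 1.0 / denom, S2g[single])
                info -= np.einsum("gi,gj->ij", Z, Z)

    for gi in multi:
        blk = slice(starts[gi], ends[gi])
        mask = ev[blk]
        we = ws[blk][mask]
        Xe = Xs[blk][mask]
        d = len(we)
        d0 = we.sum()
        d1 = (we[:, None] * Xe).sum(axis=0)
        d2 = Xe.T @ (we[:, None] * Xe) if want_hess else None
        fracs = (np.arange(d) / d) if ties == "efron" else np.zeros(d)
        denom = S0g[gi] - fracs * d0                    # (d,)
        ll -= float(np.log(denom).sum())
        if want_grad or want_hess:
            Zl = (S1g[gi][None, :] - fracs[:, None] * d1[None, :]) / denom[:, None]
            if want_grad:
                grad -= Zl.sum(axis=0)
            if want_hess:
                S2l = S2g[gi][None] - fracs[:, None, None] * d2[None]
                info += np.einsum("l,lij->ij", 1.0 / denom, S2l)
                info -= np.einsum("li,lj->ij", Zl, Zl)
    return ll, grad, info


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit.

    ``beta`` are log-hazard coefficients, ``hr = exp(beta)``, ``ci95``
    the Wald interval exp(beta +- 1.96 se).  ``loglik`` is the maximized
    partial log-likelihood, ``loglik_null`` its value at beta = 0.
    """

    beta: pd.Series
    se: pd.Series
    loglik: float
    loglik_null: float
    converged: bool
    n: int
    n_events: int
    ties: str = "efron"
    info: np.ndarray | None = None

    @property
    def hr(self) -> pd.Series:
        return np.exp(self.beta)

    @property
    def ci95(self) -> pd.DataFrame:
        lo = np.exp(self.beta - 1.96 * self.se)
        hi = np.exp(self.beta + 1.96 * self.se)
        return pd.DataFrame({"lower": lo, "upper": hi})

    @property
    def z(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    @property
    def p(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.z)), index=self.beta.index)

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "hr": self.hr,
                "ci_low": self.ci95["lower"],
                "ci_high": self.ci95["upper"],
                "z": self.z,
                "p": self.p,
            }
        )
        out.index.name = "covariate"
        return out


def _as_design(X):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        arr = X.to_numpy(dtype=float)
    elif isinstance(X, pd.Series):
        names = [X.name or "x0"]
        arr = X.to_numpy(dtype=float)[:, None]
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = [f"x{i}" for i in range(arr.shape[1])]
    return arr, names


def cox_fit(X, time, event, ties="efron", max_iter=100, tol=1e-7, beta_init=None) -> CoxFit:
    """Fit a Cox PH model by Newton-Raphson with step-halving.

    Parameters
    ----------
    X : array-like or DataFrame, shape (n, p)
        Covariates; constant columns are rejected, missing values are an
        error.
    ties : {"efron", "breslow"}
        Tie correction for the partial likelihood.
    max_iter, tol : convergence control; convergence is declared when
        ``max |delta beta| < tol``.

    Non-convergence (e.g. monotone likelihood under perfect separation)
    is flagged on the result, never silent.
    """
    arr, names = _as_design(X)
    time, event = _check_surv(time, event)
    if np.isnan(arr).any():
        raise ValueError("covariates contain missing values")
    if arr.shape[0] != len(time):
        raise ValueError("X rows must match number of patients")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    const = np.ptp(arr, axis=0) == 0
    if const.any():
        bad = [names[i] for i in np.flatnonzero(const)]
        raise ValueError(f"constant covariate column(s): {bad}")
    n, p = arr.shape

    ll_null, _, _ = _cox_loglik(arr, time, event, np.zeros(p), ties,
                                want_hess=False, want_grad=False)
    beta = np.zeros(p) if beta_init is None else np.asarray(beta_init, dtype=float).copy()
    if beta_init is None:
        ll = ll_null
    else:
        ll, _, _ = _cox_loglik(arr, time, event, beta, ties, want_hess=False, want_grad=False)
    converged = False
    info = None
    for _ in range(max_iter):
        ll, grad, info = _cox_loglik(arr, time, event, beta, ties)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix") from exc
        # step-halving: insist the partial likelihood does not decrease
        scale = 1.0
        for _h in range(30):
            cand = beta + scale * step
            ll_new, _, _ = _cox_loglik(arr, time, event, cand, ties,
                                       want_hess=False, want_grad=False)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2
        else:
            break  # no improving step found
        beta = cand
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > 20:
        converged = False  # monotone likelihood / separation
    ll, grad, info = _cox_loglik(arr, time, event, beta, ties)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    idx = pd.Index(names)
    return CoxFit(
        beta=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        loglik=float(ll),
        loglik_null=float(ll_null),
        converged=converged,
        n=n,
        n_events=int(event.sum()),
        ties=ties,
        info=info,
    )


def _empty_fit(time, event, ties="efron") -> CoxFit:
    time, event = _check_surv(time, event)
    idx = pd.Index([], dtype=object)
    return CoxFit(
        beta=pd.Series(dtype=float, index=idx),
        se=pd.Series(dtype=float, index=idx),
        loglik=0.0,
        loglik_null=0.0,
        converged=True,
        n=len(time),
        n_events=int(np.asarray(event).sum()),
        ties=ties,
    )


def cox_score_tests(X_model, beta_model, X_candidates, time, event, ties="efron"):
    """Rao (efficient) score test for adding each candidate covariate.

    Evaluates the partial-likelihood gradient and information at
    ``(beta_model, 0)`` over the stacked design and returns, per
    candidate, the 1-df score statistic ``U_j^2 / I_jj.A`` with
    ``I_jj.A`` the candidate's information residualised on the current
    model.  Returns (stat array, p array).
    """
    Xc, _ = _as_design(X_candidates)
    time, event = _check_surv(time, event)
    m = Xc.shape[1]
    if X_model is None or (hasattr(X_model, "shape") and np.size(X_model) == 0):
        Xa = np.empty((len(time), 0))
        beta_a = np.empty(0)
    else:
        Xa, _ = _as_design(X_model)
        beta_a = np.asarray(beta_model, dtype=float)
    pA = Xa.shape[1]
    X_full = np.hstack([Xa, Xc])
    beta_full = np.concatenate([beta_a, np.zeros(m)])
    _, g, H = _cox_loglik(X_full, time, event, beta_full, ties)
    g_c = g[pA:]
    H_cc = H[pA:, pA:]
    if pA:
        H_aa = H[:pA, :pA]
        H_ac = H[:pA, pA:]
        try:
            W = np.linalg.solve(H_aa, H_ac)
        except np.linalg.LinAlgError:
            W = np.linalg.lstsq(H_aa, H_ac, rcond=None)[0]
        denom = np.diag(H_cc) - np.sum(H_ac * W, axis=0)
    else:
        denom = np.diag(H_cc).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, g_c**2 / denom, 0.0)
    pvals = stats.chi2.sf(stat, 1)
    return stat, pvals


@dataclass
class StepRecord:
    action: str  # "enter" | "remove"
    covariate: str
    stat: float
    p: float


@dataclass
class StepwiseTrace:
    selected: list[str] = field(default_factory=list)
    steps: list[StepRecord] = field(default_factory=list)
    stopped: str = ""


def cox_forward_conditional(
    X_candidates: pd.DataFrame,
    time,
    event,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 100,
    ties: str = "efron",
) -> tuple[StepwiseTrace, CoxFit]:
    """Forward-conditional stepwise Cox selection.

    Each iteration: (enter) compute the Rao score-test p-value for every
    excluded candidate given the current model and add the smallest if
    below ``p_enter``; (remove) re-test every included covariate by a
    conditional likelihood-ratio test (refitting without it) and drop the
    worst while its p exceeds ``p_remove``.  Stops when no candidate
    qualifies for entry, on ``max_steps``, or when the selected set
    revisits a previous state (cycling guard).  The final model is refit
    by full Newton iteration.
    """
    if not (0 < p_enter <= p_remove < 1):
        raise ValueError("require 0 < p_enter <= p_remove < 1")
    if X_candidates.shape[1] < 1:
        raise ValueError("at least one candidate covariate required")
    time, event = _check_surv(time, event)
    names = list(X_candidates.columns)
    arr = X_candidates.to_numpy(dtype=float)
    selected: list[str] = []
    trace = StepwiseTrace(selected=selected)
    seen: set[frozenset] = {frozenset()}

    def model_matrix():
        cols = [names.index(s) for s in selected]
        return arr[:, cols]

    current_fit: CoxFit | None = None
    for _ in range(max_steps):
        excluded = [c for c in names if c not in selected]
        if not excluded:
            trace.stopped = "all candidates entered"
            break
        if selected:
            current_fit = cox_fit(
                pd.DataFrame(model_matrix(), columns=selected), time, event, ties=ties
            )
            beta = current_fit.beta.to_numpy()
            Xm = model_matrix()
        else:
            beta = np.empty(0)
            Xm = np.empty((len(time), 0))
        cols = [names.index(c) for c in excluded]
        stat, pvals = cox_score_tests(Xm, beta, arr[:, cols], time, event, ties)
        best = int(np.argmin(pvals))
        if pvals[best] >= p_enter:
            trace.stopped = "no candidate qualifies for entry"
            break
        entrant = excluded[best]
        selected.append(entrant)
        trace.steps.append(StepRecord("enter", entrant, float(stat[best]), float(pvals[best])))

        # removal sweep by conditional likelihood ratio
        while len(selected) > 1:
            full = cox_fit(
                pd.DataFrame(model_matrix(), columns=selected), time, event, ties=ties
            )
            worst, worst_p, worst_lr = None, -1.0, 0.0
            for cov in selected:
                rest = [s for s in selected if s != cov]
                cols_r = [names.index(s) for s in rest]
                red = cox_fit(
                    pd.DataFrame(arr[:, cols_r], columns=rest), time, event, ties=ties,
                    beta_init=full.beta.loc[rest].to_numpy(),
                )
                lr = max(0.0, 2 * (full.loglik - red.loglik))
                p_lr = float(stats.chi2.sf(lr, 1))
                if p_lr > worst_p:
                    worst, worst_p, worst_lr = cov, p_lr, lr
            if worst_p > p_remove:
                selected.remove(worst)
                trace.steps.append(StepRecord("remove", worst, worst_lr, worst_p))
            else:
                break

        state = frozenset(selected)
        if state in seen:
            trace.stopped = "cycling guard triggered"
            break
        seen.add(state)
    else:
        trace.stopped = "max_steps reached"

    if selected:
        cols = [names.index(s) for s in selected]
        final = cox_fit(pd.DataFrame(arr[:, cols], columns=selected), time, event, ties=ties)
    else:
        final = _empty_fit(time, event, ties)
    trace.selected = selected
    return trace, final
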