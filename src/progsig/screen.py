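"""Per-gene median-split survival screen and gene-set enrichment.

Every gene is screened by splitting the cohort at its median expression
(ties to the low group), comparing relapse-free survival between the
low and high halves with a log-rank test, and estimating the hazard
ratio of high vs low from a univariate Cox fit on the group indicator.
Family-wise error is controlled by Bonferroni over the genes actually
tested.  Enrichment is a flat one-sided hypergeometric
over-representation test against user-supplied gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, SurvivalCohort
from .survival import cox_fit, logrank_test

__all__ = [
    "ScreenRecord",
    "median_split",
    "screen_gene",
    "screen_all",
    "enrich_gene_set",
]


def median_split(expr_vector) -> np.ndarray:
    """Label each patient 'low' (value <= median) or 'high' (> median).

    Raises on constant vectors (a single group); callers screening many
    genes catch this and skip the gene.
    """
    x = np.asarray(expr_vector, dtype=float)
    if len(x) < 4:
        raise ValueError("median split needs at least 4 patients")
    med = np.median(x)
    labels = np.where(x <= med, "low", "high")
    if len(np.unique(labels)) < 2:
        raise ValueError("constant expression vector: all patients in one group")
    return labels


@dataclass
class ScreenRecord:
    gene_id: str
    hr: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    logrank_chi2: float = np.nan
    logrank_p: float = np.nan
    n_low: int = 0
    n_high: int = 0
    skipped: bool = False
    reason: str = ""

    @property
    def prognosis_class(self) -> str:
        if np.isnan(self.hr):
            return "na"
        return "adverse" if self.hr > 1 else "favorable"


def screen_gene(expr_vector, cohort: SurvivalCohort, gene_id: str = "gene") -> ScreenRecord:
    """Median-split screen of one gene against the cohort's outcome."""
    x = np.asarray(expr_vector, dtype=float)
    if len(x) != cohort.n_patients:
        raise ValueError("expression vector not aligned with cohort")
    try:
        labels = median_split(x)
    except ValueError as exc:
        return ScreenRecord(gene_id, skipped=True, reason=str(exc))
    time = cohort.time.to_numpy()
    event = cohort.event.to_numpy()
    lr = logrank_test(time, event, labels)
    high = (labels == "high").astype(float)
    fit = cox_fit(pd.DataFrame({"high": high}), time, event)
    ci = fit.ci95
    return ScreenRecord(
        gene_id=gene_id,
        hr=float(fit.hr.iloc[0]),
        ci_low=float(ci["lower"].iloc[0]),
        ci_high=float(ci["upper"].iloc[0]),
        logrank_chi2=lr.chi2,
        logrank_p=lr.p,
        n_low=int((labels == "low").sum()),
        n_high=int((labels == "high").sum()),
    )


def screen_all(
    matrix: ExpressionMatrix, cohort: SurvivalCohort, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Screen every gene; Bonferroni threshold alpha / m.

    ``m`` is the number of genes actually tested (constant genes are
    skipped and excluded from the denominator, which is reported in the
    metadata).  Returns (table, metadata) where metadata carries the
    threshold and the favorable/adverse significant counts.
    """
    if matrix.n_features < 1:
        raise ValueError("need at least one gene")
    records = [
        screen_gene(matrix.values.loc[g].to_numpy(), cohort, g)
        for g in matrix.feature_ids
    ]
    rows = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "hr": r.hr,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "logrank_chi2": r.logrank_chi2,
                "logrank_p": r.logrank_p,
                "n_low": r.n_low,
                "n_high": r.n_high,
                "skipped": r.skipped,
            }
            for r in records
        ]
    ).set_index("gene_id")
    m = int((~rows["skipped"]).sum())
    threshold = alpha / m if m else np.nan
    rows["significant"] = (~rows["skipped"]) & (rows["logrank_p"] < threshold)
    rows["prognosis_class"] = np.where(
        rows["hr"].isna(), "na", np.where(rows["hr"] > 1, "adverse", "favorable")
    )
    sig = rows[rows["significant"]]
    meta = {
        "alpha": alpha,
        "m_tested": m,
        "bonferroni_threshold": threshold,
        "n_significant": int(len(sig)),
        "n_hr_lt_1": int((sig["hr"] < 1).sum()),
        "n_hr_gt_1": int((sig["hr"] > 1).sum()),
    }
    return rows, meta


def enrich_gene_set(
    hit_genes, background_genes, gene_sets: dict[str, set]
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of hits in each set.

    ``gene_sets`` maps set name -> gene collection (e.g. from a GMT
    file).  Sets with no overlap with the background are skipped.  The
    returned table carries the overlap count, hypergeometric p and BH q,
    sorted by p.
    """
    hits = set(hit_genes)
    bg = set(background_genes)
    if not bg:
        raise ValueError("empty background")
    if not hits <= bg:
        raise ValueError("hit genes must be a subset of the background")
    names, overlaps, sizes, pvals = [], [], [], []
    M, N = len(bg), len(hits)
    for name, genes in gene_sets.items():
        in_bg = set(genes) & bg
        if not in_bg:
            continue
        K = len(in_bg)
        k = len(in_bg & hits)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        names.append(name)
        overlaps.append(k)
        sizes.append(K)
        pvals.append(p)
    if not names:
        return pd.DataFrame(columns=["set_size", "overlap", "p", "q"])
    q = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"set_size": sizes, "overlap": overlaps, "p": pvals, "q": q}, index=names
    )
    out.index.name = "gene_set"
    return out.sort_values("p")
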