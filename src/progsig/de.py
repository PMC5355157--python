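"""Per-study differential expression and cross-study consensus.

Each study is tested feature-wise with a Welch two-sample t-test on
log2 values, BH-adjusted across features, and thresholded on linear
fold change and adjusted p.  The consensus keeps a feature only when
every study calls the same non-ns direction — the "common deregulated
set" logic of a multi-study case-control meta-analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

__all__ = ["differential_expression", "consensus", "collapse_probes"]

log = logging.getLogger(__name__)


def _assign_direction(log2fc, q, fc_cut, q_cut):
    """Vectorised direction call: ns unless fold >= fc_cut AND q < q_cut."""
    fold = 2.0 ** np.abs(log2fc)
    sig = (fold >= fc_cut) & (q < q_cut)
    out = np.where(sig & (log2fc > 0), "up", np.where(sig & (log2fc < 0), "down", "ns"))
    return out


def differential_expression(
    matrix: ExpressionMatrix, fc_cut: float = 1.5, q_cut: float = 0.01
) -> pd.DataFrame:
    """Welch t-test tumor vs normal per feature, BH-adjusted.

    Returns a DataFrame indexed by feature id with columns
    ``log2fc`` (tumor minus normal mean), ``fold_change`` (2^|log2fc|),
    ``p``, ``q`` (BH) and ``direction`` in {up, down, ns}.  Constant
    features (zero variance in both classes) get p = 1.
    """
    tumor = matrix.class_values("tumor").to_numpy()
    normal = matrix.class_values("normal").to_numpy()
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("each class needs at least 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(tumor, normal, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    log2fc = tumor.mean(axis=1) - normal.mean(axis=1)
    q = multipletests(p, method="fdr_bh")[1]
    direction = _assign_direction(log2fc, q, fc_cut, q_cut)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold_change": 2.0 ** np.abs(log2fc),
            "p": p,
            "q": q,
            "direction": direction,
        },
        index=matrix.values.index.copy(),
    )


def consensus(de_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Direction-consistent consensus over >= 2 per-study DE tables.

    The feature universe is the intersection of the study universes
    (mismatches are logged).  A feature's consensus direction is ``up``
    or ``down`` iff every study calls that same non-ns direction, else
    ``excluded``.  ``n_consistent`` counts the studies agreeing with the
    modal non-ns call; ``mean_abs_log2fc`` averages |log2fc| across
    studies (used later for probe collapse).
    """
    if len(de_tables) < 2:
        raise ValueError("consensus requires at least 2 studies")
    common = de_tables[0].index
    for t in de_tables[1:]:
        common = common.intersection(t.index)
    if len(common) == 0:
        raise ValueError("empty feature intersection across studies")
    dropped = sum(len(t) - len(common) for t in de_tables)
    if dropped:
        log.info("consensus: %d study-feature records outside the common universe", dropped)
    k = len(de_tables)
    dirs = pd.DataFrame(
        {f"direction_study{i+1}": t.loc[common, "direction"] for i, t in enumerate(de_tables)}
    )
    n_up = (dirs == "up").sum(axis=1)
    n_down = (dirs == "down").sum(axis=1)
    cons = np.where(n_up == k, "up", np.where(n_down == k, "down", "excluded"))
    out = dirs.copy()
    out["consensus_direction"] = cons
    out["n_consistent"] = np.maximum(n_up, n_down)
    out["mean_abs_log2fc"] = np.mean(
        [t.loc[common, "log2fc"].abs() for t in de_tables], axis=0
    )
    return out


def collapse_probes(consensus_table: pd.DataFrame, probe_gene_map: pd.Series) -> pd.DataFrame:
    """Collapse a probe-level consensus table to gene level.

    Probes without a map entry are dropped with a log warning.  Among a
    gene's probes the one with the largest cross-study mean |log2fc| is
    kept; genes whose probes disagree in consensus direction are
    excluded and logged.  The output is indexed by gene id and keeps a
    ``probe_id`` column naming the retained probe.
    """
    if not isinstance(probe_gene_map, pd.Series):
        raise ValueError("probe_gene_map must be a Series probe -> gene")
    kept = consensus_table[consensus_table["consensus_direction"] != "excluded"].copy()
    covered = kept.index.intersection(probe_gene_map.index)
    n_uncovered = len(kept) - len(covered)
    if n_uncovered:
        log.warning("collapse_probes: %d retained probes lack a gene mapping; dropped",
                    n_uncovered)
    kept = kept.loc[covered]
    kept["gene"] = probe_gene_map.loc[covered].values
    records = []
    for gene, grp in kept.groupby("gene", sort=True):
        if grp["consensus_direction"].nunique() > 1:
            log.warning("collapse_probes: gene %s has probes with conflicting consensus "
                        "directions; excluded", gene)
            continue
        best = grp["mean_abs_log2fc"].idxmax()
        rec = grp.loc[best].copy()
        rec["probe_id"] = best
        rec.name = gene
        records.append(rec)
    if not records:
        return pd.DataFrame(columns=list(consensus_table.columns) + ["gene", "probe_id"])
    out = pd.DataFrame(records).drop(columns=["gene"])
    out.index.name = "gene"
    return out
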