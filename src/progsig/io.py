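"""Plain-text readers and writers (TSV, GMT, truth JSON).

Expression travels as a TSV whose first column is the feature id and
whose header row lists sample ids; sample classes and survival tables
are patient-indexed TSVs.  All writers round-trip through the matching
reader.
"""

from __future__ import annotations

import json

import pandas as pd

from .containers import ExpressionMatrix, SimTruth, SurvivalCohort

__all__ = [
    "write_expression_tsv",
    "read_expression_tsv",
    "write_class_tsv",
    "read_class_tsv",
    "write_survival_tsv",
    "read_survival_tsv",
    "write_truth_json",
    "read_truth_json",
    "read_gmt",
    "load_cohort",
]


def write_expression_tsv(matrix: ExpressionMatrix, path: str) -> None:
    df = matrix.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_expression_tsv(path: str, class_path: str | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if class_path:
        classes = read_class_tsv(class_path)
    else:
        classes = pd.Series("unlabeled", index=df.columns)
    return ExpressionMatrix(df, classes)


def write_class_tsv(matrix: ExpressionMatrix, path: str) -> None:
    out = matrix.sample_class.rename("class").to_frame()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_class_tsv(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df["class"]


def write_survival_tsv(cohort: SurvivalCohort, path: str) -> None:
    out = pd.DataFrame({"time": cohort.time, "event": cohort.event})
    if cohort.covariates is not None:
        out = out.join(cohort.covariates)
    out.index.name = "patient_id"
    out.to_csv(path, sep="\t")


def read_survival_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def load_cohort(expression_path: str, survival_path: str) -> SurvivalCohort:
    """Couple an expression TSV with a survival TSV into a cohort."""
    surv = read_survival_tsv(survival_path)
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    pids = [p for p in surv.index if p in expr.columns]
    if not pids:
        raise ValueError("no shared patient ids between expression and survival")
    surv = surv.loc[pids]
    mat = ExpressionMatrix(expr[pids], pd.Series("unlabeled", index=pids))
    extra = [c for c in surv.columns if c not in ("time", "event")]
    return SurvivalCohort(
        surv["time"], surv["event"], mat, surv[extra] if extra else None
    )


def write_truth_json(truth: SimTruth, path: str) -> None:
    payload = {
        "de_features": truth.de_features,
        "block_assignments": truth.block_assignments,
        "negative_hubs": truth.negative_hubs,
        "signature_genes": truth.signature_genes,
        "signature_betas": truth.signature_betas,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_truth_json(path: str) -> SimTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return SimTruth(**payload)


def read_gmt(path: str) -> dict[str, set]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> ...

    Returns {set name: set of genes}.  Malformed lines (fewer than 3
    fields) raise.
    """
    sets: dict[str, set] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {ln}: expected >= 3 fields")
            sets[fields[0]] = set(g for g in fields[2:] if g)
    return sets
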