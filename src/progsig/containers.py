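"""In-memory containers shared across the pipeline.

Expression is always carried on a log2-like additive scale as a
features x samples :class:`pandas.DataFrame`; fold change between tumor
and normal is ``2 ** (mean difference)``.  Survival cohorts couple a
follow-up time / event-indicator pair with an expression slice and an
optional clinical-covariate table, with patient identifiers kept in a
single consistent order across all three.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_CLASSES = ("tumor", "normal", "unlabeled")


@dataclass
class ExpressionMatrix:
    """Features x samples expression matrix with per-sample class labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric matrix, index = feature ids, columns = sample ids.
        Values are log2-scale expression (unitless).
    sample_class : pandas.Series
        Per-sample label in ``{"tumor", "normal", "unlabeled"}``,
        indexed exactly like ``values.columns``.
    """

    values: pd.DataFrame
    sample_class: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if v.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.sample_class = self.sample_class.reindex(v.columns)
        if self.sample_class.isna().any():
            raise ValueError("sample_class missing for some samples")
        bad = set(self.sample_class.unique()) - set(SAMPLE_CLASSES)
        if bad:
            raise ValueError(f"unknown sample classes: {sorted(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_values(self, label: str) -> pd.DataFrame:
        """Sub-matrix of the samples carrying class ``label``."""
        return self.values.loc[:, self.sample_class == label]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[:, list(sample_ids)], self.sample_class.loc[list(sample_ids)]
        )

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)], self.sample_class)


@dataclass
class SimTruth:
    """Ground truth planted by the synthetic-data generators.

    Attributes
    ----------
    de_features : dict
        Feature id -> planted signed log2 fold change (tumor minus normal).
    block_assignments : dict
        Feature id -> correlation-block index; 0 means background.
    negative_hubs : dict
        Feature id -> index of the block the hub is anti-correlated with.
        Hubs themselves always carry block assignment 0.
    signature_genes : list
        Features with a nonzero hazard coefficient.
    signature_betas : dict
        Feature id -> true Cox log-hazard coefficient per expression unit.
    """

    de_features: dict[str, float] = field(default_factory=dict)
    block_assignments: dict[str, int] = field(default_factory=dict)
    negative_hubs: dict[str, int] = field(default_factory=dict)
    signature_genes: list[str] = field(default_factory=list)
    signature_betas: dict[str, float] = field(default_factory=dict)

    def validate(self, matrix: ExpressionMatrix, min_effect: float | None = None) -> None:
        """Check the structural invariants against a generated matrix."""
        feats = set(matrix.feature_ids)
        if not set(self.signature_genes) <= feats:
            raise ValueError("signature genes not all present in matrix")
        for hub in self.negative_hubs:
            if self.block_assignments.get(hub, 0) != 0:
                raise ValueError(f"negative hub {hub} is inside a block")
        if min_effect is not None:
            for f, lfc in self.de_features.items():
                if abs(lfc) < min_effect:
                    raise ValueError(f"planted effect of {f} below minimum")


@dataclass
class SurvivalCohort:
    """Right-censored survival outcomes coupled to expression and covariates.

    ``time`` is follow-up in arbitrary but consistent units (strictly
    positive); ``event`` is 1 for an observed event, 0 for censoring.
    Expression columns, outcome rows and covariate rows share the same
    patient ids in the same order.
    """

    time: pd.Series
    event: pd.Series
    expression: ExpressionMatrix
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.time = pd.Series(self.time, dtype=float)
        self.event = pd.Series(self.event).astype(int)
        if (self.time <= 0).any():
            raise ValueError("follow-up times must be strictly positive")
        if not self.event.isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        pids = list(self.time.index)
        if list(self.event.index) != pids:
            raise ValueError("time/event patient ids differ")
        if self.expression.sample_ids != pids:
            raise ValueError("expression columns do not match patient ids")
        if self.covariates is not None and list(self.covariates.index) != pids:
            raise ValueError("covariate rows do not match patient ids")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.time.index)

    @property
    def n_patients(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, patient_ids) -> "SurvivalCohort":
        ids = list(patient_ids)
        return SurvivalCohort(
            self.time.loc[ids],
            self.event.loc[ids],
            self.expression.subset_samples(ids),
            None if self.covariates is None else self.covariates.loc[ids],
        )
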