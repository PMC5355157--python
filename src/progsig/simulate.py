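"""Seeded synthetic-data generators with planted ground truth.

These emulate the structure of the study designs the pipeline targets:
multiple case-control expression studies sharing differentially
expressed genes, correlated gene blocks with negative-hub genes, and
survival cohorts generated under a Weibull proportional-hazards model
driven by a planted gene signature with independent right censoring.

Every generator is a pure function of its arguments including the seed:
the same call reproduces bit-identical output.  Expression is on a
log2-like additive scale; a planted log2 fold change of ``d`` means a
tumor/normal fold change of ``2**d``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import ExpressionMatrix, SimTruth, SurvivalCohort

__all__ = [
    "simulate_case_control",
    "simulate_multistudy",
    "simulate_correlated_blocks",
    "simulate_survival",
    "simulate_clinical_covariates",
]

_BASELINE_LO, _BASELINE_HI = 6.0, 12.0  # typical log2 microarray intensities


def _feature_ids(n):
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _n_de(n_features, de_fraction, rng):
    """floor(n * fraction), the seed deciding rounding of the remainder."""
    exact = n_features * de_fraction
    base = int(np.floor(exact))
    frac = exact - base
    if frac > 0 and rng.random() < frac:
        base += 1
    return min(base, n_features)


def _plant_de(n_features, de_fraction, effect_lfc, rng):
    """Pick DE features, ~50/50 up/down, |lfc| in [effect, 1.25*effect]."""
    n_de = _n_de(n_features, de_fraction, rng)
    idx = rng.choice(n_features, size=n_de, replace=False)
    n_up = n_de // 2 + (int(rng.integers(2)) if n_de % 2 else 0)
    signs = np.ones(n_de)
    signs[n_up:] = -1.0
    signs = signs[rng.permutation(n_de)]
    mags = effect_lfc * (1.0 + 0.25 * rng.random(n_de))
    return idx, signs * mags


def simulate_case_control(
    n_features: int,
    n_tumor: int,
    n_normal: int,
    de_fraction: float = 0.1,
    effect_lfc: float = 1.5,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimTruth]:
    """One case-control expression study with planted DE features.

    Background features are baseline + Gaussian noise in both classes;
    each DE feature's tumor mean is shifted by a signed log2 fold change
    of magnitude >= ``effect_lfc``, with the sign split ~50/50 up/down.
    The DE count is ``floor(n_features * de_fraction)`` with the seed
    deciding the rounding of any fractional remainder.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if n_tumor <= 0 or n_normal <= 0:
        raise ValueError("sample counts must be positive")
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must lie in [0, 1]")
    if effect_lfc <= 0 or noise_sd <= 0:
        raise ValueError("effect_lfc and noise_sd must be positive")
    rng = np.random.default_rng(seed)
    baseline = rng.uniform(_BASELINE_LO, _BASELINE_HI, n_features)
    idx, lfcs = _plant_de(n_features, de_fraction, effect_lfc, rng)
    n = n_tumor + n_normal
    values = baseline[:, None] + rng.normal(0.0, noise_sd, (n_features, n))
    values[idx, :n_tumor] += lfcs[:, None]
    feats = _feature_ids(n_features)
    samples = [f"T{i+1:03d}" for i in range(n_tumor)] + [
        f"N{i+1:03d}" for i in range(n_normal)
    ]
    classes = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal, index=samples)
    mat = ExpressionMatrix(pd.DataFrame(values, index=feats, columns=samples), classes)
    truth = SimTruth(de_features={feats[i]: float(l) for i, l in zip(idx, lfcs)})
    return mat, truth


def simulate_multistudy(
    k_studies: int,
    shared_truth: SimTruth,
    per_study_sizes: list[tuple[int, int]],
    study_shift_sd: float = 0.5,
    seed: int = 0,
    n_features: int | None = None,
    noise_sd: float = 0.3,
) -> list[ExpressionMatrix]:
    """Independent studies sharing one DE truth (same features, same signs).

    Each study receives an additive per-feature Gaussian baseline shift
    (batch effect, sd ``study_shift_sd``) on top of a common baseline,
    plus independent measurement noise.  ``per_study_sizes`` is a list
    of (n_tumor, n_normal) pairs, one per study.
    """
    if k_studies < 2:
        raise ValueError("k_studies must be >= 2")
    if not per_study_sizes:
        raise ValueError("per_study_sizes must be non-empty")
    if len(per_study_sizes) != k_studies:
        raise ValueError("per_study_sizes length must equal k_studies")
    rng = np.random.default_rng(seed)
    if n_features is None:
        # infer the feature universe from the planted truth's id width
        ids = sorted(shared_truth.de_features)
        if not ids:
            raise ValueError("cannot infer n_features from empty truth; pass n_features")
        n_features = int(ids[-1][1:])
        n_features = max(n_features, len(ids))
    feats = _feature_ids(n_features)
    baseline = rng.uniform(_BASELINE_LO, _BASELINE_HI, n_features)
    lfc = np.zeros(n_features)
    for f, d in shared_truth.de_features.items():
        lfc[feats.index(f)] = d
    studies = []
    for s, (n_tumor, n_normal) in enumerate(per_study_sizes):
        if n_tumor <= 0 or n_normal <= 0:
            raise ValueError("sample counts must be positive")
        shift = rng.normal(0.0, study_shift_sd, n_features) if study_shift_sd > 0 else 0.0
        n = n_tumor + n_normal
        values = (baseline + shift)[:, None] + rng.normal(0, noise_sd, (n_features, n))
        values[:, :n_tumor] += lfc[:, None]
        samples = [f"S{s+1}T{i+1:03d}" for i in range(n_tumor)] + [
            f"S{s+1}N{i+1:03d}" for i in range(n_normal)
        ]
        classes = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal, index=samples)
        studies.append(
            ExpressionMatrix(pd.DataFrame(values, index=feats, columns=samples), classes)
        )
    return studies


def simulate_correlated_blocks(
    block_sizes: list[int],
    n_background: int = 0,
    within_rho: float = 0.8,
    n_samples: int = 500,
    n_negative_hubs: int = 0,
    hub_rho: float = -0.7,
    hub_target_block: int = 1,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Block-correlated expression via a one-factor model per block.

    Block members are ``sqrt(rho) * f + sqrt(1-rho) * e`` around a
    per-feature baseline, giving pairwise population (Pearson)
    correlation ``within_rho`` inside the block and independence across
    blocks.  Each negative hub loads on block ``hub_target_block``'s
    factor with a negative weight chosen so its population correlation
    with block members is ~``hub_rho``; hubs are recorded as background
    (block 0) in the truth.  Background features are independent noise.
    """
    if not 0 < within_rho < 1:
        raise ValueError("within_rho must lie in (0, 1)")
    if n_negative_hubs > 0:
        if hub_rho >= 0:
            raise ValueError("hub_rho must be negative when hubs are requested")
        if abs(hub_rho) >= 1:
            raise ValueError("|hub_rho| must be < 1")
        if abs(hub_rho) > np.sqrt(within_rho):
            raise ValueError("|hub_rho| cannot exceed sqrt(within_rho) in a one-factor model")
        if not 1 <= hub_target_block <= len(block_sizes):
            raise ValueError("hub_target_block out of range")
    n_block = sum(block_sizes)
    n_features = n_block + n_negative_hubs + n_background
    rng = np.random.default_rng(seed)
    feats = _feature_ids(n_features)
    baseline = rng.uniform(_BASELINE_LO, _BASELINE_HI, n_features)
    values = np.empty((n_features, n_samples))
    assignments: dict[str, int] = {}
    factors = rng.normal(size=(len(block_sizes), n_samples))
    row = 0
    a, b = np.sqrt(within_rho), np.sqrt(1 - within_rho)
    for bi, size in enumerate(block_sizes, start=1):
        for _ in range(size):
            values[row] = a * factors[bi - 1] + b * rng.normal(size=n_samples)
            assignments[feats[row]] = bi
            row += 1
    hubs: dict[str, int] = {}
    load = hub_rho / a if n_negative_hubs else 0.0
    for _ in range(n_negative_hubs):
        values[row] = load * factors[hub_target_block - 1] + np.sqrt(
            1 - load**2
        ) * rng.normal(size=n_samples)
        assignments[feats[row]] = 0
        hubs[feats[row]] = hub_target_block
        row += 1
    for _ in range(n_background):
        values[row] = rng.normal(size=n_samples)
        assignments[feats[row]] = 0
        row += 1
    values += baseline[:, None]
    samples = [f"P{i+1:04d}" for i in range(n_samples)]
    classes = pd.Series("unlabeled", index=samples)
    mat = ExpressionMatrix(pd.DataFrame(values, index=feats, columns=samples), classes)
    truth = SimTruth(block_assignments=assignments, negative_hubs=hubs)
    return mat, truth


def _solve_censor_rate(event_times: np.ndarray, censor_rate: float) -> float:
    """Exponential-censoring rate hitting the expected censored fraction.

    Censored iff C < T with C ~ Exp(lam); given the drawn event times,
    E[censored fraction] = mean(1 - exp(-lam * t)).  Solved by Brent.
    """
    def f(lam):
        return np.mean(1.0 - np.exp(-lam * event_times)) - censor_rate

    lo, hi = 1e-12, 1.0 / max(event_times.mean(), 1e-300)
    while f(hi) < 0:
        hi *= 10
        if hi > 1e18:
            break
    return float(optimize.brentq(f, lo, hi, maxiter=200))


def simulate_survival(
    expression: ExpressionMatrix,
    signature_genes: list[str],
    signature_betas,
    baseline_shape: float = 1.5,
    baseline_scale: float = 10.0,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> SurvivalCohort:
    """Weibull proportional-hazards survival outcomes for a cohort.

    The linear predictor is ``eta_i = sum_g beta_g * x_{g,i}`` (centered
    across patients for numerical sanity; proportional hazards are
    unaffected).  Event times satisfy
    ``S(t | x) = exp(-(t/scale)^shape * exp(eta))``; censoring times are
    independent exponentials with rate solved so the expected censored
    fraction is ~``censor_rate``.
    """
    genes = list(signature_genes)
    betas = np.asarray(signature_betas, dtype=float)
    if len(genes) != len(betas):
        raise ValueError("signature_genes and signature_betas length mismatch")
    missing = [g for g in genes if g not in expression.values.index]
    if missing:
        raise ValueError(f"signature genes absent from expression: {missing}")
    if baseline_shape <= 0 or baseline_scale <= 0:
        raise ValueError("baseline_shape and baseline_scale must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = expression.n_samples
    if genes:
        Xg = expression.values.loc[genes].to_numpy()
        eta = betas @ Xg
        eta = eta - eta.mean()
    else:
        eta = np.zeros(n)
    u = rng.uniform(size=n)
    t_event = baseline_scale * (-np.log(u) * np.exp(-eta)) ** (1.0 / baseline_shape)
    t_event = np.maximum(t_event, 1e-12)
    if censor_rate > 0:
        lam = _solve_censor_rate(t_event, censor_rate)
        t_cens = rng.exponential(1.0 / lam, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    pids = expression.sample_ids
    truth = SimTruth(
        signature_genes=genes, signature_betas=dict(zip(genes, map(float, betas)))
    )
    cohort = SurvivalCohort(
        pd.Series(time, index=pids), pd.Series(event, index=pids), expression
    )
    cohort.truth = truth  # attach planted truth for downstream checks
    return cohort


def simulate_clinical_covariates(
    patient_ids,
    rng_or_seed=0,
    confounder_with: np.ndarray | None = None,
    r: float = 0.0,
    subtypes=("LumA", "LumB", "HER2", "Basal", "Normal"),
) -> pd.DataFrame:
    """Clinical covariate table (age, stage, grade, ER, PR, subtype).

    ``confounder_with`` optionally makes age correlate (Pearson ~``r``)
    with a supplied per-patient vector, for adjusted-effect experiments.
    """
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    n = len(patient_ids)
    z = rng.normal(size=n)
    if confounder_with is not None and r != 0.0:
        c = np.asarray(confounder_with, dtype=float)
        c = (c - c.mean()) / (c.std() or 1.0)
        z = r * c + np.sqrt(max(0.0, 1 - r**2)) * z
    age = np.clip(58 + 12 * z, 25, 95).round(1)
    stage = rng.choice(["I", "II", "III", "IV"], size=n, p=[0.35, 0.4, 0.18, 0.07])
    grade = rng.choice(["1", "2", "3"], size=n, p=[0.2, 0.45, 0.35])
    er = rng.binomial(1, 0.75, size=n)
    pr = rng.binomial(1, 0.65, size=n)
    subtype = rng.choice(list(subtypes), size=n)
    df = pd.DataFrame(
        {
            "age": age,
            "stage": pd.Categorical(stage, categories=["I", "II", "III", "IV"], ordered=True),
            "grade": pd.Categorical(grade, categories=["1", "2", "3"], ordered=True),
            "ER": er,
            "PR": pr,
            "subtype": subtype,
        },
        index=list(patient_ids),
    )
    return df
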