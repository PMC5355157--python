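"""Shared helpers for the test suite: small simulated datasets and
independent reference implementations (oracles)."""

from __future__ import annotations

import numpy as np
import pandas as pd

import progsig as ps


def gene_matrix(n_genes, n_patients, seed=0, loc=8.0, scale=1.0, prefix="g"):
    """Plain iid-normal expression matrix with unlabeled samples."""
    rng = np.random.default_rng(seed)
    feats = [f"{prefix}{i:04d}" for i in range(n_genes)]
    pids = [f"P{i:04d}" for i in range(n_patients)]
    vals = rng.normal(loc, scale, (n_genes, n_patients))
    return ps.ExpressionMatrix(
        pd.DataFrame(vals, index=feats, columns=pids),
        pd.Series("unlabeled", index=pids),
    )


def planted_cohort(
    n_patients=393,
    n_genes=100,
    n_signature=12,
    beta_low=0.4,
    beta_high=0.7,
    censor_rate=0.3,
    data_seed=0,
    surv_seed=1,
):
    """Cohort with a planted signature: first ``n_signature`` genes carry
    alternating-sign betas evenly spaced in [beta_low, beta_high]."""
    mat = gene_matrix(n_genes, n_patients, seed=data_seed)
    genes = mat.feature_ids[:n_signature]
    mags = np.linspace(beta_low, beta_high, n_signature)
    betas = [m * (1 if i % 2 == 0 else -1) for i, m in enumerate(mags)]
    cohort = ps.simulate_survival(
        mat, genes, betas, censor_rate=censor_rate, seed=surv_seed
    )
    return mat, cohort, genes, betas


def bh_reference(p):
    """Brute-force Benjamini-Hochberg: sort, p*m/rank, reverse cummin."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(q_sorted, 0.0, 1.0)
    return out


def partial_loglik_1d(beta, x, time, event):
    """Independent 1-covariate Cox partial log-likelihood (no ties),
    written directly from the definition with explicit risk sets."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll
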