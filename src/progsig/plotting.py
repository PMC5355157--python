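"""Kaplan-Meier and forest-plot rendering (matplotlib)."""

from __future__ import annotations

import numpy as np

from .survival import KMCurve


def _steps(curve: KMCurve, tmax=None):
    t = np.concatenate([[0.0], curve.event_times])
    s = np.concatenate([[1.0], curve.survival])
    if tmax is not None and (len(t) == 0 or t[-1] < tmax):
        t = np.append(t, tmax)
        s = np.append(s, s[-1])
    return t, s


def plot_km(curves: dict[str, KMCurve], ax=None, title: str | None = None):
    """Overlay step-function survival curves, one per labelled group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    tmax = max(
        (c.event_times[-1] for c in curves.values() if len(c.event_times)), default=1.0
    )
    for label, curve in curves.items():
        t, s = _steps(curve, tmax)
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax


def plot_forest(forest_table, ax=None):
    """Per-test-set hazard ratios with 95% CIs on a log scale."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 8))
    rows = forest_table.rows[~forest_table.rows["flagged"]]
    y = np.arange(len(rows))
    crosses = (rows["ci_low"] <= 1) & (rows["ci_high"] >= 1)
    colors = np.where(crosses, "red", "black")
    for yi, (_, r), c in zip(y, rows.iterrows(), colors):
        ax.plot([r["ci_low"], r["ci_high"]], [yi, yi], color=c, lw=1)
        ax.plot(r["hr"], yi, "s", color=c, ms=3)
    ax.axvline(1.0, color="red", lw=1, ls="--")
    ax.set_xscale("log")
    ax.set_xlabel("hazard ratio (high vs low, 95% CI)")
    ax.set_ylabel("test set")
    return ax
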