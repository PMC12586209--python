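"""Plotting helpers: age trajectories and biomarker scatter panels."""

from __future__ import annotations

import numpy as np

_COLORS = {"Chinese": "#d62728", "Indian": "#1f77b4", "Malay": "#2ca02c"}


def plot_trajectories(fits, ax=None, title: str | None = None):
    """Overlay per-ethnicity LOWESS trajectories with their bands.

    ``fits`` is a list of :class:`~femfall.stats.TrajectoryFit` for one
    variable (typically one sex); returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for fit in fits:
        color = _COLORS.get(fit.ethnicity)
        label = fit.ethnicity or fit.variable
        ax.plot(fit.ages, fit.fitted, color=color, label=label)
        if fit.band_low is not None:
            ax.fill_between(fit.ages, fit.band_low, fit.band_high,
                            color=color, alpha=0.2, linewidth=0)
    ax.set_xlabel("age (years)")
    if fits:
        ax.set_ylabel(fits[0].variable)
    ax.set_title(title or "")
    ax.legend()
    return ax


def plot_strength_vs_frax(df, thresholds, sex: str, ax=None):
    """Scatter femoral strength against FRAX-HFP for one sex, with the
    at-risk threshold lines (FRAX vertical, fragility horizontal)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = df[df["sex"] == sex]
    for eth, grp in sub.groupby("ethnicity"):
        ax.scatter(grp["frax_hfp"], grp["strength"], s=6, alpha=0.5,
                   color=_COLORS.get(eth), label=eth)
    ax.axvline(thresholds.frax_at_risk, color="red")
    ax.axhline(thresholds.strength_threshold(sex), color="blue", linestyle="--")
    ax.set_xlabel("FRAX-HFP (%)")
    ax.set_ylabel("femoral strength (kN)")
    ax.set_title(sex)
    ax.legend(markerscale=2)
    return ax
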