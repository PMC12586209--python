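"""Cohort statistics: descriptives, ANOVA, age adjustment, LOWESS.

Implements the statistical toolkit of the cohort analysis: per-group
descriptive statistics and size-weighted pooling, one-way ANOVA across
ethnicities, ANCOVA-style age adjustment (single common slope, adjusted
means at the grand mean age), and LOWESS age trajectories with
bootstrap-percentile confidence bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class GroupSummary:
    labels: list
    n: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    pooled_mean: float
    pooled_sd: float


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int


@dataclass
class AncovaResult:
    adjusted_means: dict
    F: float
    p: float
    slope: float
    grand_mean_age: float


@dataclass
class TrajectoryFit:
    """LOWESS curve on an even age grid with a bootstrap band."""

    variable: str
    ages: np.ndarray
    fitted: np.ndarray
    band_low: np.ndarray | None
    band_high: np.ndarray | None
    frac: float
    sex: str | None = None
    ethnicity: str | None = None
    extra: dict = field(default_factory=dict)


def pooled_mean(groups) -> float:
    """Size-weighted mean of (n, mean) pairs: sum(n_i m_i) / sum(n_i)."""
    ns = np.array([g[0] for g in groups], dtype=float)
    ms = np.array([g[1] for g in groups], dtype=float)
    if np.any(ns < 0):
        raise ValueError("group sizes must be >= 0")
    total = ns.sum()
    if total <= 0:
        raise ValueError("pooled mean undefined for total n = 0")
    return float(ns @ ms / total)


def pooled_sd(groups) -> float:
    """Size-weighted SD of (n, mean, sd) triples (law of total variance,
    population convention)."""
    ns = np.array([g[0] for g in groups], dtype=float)
    ms = np.array([g[1] for g in groups], dtype=float)
    sds = np.array([g[2] for g in groups], dtype=float)
    total = ns.sum()
    if total <= 0:
        raise ValueError("pooled sd undefined for total n = 0")
    grand = ns @ ms / total
    var = (ns @ (sds**2) + ns @ (ms - grand) ** 2) / total
    return float(np.sqrt(var))


def summarize_groups(values_by_group: dict) -> GroupSummary:
    labels = list(values_by_group)
    arrs = [np.asarray(values_by_group[k], float) for k in labels]
    if any(len(a) < 1 for a in arrs):
        raise ValueError("each reported group needs n >= 1")
    n = np.array([len(a) for a in arrs])
    means = np.array([a.mean() for a in arrs])
    sds = np.array([a.std(ddof=1) if len(a) > 1 else 0.0 for a in arrs])
    allv = np.concatenate(arrs)
    return GroupSummary(labels, n, means, sds, float(allv.mean()),
                        float(allv.std(ddof=1)) if len(allv) > 1 else 0.0)


def anova_oneway(groups) -> AnovaResult:
    """Classical one-way ANOVA over a sequence of value arrays.

    F = MS_between / MS_within with (k-1, N-k) degrees of freedom; zero
    within-group variance with unequal means returns F = +inf, p = 0 by
    convention (and F = 0 when the means also coincide).
    """
    arrs = [np.asarray(g, float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise ValueError("one-way ANOVA needs >= 2 groups with n >= 2 each")
    N = sum(len(a) for a in arrs)
    k = len(arrs)
    grand = np.concatenate(arrs).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    dfb, dfw = k - 1, N - k
    if ssw <= 0:
        if ssb <= 1e-300:
            return AnovaResult(0.0, 1.0, dfb, dfw)
        return AnovaResult(float("inf"), 0.0, dfb, dfw)
    F = (ssb / dfb) / (ssw / dfw)
    return AnovaResult(float(F), float(sps.f.sf(F, dfb, dfw)), dfb, dfw)


def age_adjust(values, ages, groups) -> AncovaResult:
    """ANCOVA age adjustment: value ~ common age slope + group offsets.

    Adjusted group means are the fitted group levels evaluated at the
    grand mean age; the group effect is tested by the extra-sum-of-
    squares F conditional on age.  A constant age vector makes the slope
    unidentifiable; the function then falls back to plain one-way ANOVA
    on the raw means, with a warning.
    """
    y = np.asarray(values, float)
    a = np.asarray(ages, float)
    g = np.asarray(groups)
    if not (len(y) == len(a) == len(g)):
        raise ValueError("values, ages and groups must have equal length")
    labels = list(dict.fromkeys(g.tolist()))
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if np.ptp(a) == 0:
        warnings.warn("constant age vector: slope unidentifiable; "
                      "falling back to unadjusted one-way ANOVA")
        res = anova_oneway([y[g == lab] for lab in labels])
        means = {lab: float(y[g == lab].mean()) for lab in labels}
        return AncovaResult(means, res.F, res.p, 0.0, float(a.mean()))

    ind = np.column_stack([(g == lab).astype(float) for lab in labels])
    X_full = np.column_stack([ind, a])
    beta, _, _, _ = np.linalg.lstsq(X_full, y, rcond=None)
    resid = y - X_full @ beta
    ss_full = float(resid @ resid)
    slope = float(beta[-1])
    abar = float(a.mean())
    adjusted = {lab: float(beta[i] + slope * abar) for i, lab in enumerate(labels)}

    # reduced model: common intercept + age
    X_red = np.column_stack([np.ones_like(a), a])
    br, _, _, _ = np.linalg.lstsq(X_red, y, rcond=None)
    rr = y - X_red @ br
    ss_red = float(rr @ rr)
    dfb = len(labels) - 1
    dfw = len(y) - len(labels) - 1
    if dfw <= 0:
        raise ValueError("not enough observations for ANCOVA")
    num = max(ss_red - ss_full, 0.0) / dfb
    if ss_full <= 1e-12 * max(ss_red, 1.0):
        F, p = (float("inf"), 0.0) if num > 0 else (0.0, 1.0)
    else:
        F = num / (ss_full / dfw)
        p = float(sps.f.sf(F, dfb, dfw))
    return AncovaResult(adjusted, float(F), p, slope, abar)


def lowess_trajectory(ages, values, frac: float = 2.0 / 3.0, it: int = 1,
                      grid: np.ndarray | None = None, n_grid: int = 50,
                      n_boot: int = 199, conf: float = 0.95,
                      seed: int | None = None,
                      variable: str = "", sex: str | None = None,
                      ethnicity: str | None = None) -> TrajectoryFit:
    """LOWESS trend of ``values`` against ``ages`` on an even age grid.

    Locally weighted linear regression (statsmodels backend) with
    ``it`` robustness iterations; the confidence band is a seeded
    bootstrap percentile band over ``n_boot`` pair resamples
    (``n_boot=0`` disables it).
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    a = np.asarray(ages, float)
    y = np.asarray(values, float)
    if len(a) != len(y):
        raise ValueError("ages and values must have equal length")
    if len(a) < 10:
        raise ValueError("LOWESS trajectory needs n >= 10")
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    if np.ptp(a) == 0:
        raise ValueError("trajectory undefined: all ages identical")
    if grid is None:
        grid = np.linspace(a.min(), a.max(), n_grid)
    grid = np.asarray(grid, float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("age grid must be strictly increasing")

    fitted = lowess(y, a, frac=frac, it=it, xvals=grid, delta=0.0)
    band_low = band_high = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty((n_boot, len(grid)))
        n = len(a)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            ab = a[idx]
            if np.ptp(ab) == 0:      # degenerate resample: reuse point fit
                boot[b] = np.full(len(grid), y[idx].mean())
                continue
            boot[b] = lowess(y[idx], ab, frac=frac, it=it, xvals=grid, delta=0.0)
        alpha = (1 - conf) / 2
        band_low = np.nanquantile(boot, alpha, axis=0)
        band_high = np.nanquantile(boot, 1 - alpha, axis=0)
    return TrajectoryFit(variable, grid, np.asarray(fitted), band_low, band_high,
                         frac, sex, ethnicity)


def trajectories_by_group(df, variables, frac: float = 2.0 / 3.0,
                          n_boot: int = 0, seed: int | None = None) -> list:
    """Per-(sex, ethnicity) LOWESS trajectories for each variable."""
    fits = []
    for (sex, eth), sub in df.groupby(["sex", "ethnicity"], sort=True):
        for var in variables:
            vals = sub[var].to_numpy(float)
            ages = sub["age"].to_numpy(float)
            keep = np.isfinite(vals) & np.isfinite(ages)
            if keep.sum() < 10:
                continue
            fits.append(lowess_trajectory(ages[keep], vals[keep], frac=frac,
                                          n_boot=n_boot, seed=seed, variable=var,
                                          sex=sex, ethnicity=eth))
    return fits
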