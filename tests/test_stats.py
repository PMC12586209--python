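"""Descriptives, ANOVA, ANCOVA age adjustment, LOWESS trajectories."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import femfall as ff
from femfall.cohort import ETHNICITIES


class TestPooledMean:
    def test_published_male_strength_cells(self):
        """Size-weighted mean of the three ethnicity cells reproduces the
        pooled male femoral strength (4.99 kN) within input rounding."""
        got = ff.pooled_mean([(494, 4.56), (213, 5.89), (273, 5.05)])
        assert got == pytest.approx(4.99, abs=0.02)

    def test_hand_arithmetic(self):
        assert ff.pooled_mean([(1, 0.0), (1, 2.0)]) == 1.0

    def test_constant_groups(self):
        assert ff.pooled_mean([(10, 3.3), (5, 3.3), (7, 3.3)]) == pytest.approx(3.3)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            ff.pooled_mean([(0, 1.0), (0, 2.0)])


class TestAnova:
    def test_hand_computed_toy_case(self):
        """Groups [1,2,3] and [2,3,4]: SSB = 1.5, SSW = 4, F = 1.5 with
        df (1, 4)."""
        res = ff.anova_oneway([[1, 2, 3], [2, 3, 4]])
        assert res.F == pytest.approx(1.5, abs=1e-12)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_identical_groups_give_zero(self):
        res = ff.anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert res.F == 0.0

    def test_zero_within_variance_unequal_means(self):
        res = ff.anova_oneway([[1, 1, 1], [2, 2, 2]])
        assert res.F == float("inf") and res.p == 0.0

    def test_permutation_within_groups_invariant(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=6)
        r1 = ff.anova_oneway([a, b])
        r2 = ff.anova_oneway([rng.permutation(a), rng.permutation(b)])
        assert r1.F == pytest.approx(r2.F, rel=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_two_group_F_equals_t_squared(self, seed):
        g = np.random.default_rng(seed)
        a, b = g.normal(size=9), g.normal(1.0, 1.0, size=7)
        from scipy import stats as sps
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        res = ff.anova_oneway([a, b])
        assert res.F == pytest.approx(t**2, abs=1e-9)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(size=20), rng.normal(0.4, 1.2, 15), rng.normal(size=18)]
        from scipy import stats as sps
        F, p = sps.f_oneway(*groups)
        res = ff.anova_oneway(groups)
        assert res.F == pytest.approx(F, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)


class TestAgeAdjust:
    def test_no_age_effect_returns_raw_means(self, rng):
        ages = rng.uniform(60, 90, 120)
        groups = np.repeat(["a", "b", "c"], 40)
        values = np.where(groups == "a", 1.0, np.where(groups == "b", 2.0, 3.0)) \
            + rng.normal(0, 0.05, 120)
        res = ff.age_adjust(values, ages, groups)
        for lab, raw in (("a", 1.0), ("b", 2.0), ("c", 3.0)):
            assert res.adjusted_means[lab] == pytest.approx(raw, abs=0.05)

    def test_exact_linear_recovery(self):
        """value = 2*age + group offset, noiseless: offsets recovered
        exactly and the group F diverges."""
        ages = np.tile(np.linspace(60, 80, 10), 2)
        groups = np.repeat(["a", "b"], 10)
        offsets = {"a": 5.0, "b": -3.0}
        values = 2.0 * ages + np.array([offsets[g] for g in groups])
        res = ff.age_adjust(values, ages, groups)
        assert res.slope == pytest.approx(2.0, abs=1e-9)
        abar = ages.mean()
        assert res.adjusted_means["a"] - res.adjusted_means["b"] == pytest.approx(8.0, abs=1e-8)
        assert res.adjusted_means["a"] == pytest.approx(2.0 * abar + 5.0, abs=1e-8)
        assert res.F == float("inf") and res.p == 0.0

    def test_age_translation_invariance(self, rng):
        ages = rng.uniform(60, 90, 60)
        groups = np.repeat(["a", "b"], 30)
        values = -0.03 * ages + (groups == "b") * 0.4 + rng.normal(0, 0.1, 60)
        r1 = ff.age_adjust(values, ages, groups)
        r2 = ff.age_adjust(values, ages + 7.5, groups)
        for lab in ("a", "b"):
            assert r1.adjusted_means[lab] == pytest.approx(r2.adjusted_means[lab], abs=1e-9)
        assert r1.F == pytest.approx(r2.F, rel=1e-9)

    def test_balanced_design_returns_raw_means(self):
        """With ages identical across groups (orthogonal design), the
        adjusted means equal the raw group means exactly."""
        base = np.linspace(60, 80, 8)
        ages = np.tile(base, 2)
        groups = np.repeat(["a", "b"], 8)
        rng = np.random.default_rng(3)
        values = 0.5 * ages + (groups == "b") * 2.0 + rng.normal(0, 0.2, 16)
        res = ff.age_adjust(values, ages, groups)
        for lab in ("a", "b"):
            assert res.adjusted_means[lab] == pytest.approx(
                values[groups == lab].mean(), abs=1e-9)

    def test_constant_age_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="unidentifiable"):
            res = ff.age_adjust([1.0, 2.0, 3.0, 4.0], [70.0] * 4, ["a", "a", "b", "b"])
        assert res.slope == 0.0


class TestLowess:
    def test_constant_signal(self, rng):
        ages = rng.uniform(60, 90, 40)
        fit = ff.lowess_trajectory(ages, np.full(40, 2.5), n_boot=0)
        np.testing.assert_allclose(fit.fitted, 2.5, atol=1e-9)

    def test_linear_exactness_at_full_span(self, rng):
        """Local linear regression reproduces noiseless linear data."""
        ages = np.sort(rng.uniform(60, 90, 60))
        values = -0.03 * ages + 5.0
        fit = ff.lowess_trajectory(ages, values, frac=1.0, n_boot=0)
        np.testing.assert_allclose(fit.fitted, -0.03 * fit.ages + 5.0, atol=1e-6)

    def test_shuffle_invariance(self, rng):
        ages = rng.uniform(60, 90, 50)
        values = np.sin(ages / 5.0) + rng.normal(0, 0.1, 50)
        grid = np.linspace(62, 88, 20)
        f1 = ff.lowess_trajectory(ages, values, grid=grid, n_boot=0)
        perm = rng.permutation(50)
        f2 = ff.lowess_trajectory(ages[perm], values[perm], grid=grid, n_boot=0)
        np.testing.assert_allclose(f1.fitted, f2.fitted, atol=1e-9)

    def test_bootstrap_band_reproducible_and_widens_with_noise(self, rng):
        ages = rng.uniform(60, 90, 80)
        clean = -0.02 * ages + 4.0
        grid = np.linspace(65, 85, 15)
        kw = dict(grid=grid, n_boot=60, seed=42)
        lo_n, hi_n = [], []
        for scale in (0.05, 0.5):
            values = clean + np.random.default_rng(1).normal(0, scale, 80)
            f1 = ff.lowess_trajectory(ages, values, **kw)
            f2 = ff.lowess_trajectory(ages, values, **kw)
            np.testing.assert_array_equal(f1.band_low, f2.band_low)
            lo_n.append(np.mean(f1.band_high - f1.band_low))
        assert lo_n[1] > lo_n[0]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            ff.lowess_trajectory([70.0] * 12, np.arange(12.0), n_boot=0)
        with pytest.raises(ValueError, match="n >= 10"):
            ff.lowess_trajectory([60, 70, 80], [1, 2, 3], n_boot=0)


def test_trajectory_ethnic_ordering(table_params):
    """On a Table 1-calibrated cohort with the configured age trends,
    the Chinese trajectory stays below Indian/Malay for aBMD, supine
    TSTT and strength, and above for FRAX, at every grid age (a small
    tolerance absorbs cells whose published means nearly tie)."""
    records = ff.generate_cohort(table_params, n_override=300, seed=104)
    df = ff.cohort_to_frame(records)
    grid = np.linspace(65, 85, 9)
    for sex in ("male", "female"):
        sub = df[df.sex == sex]
        for var, chinese_low in (("abmd", True), ("tstt_sup", True),
                                 ("strength", True), ("frax_hfp", False)):
            fits = {}
            for eth in ETHNICITIES:
                cell = sub[sub.ethnicity == eth]
                fits[eth] = ff.lowess_trajectory(
                    cell.age.to_numpy(), cell[var].to_numpy(),
                    grid=grid, n_boot=0).fitted
            tol = 0.1 * sub[var].std()
            for other in ("Indian", "Malay"):
                if chinese_low:
                    assert np.all(fits["Chinese"] <= fits[other] + tol), (sex, var, other)
                else:
                    assert np.all(fits["Chinese"] >= fits[other] - tol), (sex, var, other)


def test_pooled_sd_and_summary(rng):
    a, b = rng.normal(0, 1, 300), rng.normal(2, 1, 300)
    summ = ff.summarize_groups({"a": a, "b": b})
    pooled = ff.pooled_sd([(300, a.mean(), a.std()), (300, b.mean(), b.std())])
    # law of total variance vs direct pooled SD (population convention)
    assert pooled == pytest.approx(np.concatenate([a, b]).std(), rel=1e-9)
    assert summ.pooled_mean == pytest.approx(np.concatenate([a, b]).mean())
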