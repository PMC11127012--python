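"""Bloom detection exactness, metric invariances, and timing-trend fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baybloom import (
    DLMSpec,
    SeasonWindows,
    bloom_threshold,
    detect_blooms,
    phenology_table,
    phenology_over_ensemble,
    poisson_glm,
    seasonal_metrics,
    trend_rate_days_per_decade,
)
from baybloom.core import WEEKS_PER_YEAR, WeekIndex
from baybloom.dlm import ImputationEnsemble


def year_with_pulses(baseline=1.0, pulses=()):
    """52-week year: flat baseline with rectangular pulses (start, end, level)."""
    v = np.full(WEEKS_PER_YEAR, baseline)
    for a, b, level in pulses:
        v[a - 1 : b] = level
    return v


class TestThreshold:
    def test_constant_year(self):
        v = np.full(52, 3.0)
        thr = bloom_threshold(v)
        assert thr == pytest.approx(1.05 * 3.0)
        assert not (v > thr).any()

    def test_weeks_one_to_fiftytwo(self):
        thr = bloom_threshold(np.arange(1.0, 53.0))
        assert thr == pytest.approx(27.825)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.5, 8, 52)
        assert bloom_threshold(v) == bloom_threshold(v[::-1])

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError, match="26"):
            bloom_threshold(np.ones(10))

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="all-missing"):
            bloom_threshold(np.full(52, np.nan))


class TestDetectBlooms:
    def test_constant_year_has_no_blooms(self):
        assert detect_blooms(np.full(52, 2.0), 1980) == []

    def test_single_rectangular_pulse(self):
        v = year_with_pulses(1.0, [(10, 14, 10.0)])
        events = detect_blooms(v, 1980)
        assert len(events) == 1
        e = events[0]
        assert (e.start_week, e.end_week, e.duration_weeks) == (10, 14, 5)
        assert e.peak_week == 10  # tie resolves to the earliest week
        assert e.season == "winter-spring"

    def test_two_pulses_labeled_by_season(self):
        v = year_with_pulses(1.0, [(5, 7, 8.0), (30, 33, 6.0)])
        events = detect_blooms(v, 1980)
        assert [e.season for e in events] == ["winter-spring", "summer-fall"]
        rec = seasonal_metrics(events, 1980)
        assert rec["n_blooms_annual"] == 2
        assert rec["winter_spring_count"] == 1
        assert rec["summer_fall_count"] == 1

    def test_event_outside_windows_labeled_other(self):
        v = year_with_pulses(1.0, [(18, 20, 9.0)])
        events = detect_blooms(v, 1980)
        assert events[0].season == "other"
        rec = seasonal_metrics(events, 1980)
        assert rec["n_blooms_annual"] == 1
        assert rec["winter_spring_count"] == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_bloom_weeks_are_exactly_weeks_above_threshold(self, seed):
        """Events partition the above-threshold weeks into maximal runs."""
        rng = np.random.default_rng(seed)
        v = np.exp(rng.normal(0.5, 0.8, 52))
        events = detect_blooms(v, 2000)
        thr = bloom_threshold(v)
        above = set(np.flatnonzero(v > thr) + 1)
        covered = set()
        for e in events:
            weeks = set(range(e.start_week, e.end_week + 1))
            assert not (weeks & covered)  # disjoint
            covered |= weeks
            # maximal: neighbors outside the run are not above threshold
            assert e.start_week == 1 or v[e.start_week - 2] <= thr
            assert e.end_week == 52 or v[e.end_week] <= thr
        assert covered == above

    @given(st.floats(0.01, 1000.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(11)
        v = np.exp(rng.normal(0.5, 0.8, 52))
        base = [
            (e.start_week, e.end_week, e.peak_week) for e in detect_blooms(v, 2000)
        ]
        scaled = [
            (e.start_week, e.end_week, e.peak_week)
            for e in detect_blooms(c * v, 2000)
        ]
        assert base == scaled


class TestSeasonalMetrics:
    def test_single_winter_pulse(self):
        v = year_with_pulses(1.0, [(6, 9, 5.0)])
        v[7] = 6.0  # peak at week 8
        rec = seasonal_metrics(detect_blooms(v, 1990), 1990)
        assert rec["winter_spring_start"] == 6
        assert rec["winter_spring_peak"] == 8
        assert rec["winter_spring_duration"] == 4

    def test_empty_window_fields_absent(self):
        v = year_with_pulses(1.0, [(6, 9, 5.0)])
        rec = seasonal_metrics(detect_blooms(v, 1990), 1990)
        assert rec["summer_fall_count"] == 0
        assert np.isnan(rec["summer_fall_start"])

    def test_cyclic_shift_moves_weeks(self):
        v = year_with_pulses(1.0, [(6, 9, 5.0)])
        shifted = np.roll(v, 3)
        e0 = detect_blooms(v, 1990)[0]
        e3 = detect_blooms(shifted, 1990)[0]
        assert (e3.start_week, e3.end_week) == (e0.start_week + 3, e0.end_week + 3)


class TestEnsemblePhenology:
    def _ensemble(self, members):
        return ImputationEnsemble(
            name="chl", members=members,
            mask=np.ones(members.shape[1], bool),
            start=WeekIndex(1990, 1), seed=0, spec=DLMSpec(),
        )

    def test_identical_members_zero_sd(self):
        year = year_with_pulses(1.0, [(5, 8, 6.0), (30, 34, 4.0)])
        series = np.tile(year, 3)
        members = np.tile(series, (4, 1))
        _, summary = phenology_over_ensemble(self._ensemble(members))
        sd_cols = [c for c in summary.columns if c.endswith("_sd")]
        assert np.nanmax(summary[sd_cols].to_numpy()) == 0.0

    def test_masked_panel_phenology_matches_unmasked_truth(self, small_panel):
        """Imputation-based start weeks track the complete-data phenology."""
        from baybloom import impute_panel

        masked, full, truth = small_panel
        ens, _ = impute_panel(masked, M=20, seed=3)
        years, _ = full["chl"].week_grid()
        full_tab = phenology_table(truth.chl_full, years)
        _, summary = phenology_over_ensemble(ens)
        d = np.abs(summary["winter_spring_start_median"].to_numpy()
                   - full_tab["winter_spring_start"].to_numpy())
        d = d[np.isfinite(d)]
        assert (d <= 1.0).mean() >= 0.9

    def test_drifting_peak_gives_negative_start_trend(self):
        """Bump centers drifting earlier should surface as a negative trend
        in winter-spring start week."""
        from baybloom import SynthConfig, generate_panel

        cfg = SynthConfig(n_years=40, seed=13, bump_drift_per_year=-0.07,
                          noise_sd=0.3)
        panel, _ = generate_panel(cfg)
        years, _ = panel["chl"].week_grid()
        tab = phenology_table(panel["chl"].values, years)
        rate, se = trend_rate_days_per_decade(
            tab.index.to_numpy(), tab["winter_spring_start"].to_numpy()
        )
        assert rate < 0


class TestPoissonGLM:
    def test_matches_direct_likelihood_maximization(self):
        """IRLS estimates equal a scipy-optimized Poisson log-likelihood."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(1)
        n = 30
        x = rng.normal(0, 1, n)
        lam = np.exp(1.0 + 0.5 * x)
        y = rng.poisson(lam)
        tab = poisson_glm(y, pd.DataFrame({"x": x}))

        X = np.column_stack([np.ones(n), x])

        def nll(b):
            eta = X @ b
            return -(y @ eta - np.exp(eta).sum())

        opt = minimize(nll, np.zeros(2), method="BFGS", tol=1e-12)
        assert np.abs(tab["coef"].to_numpy() - opt.x).max() < 1e-6

    def test_year_slope_recovery(self):
        """Simulated log-linear decline in week numbers is recovered."""
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            years = np.arange(1970, 2020)
            lam = np.exp(2.0 - 0.01 * (years - 1970))
            y = rng.poisson(lam)
            tab = poisson_glm(y, pd.DataFrame({"year": years - 1970}))
            ok += abs(tab.loc["year", "coef"] + 0.01) <= 2 * tab.loc["year", "se"]
        assert ok >= 18

    def test_constant_response_null_slope(self):
        years = np.arange(1970, 2000)
        tab = poisson_glm(np.full(30, 7), pd.DataFrame({"year": years}))
        assert abs(tab.loc["year", "z"]) < 2

    def test_non_integer_response_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            poisson_glm(np.array([1.5, 2.0, 3.0, 4.0, 5.0, 6.0]),
                        pd.DataFrame({"x": np.arange(6.0)}))


class TestTrendRate:
    def test_unit_conversion_identity(self):
        years = np.arange(1970, 2020)
        weeks = 10.0 - 0.07 * (years - 1970)
        rate, se = trend_rate_days_per_decade(years, weeks)
        assert rate == pytest.approx(-4.9, abs=1e-9)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_constant_weeks_zero_rate(self):
        years = np.arange(1970, 1990)
        rate, _ = trend_rate_days_per_decade(years, np.full(20, 8.0))
        assert rate == pytest.approx(0.0, abs=1e-12)

    def test_requires_ten_years(self):
        with pytest.raises(ValueError, match="10"):
            trend_rate_days_per_decade(np.arange(5), np.arange(5.0))
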