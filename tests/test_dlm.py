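"""DLM filter/smoother/FFBS against independent Gaussian-conditioning oracles."""

import warnings

import numpy as np
import pytest

from baybloom import (
    DLMSpec,
    SynthConfig,
    decompose,
    ffbs_sample,
    generate_panel,
    impute_panel,
    kalman_filter,
    kalman_smooth,
)
from baybloom.core import WEEKS_PER_YEAR, WeekIndex, WeeklySeries
from baybloom.synth import MissingnessConfig, apply_missingness

from conftest import make_series


def brute_force_smoothed_means(spec: DLMSpec, series: WeeklySeries) -> np.ndarray:
    """Joint-Gaussian conditioning of all states on all observations.

    Builds the full T*d-dimensional prior of the state path implied by the
    evolution equation and conditions on the observed y values — an oracle
    completely independent of the Kalman recursions (known-variance specs).
    """
    F, G = spec.matrices()
    d = spec.dim
    T = len(series)
    m0, C0 = spec.priors(series)
    W = spec.state_cov
    V = spec.obs_variance
    means = []
    m = m0
    for _ in range(T):
        m = G @ m
        means.append(m)
    mean = np.concatenate(means)
    P = []
    prev = C0
    for _ in range(T):
        prev = G @ prev @ G.T + W
        P.append(prev)
    cov = np.zeros((T * d, T * d))
    for s in range(T):
        cov[s * d:(s + 1) * d, s * d:(s + 1) * d] = P[s]
        acc = P[s]
        for t in range(s + 1, T):
            acc = acc @ G.T
            cov[s * d:(s + 1) * d, t * d:(t + 1) * d] = acc
            cov[t * d:(t + 1) * d, s * d:(s + 1) * d] = acc.T
    obs = np.flatnonzero(series.mask)
    H = np.zeros((len(obs), T * d))
    for r, t in enumerate(obs):
        H[r, t * d:(t + 1) * d] = F
    y = series.values[obs]
    S = H @ cov @ H.T + V * np.eye(len(obs))
    K = cov @ H.T @ np.linalg.inv(S)
    return (mean + K @ (y - H @ mean)).reshape(T, d)


def local_level_spec(V=0.5, W=0.1, C0=4.0):
    return DLMSpec(
        trend="level", harmonics=0, obs_variance=V,
        state_cov=np.array([[W]]), prior_mean=np.zeros(1),
        prior_cov=np.array([[C0]]), transform="raw",
    )


TOY_SPECS = [
    local_level_spec(),
    DLMSpec(trend="local-linear", harmonics=0, obs_variance=0.3,
            state_cov=np.diag([0.1, 0.01]), prior_cov=np.eye(2) * 4,
            transform="raw"),
    DLMSpec(trend="local-linear", harmonics=1, period=4, obs_variance=0.5,
            state_cov=np.diag([0.1, 0.01, 0.05, 0.05]),
            prior_cov=np.eye(4) * 4, transform="raw"),
]


class TestFilterAgainstOracles:
    def test_single_observation_diffuse_prior_returns_observation(self):
        spec = DLMSpec(trend="level", harmonics=0, obs_variance=1.0,
                       state_cov=np.array([[0.1]]), transform="raw")
        mom = kalman_filter(spec, make_series([7.3]))
        assert mom.filtered_means[0, 0] == pytest.approx(7.3, abs=1e-4)

    def test_five_point_local_level_matches_hand_recursion(self):
        y = np.array([1.0, 2.0, 1.5, 3.0, 2.5])
        V, W, C0 = 0.5, 0.1, 4.0
        # independent scalar Kalman recursion
        m, C = 0.0, C0
        expect = []
        for yt in y:
            R = C + W
            q = R + V
            K = R / q
            m = m + K * (yt - m)
            C = R * (1 - K)
            expect.append(m)
        mom = kalman_filter(local_level_spec(V, W, C0), make_series(y))
        assert np.allclose(mom.filtered_means[:, 0], expect, atol=1e-10)

    def test_constant_series_forecasts_converge(self):
        spec = DLMSpec(trend="level", harmonics=0, discount_trend=1.0,
                       obs_variance=0.1, state_cov=np.array([[0.0]]),
                       prior_cov=np.array([[100.0]]), transform="raw")
        mom = kalman_filter(spec, make_series(np.full(60, 4.2)))
        assert mom.forecast_means[-1] == pytest.approx(4.2, abs=1e-3)

    @pytest.mark.parametrize("spec", TOY_SPECS)
    @pytest.mark.parametrize("missing", [(), (3,), (2, 6)])
    def test_smoother_equals_joint_gaussian_conditioning(self, spec, missing):
        rng = np.random.default_rng(17)
        n = 9
        vals = rng.normal(1.0, 1.0, n)
        mask = np.ones(n, bool)
        mask[list(missing)] = False
        vals[~mask] = np.nan
        s = make_series(vals, mask=mask)
        mom = kalman_smooth(spec, kalman_filter(spec, s))
        oracle = brute_force_smoothed_means(spec, s)
        assert np.abs(mom.smoothed_means - oracle).max() < 1e-8

    def test_last_smoothed_equals_last_filtered(self):
        s = make_series(np.random.default_rng(3).normal(0, 1, 12))
        spec = TOY_SPECS[1]
        mom = kalman_smooth(spec, kalman_filter(spec, s))
        assert np.allclose(mom.smoothed_means[-1], mom.filtered_means[-1])

    def test_interior_gap_smoothed_between_neighbors(self):
        vals = np.array([1.0, 1.2, np.nan, 1.8, 2.0])
        mask = np.isfinite(vals)
        mom = kalman_smooth(
            local_level_spec(0.05, 0.1),
            kalman_filter(local_level_spec(0.05, 0.1), make_series(vals, mask)),
        )
        lvl = mom.smoothed_means[:, 0]
        assert min(lvl[1], lvl[3]) <= lvl[2] <= max(lvl[1], lvl[3])

    def test_all_missing_errors(self):
        with pytest.raises(ValueError, match="all-missing"):
            kalman_filter(TOY_SPECS[0], make_series([np.nan, np.nan],
                                                    mask=[False, False]))

    def test_loglik_invariant_to_time_relabeling(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, 30)
        spec = DLMSpec(harmonics=2, period=6)
        l1 = kalman_filter(spec, make_series(vals, year=1970)).loglik
        l2 = kalman_filter(spec, make_series(vals, year=2005)).loglik
        assert l1 == pytest.approx(l2, abs=1e-12)

    def test_observation_never_increases_filtered_variance(self):
        """Conditioning on a data point cannot inflate posterior variance."""
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, 20)
        spec = local_level_spec()
        full = kalman_filter(spec, make_series(vals))
        gapped_vals = vals.copy()
        mask = np.ones(20, bool)
        mask[10] = False
        gapped_vals[10] = np.nan
        gap = kalman_filter(spec, make_series(gapped_vals, mask=mask))
        assert full.filtered_covs[10, 0, 0] <= gap.filtered_covs[10, 0, 0] + 1e-12


class TestFFBS:
    def _gappy_series(self, n=60, seed=2):
        rng = np.random.default_rng(seed)
        vals = rng.normal(2.0, 0.7, n)
        mask = rng.random(n) > 0.25
        vals[~mask] = np.nan
        return make_series(vals, mask=mask)

    def test_observed_weeks_emitted_verbatim(self):
        s = self._gappy_series()
        spec = DLMSpec(harmonics=1, period=12)
        ens = ffbs_sample(spec, s, M=20, seed=0)
        assert np.array_equal(
            ens.members[:, s.mask],
            np.broadcast_to(s.values[s.mask], (20, s.mask.sum())),
        )

    def test_same_seed_reproducible(self):
        s = self._gappy_series()
        spec = DLMSpec(harmonics=1, period=12)
        e1 = ffbs_sample(spec, s, M=5, seed=9)
        e2 = ffbs_sample(spec, s, M=5, seed=9)
        assert np.array_equal(e1.members, e2.members)

    def test_ensemble_mean_matches_smoother(self):
        """FFBS posterior-predictive mean converges to the smoothed mean."""
        s = self._gappy_series(n=80, seed=4)
        spec = DLMSpec(harmonics=1, period=12)
        ens = ffbs_sample(spec, s, M=1000, seed=1)
        mom = kalman_smooth(spec, kalman_filter(spec, s))
        mean, _ = mom.smoothed_observation()
        miss = ~s.mask
        mc_se = ens.members[:, miss].std(axis=0) / np.sqrt(ens.m)
        diff = np.abs(ens.members[:, miss].mean(axis=0) - mean[miss])
        assert (diff <= 3 * mc_se).mean() >= 0.99

    def test_ensemble_variance_tracks_smoother_predictive_variance(self):
        s = self._gappy_series(n=80, seed=4)
        spec = DLMSpec(harmonics=1, period=12)
        ens = ffbs_sample(spec, s, M=1000, seed=3)
        mom = kalman_smooth(spec, kalman_filter(spec, s))
        _, var = mom.smoothed_observation()
        miss = ~s.mask
        ratio = ens.members[:, miss].var(axis=0) / var[miss]
        assert 0.7 < np.median(ratio) < 1.4

    def test_m_must_be_positive(self):
        with pytest.raises(ValueError, match="M"):
            ffbs_sample(DLMSpec(), self._gappy_series(), M=0)


class TestDecompose:
    def test_pure_sinusoid_lands_in_seasonal_component(self):
        t = np.arange(5 * WEEKS_PER_YEAR)
        y = 2.0 + np.sin(2 * np.pi * t / WEEKS_PER_YEAR)
        spec = DLMSpec(harmonics=2, discount_trend=0.999, transform="raw")
        trend, seasonal, _ = decompose(spec, make_series(y))
        assert np.var(seasonal) / np.var(y - y.mean()) > 0.99
        assert np.var(trend) < 0.01 * np.var(y)

    def test_linear_ramp_lands_in_trend_component(self):
        t = np.arange(3 * WEEKS_PER_YEAR)
        y = 1.0 + 0.01 * t
        spec = DLMSpec(harmonics=2, transform="raw")
        trend, seasonal, annual = decompose(spec, make_series(y))
        # seasonal picks up only a small start-up transient, no cycle
        assert np.var(seasonal) < 0.01 * np.var(y)
        assert np.corrcoef(trend, y)[0, 1] > 0.99
        assert set(annual) == {2000, 2001, 2002}

    def test_recovers_generator_trend(self, small_panel):
        """A stiff trend block tracks the generator's long-term decline."""
        masked, full, truth = small_panel
        logc = make_series(np.log(full["chl"].values), name="logchl", year=1970)
        spec = DLMSpec(discount_trend=0.999, transform="raw")
        trend, _, _ = decompose(spec, logc)
        assert np.corrcoef(trend, truth.trend_component)[0, 1] > 0.9


class TestImputePanel:
    def test_complete_panel_passes_through(self, small_panel):
        _, full, _ = small_panel
        ens, completed = impute_panel(full, M=3, seed=0)
        assert np.array_equal(ens.members[0], full["chl"].values)
        assert np.array_equal(ens.members[2], full["chl"].values)
        for name in full.names:
            assert np.array_equal(completed[name].values, full[name].values)

    def test_driver_mean_imputation_beats_marginal_sd(self, small_panel):
        masked, full, _ = small_panel
        _, completed = impute_panel(masked, M=2, seed=0)
        miss = ~masked["temp"].mask
        err = completed["temp"].values[miss] - full["temp"].values[miss]
        rmse = np.sqrt((err**2).mean())
        assert rmse < full["temp"].values.std()

    def test_sparse_variable_warns(self):
        rng = np.random.default_rng(0)
        n = 3 * WEEKS_PER_YEAR
        chl = WeeklySeries("chl", rng.uniform(1, 5, n), np.ones(n, bool),
                           WeekIndex(2000, 1))
        vals = rng.normal(10, 1, n)
        mask = np.zeros(n, bool)
        mask[:50] = True
        vals[~mask] = np.nan
        temp = WeeklySeries("temp", vals, mask, WeekIndex(2000, 1))
        from baybloom.core import EnvironmentalPanel

        panel = EnvironmentalPanel({"chl": chl, "temp": temp})
        with pytest.warns(UserWarning, match="observed weeks"):
            impute_panel(panel, M=2, seed=0)
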