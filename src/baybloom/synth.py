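"""Seeded generator of weekly estuarine panels with known ground truth.

The generator emulates the statistical structure of a long, weekly,
temperate-estuary monitoring record: a bimodal chlorophyll seasonal cycle
(winter-spring and summer-fall peaks), a multiplicative long-term decline,
nutrient cycles anti-phased with chlorophyll and themselves declining,
warming water temperature, and realistic missingness (isolated gaps,
biweekly-sampling stretches, and multi-year block gaps).

Chlorophyll is generated on the log scale:

    log chl_t = mu + trend * t + seasonal(week_t) + sum_i beta_i z_{i,t-l_i} + e_t

where z are standardized driver anomalies, l_i are weekly lags, and e_t is
AR(1) noise.  Drivers are generated first and chlorophyll depends on them, so
the causal direction is known and usable for Granger power checks.  The
deterministic part and the true coefficients are returned as ground truth for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    WEEKS_PER_YEAR,
    EnvironmentalPanel,
    WeekIndex,
    WeeklySeries,
)


def _circular_bump(weeks: np.ndarray, center: float, width: float, height: float) -> np.ndarray:
    """Gaussian bump in week-of-year with wrap-around distance."""
    d = np.abs(weeks - center)
    d = np.minimum(d, WEEKS_PER_YEAR - d)
    return height * np.exp(-0.5 * (d / width) ** 2)


@dataclass
class DriverConfig:
    """One environmental driver: baseline + sinusoidal season + trend + AR(1) noise."""

    baseline: float
    seasonal_amp: float = 0.0
    seasonal_peak_week: float = 26.0
    trend_per_year: float = 0.0
    ar1: float = 0.5
    noise_sd: float = 0.5
    log_scale: bool = False  # generate exp(path): positive, anti-phase via negative amp
    unit: str = ""


@dataclass
class MissingnessConfig:
    """Observation pattern: isolated point gaps, early biweekly sampling, and
    the multi-year block gaps characteristic of the monitoring record."""

    point_rate: float = 0.10
    biweekly_spans: tuple[tuple[int, int], ...] = ((1970, 1972),)
    block_gaps: tuple[tuple[int, int], ...] = ((1995, 1998), (2012, 2012))
    variables: tuple[str, ...] | None = None  # None = all series

    def __post_init__(self) -> None:
        if not 0.0 <= self.point_rate <= 1.0:
            raise ValueError("point_rate must be in [0, 1]")


@dataclass
class SynthConfig:
    """Study conditions for the synthetic panel.

    Defaults give a 50-year weekly record whose summary statistics sit in the
    range typical of a seasonal temperate estuary: annual chlorophyll CV near
    80-90%, a ~50% decline in cumulative chlorophyll between the first and
    last decade, bloom climatology peaks near weeks 8 and 32.
    """

    n_years: int = 50
    start_year: int = 1970
    chl_log_mean: float = 0.7           # log mg chl m^-3
    bump_centers: tuple[float, float] = (8.0, 32.0)
    bump_widths: tuple[float, float] = (3.5, 4.5)
    bump_heights: tuple[float, float] = (1.2, 0.9)
    chl_trend_per_year: float = -0.018  # log scale
    bump_drift_per_year: float = 0.0    # weeks/yr shift of both bump centers
    ar1_coefficient: float = 0.5
    noise_sd: float = 0.55              # AR(1) innovation SD (log scale)
    # (variable, lag weeks, coefficient on the standardized driver anomaly)
    exog_effects: tuple[tuple[str, int, float], ...] = (
        ("no32", 0, -0.20),
        ("no32", 1, -0.30),
        ("temp", 0, -0.05),
    )
    temp_warming_per_year: float = 0.03
    drivers: dict[str, DriverConfig] = field(default_factory=lambda: _default_drivers())
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not -1 < self.ar1_coefficient < 1:
            raise ValueError("ar1_coefficient must be in (-1, 1)")
        for name, cfg in self.drivers.items():
            if cfg.noise_sd < 0:
                raise ValueError(f"driver {name}: noise_sd must be >= 0")


def _default_drivers() -> dict[str, DriverConfig]:
    # Nutrients: log scale, anti-phased with the winter-spring bloom (their
    # seasonal peak sits in late fall / winter), declining slowly.
    return {
        "temp": DriverConfig(11.0, 9.0, 32.0, 0.0, 0.6, 1.0, unit="degC"),
        "salinity": DriverConfig(31.0, 0.8, 40.0, 0.0, 0.5, 0.5, unit="PSU"),
        "secchi": DriverConfig(1.1, -0.15, 8.0, 0.0, 0.4, 0.25, log_scale=True, unit="m"),
        "light": DriverConfig(5.5, 0.6, 26.0, -0.002, 0.3, 0.3, log_scale=True,
                              unit="mol photons m-2 d-1"),
        "precip": DriverConfig(0.7, 0.1, 40.0, 0.0, 0.1, 0.8, log_scale=True, unit="cm"),
        "strat": DriverConfig(1.5, 1.0, 30.0, -0.005, 0.5, 0.6, unit="kg m-3"),
        "no32": DriverConfig(1.0, -0.7, 8.0, -0.008, 0.6, 0.45, log_scale=True, unit="uM"),
        "nh4": DriverConfig(0.8, -0.5, 8.0, -0.006, 0.6, 0.45, log_scale=True, unit="uM"),
        "po4": DriverConfig(0.0, -0.4, 8.0, -0.004, 0.6, 0.4, log_scale=True, unit="uM"),
        "sio4": DriverConfig(1.5, -0.6, 8.0, 0.0, 0.6, 0.45, log_scale=True, unit="uM"),
    }


@dataclass
class SynthTruth:
    """Ground truth for recovery tests, on the same grid as the panel."""

    latent_log_chl: np.ndarray        # deterministic part (no AR noise)
    trend_component: np.ndarray       # mu + trend*t (log scale)
    seasonal_component: np.ndarray    # bimodal seasonal (log scale)
    exog_component: np.ndarray        # sum of driver effects (log scale)
    exog_coefficients: dict[tuple[str, int], float]
    chl_full: np.ndarray              # complete noisy chlorophyll, raw scale
    drivers_full: dict[str, np.ndarray]
    start: WeekIndex


def _ar1_path(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    e = rng.normal(0.0, sd, n)
    x = np.empty(n)
    marg = sd / np.sqrt(1 - phi**2) if abs(phi) < 1 else sd
    x[0] = rng.normal(0.0, marg)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


def generate_panel(config: SynthConfig) -> tuple[EnvironmentalPanel, SynthTruth]:
    """Generate a complete (unmasked) panel plus its ground truth.

    Deterministic given ``config.seed``.  Use :func:`apply_missingness` to
    impose the observation pattern afterwards.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_years * WEEKS_PER_YEAR
    start = WeekIndex(config.start_year, 1)
    t_years = np.arange(n) / WEEKS_PER_YEAR
    weeks = np.arange(n) % WEEKS_PER_YEAR + 1

    # drivers first (chlorophyll depends on them)
    driver_paths: dict[str, np.ndarray] = {}
    driver_anom: dict[str, np.ndarray] = {}
    for name, d in config.drivers.items():
        seas = d.seasonal_amp * np.cos(2 * np.pi * (weeks - d.seasonal_peak_week) / WEEKS_PER_YEAR)
        trend = d.trend_per_year * t_years
        if name == "temp":
            trend = trend + config.temp_warming_per_year * t_years
        noise = _ar1_path(rng, n, d.ar1, d.noise_sd)
        path = d.baseline + seas + trend + noise
        if d.log_scale:
            path = np.exp(path)
        driver_paths[name] = path
        sd = path.std()
        driver_anom[name] = (path - path.mean()) / (sd if sd > 0 else 1.0)

    trend_comp = config.chl_log_mean + config.chl_trend_per_year * t_years
    seasonal = np.zeros(n)
    for c, w, h in zip(config.bump_centers, config.bump_widths, config.bump_heights):
        centers = c + config.bump_drift_per_year * t_years
        seasonal += _circular_bump(weeks.astype(float) - (centers - c), c, w, h)
    seasonal -= seasonal.mean()

    exog_comp = np.zeros(n)
    coefs: dict[tuple[str, int], float] = {}
    for name, lag, beta in config.exog_effects:
        if name not in driver_anom:
            raise ValueError(f"exog effect references unknown driver {name!r}")
        z = driver_anom[name]
        shifted = np.concatenate([np.repeat(z[0], lag), z[: n - lag]]) if lag else z
        exog_comp += beta * shifted
        coefs[(name, lag)] = beta

    latent = trend_comp + seasonal + exog_comp
    noise = _ar1_path(rng, n, config.ar1_coefficient, config.noise_sd)
    chl = np.exp(latent + noise)

    series = {
        "chl": WeeklySeries("chl", chl, np.ones(n, bool), start, unit="mg chl m-3"),
    }
    for name, path in driver_paths.items():
        series[name] = WeeklySeries(
            name, path, np.ones(n, bool), start, unit=config.drivers[name].unit
        )
    # annual Gulf Stream Index: smooth AR(1) climate covariate
    years = np.arange(config.start_year, config.start_year + config.n_years)
    gsi = _ar1_path(rng, len(years), 0.6, 0.8)
    panel = EnvironmentalPanel(series, {"gsi": dict(zip(years.tolist(), gsi.tolist()))})

    truth = SynthTruth(
        latent_log_chl=latent,
        trend_component=trend_comp,
        seasonal_component=seasonal,
        exog_component=exog_comp,
        exog_coefficients=coefs,
        chl_full=chl.copy(),
        drivers_full={k: v.copy() for k, v in driver_paths.items()},
        start=start,
    )
    return panel, truth


def apply_missingness(
    panel: EnvironmentalPanel,
    config: SynthConfig | MissingnessConfig,
    seed: int | None = None,
) -> EnvironmentalPanel:
    """Mask the panel per the configured observation pattern.

    Point gaps are i.i.d. Bernoulli; biweekly spans mask every second week;
    block gaps mask whole calendar years.  Observed values are untouched.
    """
    if isinstance(config, SynthConfig):
        miss = config.missingness
        if seed is None:
            seed = config.seed + 1
    else:
        miss = config
        if seed is None:
            seed = 0
    rng = np.random.default_rng(seed)

    ref = next(iter(panel.series.values()))
    years, weeks = ref.week_grid()
    span = (int(years.min()), int(years.max()))
    for a, b in tuple(miss.biweekly_spans) + tuple(miss.block_gaps):
        if a < span[0] or b > span[1]:
            raise ValueError(f"gap span {a}-{b} outside panel years {span[0]}-{span[1]}")

    targets = miss.variables if miss.variables is not None else tuple(panel.series)
    new_series = {}
    for name, s in panel.series.items():
        if name not in targets:
            new_series[name] = s
            continue
        mask = s.mask.copy()
        if miss.point_rate > 0:
            mask &= rng.random(len(s)) >= miss.point_rate
        for a, b in miss.biweekly_spans:
            in_span = (years >= a) & (years <= b)
            mask &= ~(in_span & (weeks % 2 == 0))
        for a, b in miss.block_gaps:
            mask &= ~((years >= a) & (years <= b))
        vals = s.values.copy()
        vals[~mask] = np.nan
        new_series[name] = WeeklySeries(name, vals, mask, s.start, unit=s.unit)
    return EnvironmentalPanel(new_series, dict(panel.annual_covariates))
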