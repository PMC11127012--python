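"""Threshold-based bloom detection and seasonal phenology metrics.

A bloom is a maximal run of consecutive weeks whose chlorophyll exceeds a
year-specific threshold of 1.05 x the annual median (the ">5% above the
annual median" convention; the factor is configurable).  Events are labeled
by the season window containing their start week: winter-spring (weeks 1-16)
or summer-fall (weeks 22-38) by default, "other" elsewhere.  Because the
threshold scales with the median, every phenology metric is invariant to
rescaling a year's chlorophyll.

Metrics are computed per imputation-ensemble member and summarized as the
across-member median and SD, so imputation uncertainty carries into the
phenology record.  Long-term shifts in timing are quantified by Poisson
GLMs on week numbers and by an OLS rate in days per decade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import WEEKS_PER_YEAR
from .dlm import ImputationEnsemble

DEFAULT_THRESHOLD_FACTOR = 1.05


@dataclass(frozen=True)
class SeasonWindows:
    winter_spring: tuple[int, int] = (1, 16)
    summer_fall: tuple[int, int] = (22, 38)

    def __post_init__(self) -> None:
        ws, sf = self.winter_spring, self.summer_fall
        for a, b in (ws, sf):
            if not (1 <= a <= b <= WEEKS_PER_YEAR):
                raise ValueError("season windows must satisfy 1 <= start <= end <= 52")
        if not (ws[1] < sf[0] or sf[1] < ws[0]):
            raise ValueError("season windows overlap")

    def label(self, week: int) -> str:
        if self.winter_spring[0] <= week <= self.winter_spring[1]:
            return "winter-spring"
        if self.summer_fall[0] <= week <= self.summer_fall[1]:
            return "summer-fall"
        return "other"

    @property
    def names(self) -> tuple[str, str]:
        return ("winter-spring", "summer-fall")


@dataclass
class BloomEvent:
    year: int
    start_week: int
    end_week: int
    peak_week: int
    peak_value: float
    season: str

    @property
    def duration_weeks(self) -> int:
        return self.end_week - self.start_week + 1

    def __post_init__(self) -> None:
        if not self.start_week <= self.peak_week <= self.end_week:
            raise ValueError("peak_week must lie within the event")


def bloom_threshold(year_values: np.ndarray, factor: float = DEFAULT_THRESHOLD_FACTOR) -> float:
    """Year-specific bloom threshold: factor x median of the weekly values."""
    v = np.asarray(year_values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("all-missing year")
    if v.size < 26:
        raise ValueError(f"need >= 26 weekly values for a stable median, got {v.size}")
    return factor * float(np.median(v))


def detect_blooms(
    year_values: np.ndarray,
    year: int,
    windows: SeasonWindows = SeasonWindows(),
    factor: float = DEFAULT_THRESHOLD_FACTOR,
) -> list[BloomEvent]:
    """Maximal runs of weeks strictly above the annual threshold.

    One event per run; the peak is the argmax within the run, earliest week
    on ties; the season label comes from the window containing the start.
    """
    v = np.asarray(year_values, float)
    thr = bloom_threshold(v, factor)
    above = v > thr
    events: list[BloomEvent] = []
    t = 0
    n = len(v)
    while t < n:
        if above[t]:
            u = t
            while u + 1 < n and above[u + 1]:
                u += 1
            seg = v[t : u + 1]
            pk = t + int(np.argmax(seg))  # argmax returns the first maximum
            events.append(BloomEvent(
                year=year, start_week=t + 1, end_week=u + 1,
                peak_week=pk + 1, peak_value=float(v[pk]),
                season=windows.label(t + 1),
            ))
            t = u + 1
        else:
            t += 1
    return events


def seasonal_metrics(
    events: list[BloomEvent],
    year: int,
    windows: SeasonWindows = SeasonWindows(),
) -> dict:
    """Per-season start/peak/duration/count for one year.

    Per window: start = earliest event start in the window; peak = week of
    the highest chlorophyll among that window's events; duration = duration
    of the event containing that peak.  Seasons with no event get NaN fields
    and count 0.
    """
    rec: dict = {"year": year, "n_blooms_annual": len(events)}
    for season in windows.names:
        evs = [e for e in events if e.season == season]
        key = season.replace("-", "_")
        rec[f"{key}_count"] = len(evs)
        if not evs:
            rec[f"{key}_start"] = np.nan
            rec[f"{key}_peak"] = np.nan
            rec[f"{key}_duration"] = np.nan
            continue
        rec[f"{key}_start"] = min(e.start_week for e in evs)
        top = max(evs, key=lambda e: (e.peak_value, -e.peak_week))
        rec[f"{key}_peak"] = top.peak_week
        rec[f"{key}_duration"] = top.duration_weeks
    return rec


def phenology_table(
    values: np.ndarray,
    years: np.ndarray,
    windows: SeasonWindows = SeasonWindows(),
    factor: float = DEFAULT_THRESHOLD_FACTOR,
) -> pd.DataFrame:
    """Per-year phenology records for one complete weekly series."""
    rows = []
    for y in np.unique(years):
        vy = values[years == y]
        if len(vy) != WEEKS_PER_YEAR:
            continue
        events = detect_blooms(vy, int(y), windows, factor)
        rows.append(seasonal_metrics(events, int(y), windows))
    return pd.DataFrame(rows).set_index("year")


def phenology_over_ensemble(
    ensemble: ImputationEnsemble,
    windows: SeasonWindows = SeasonWindows(),
    factor: float = DEFAULT_THRESHOLD_FACTOR,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenology per ensemble member, plus per-year across-member summaries.

    Returns (per_member, summary): per_member has one row per (member, year);
    summary holds the across-member median and SD of each metric per year.
    """
    ords = ensemble.start.to_ordinal() + np.arange(ensemble.n_weeks)
    years = ords // WEEKS_PER_YEAR
    tables = []
    for i in range(ensemble.m):
        t = phenology_table(ensemble.members[i], years, windows, factor)
        t = t.reset_index()
        t.insert(0, "member", i)
        tables.append(t)
    per_member = pd.concat(tables, ignore_index=True)
    metrics = [c for c in per_member.columns if c not in ("member", "year")]
    g = per_member.groupby("year")[metrics]
    summary = g.median().add_suffix("_median").join(g.std(ddof=1).add_suffix("_sd"))
    return per_member, summary


def poisson_glm(
    response_weeks: np.ndarray,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Log-link Poisson regression of a week-number metric on covariates.

    Fit by iteratively reweighted least squares; returns a table of
    coefficients, SEs, Wald z and p-values, with the deviance and a
    convergence flag attached as attrs.  Rows with missing response are
    dropped.  Responses must be nonnegative integers (week counts).
    """
    y = np.asarray(response_weeks, float)
    X = covariates.copy()
    keep = np.isfinite(y) & np.isfinite(X.to_numpy(float)).all(axis=1)
    y, X = y[keep], X.loc[keep]
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few complete rows for the Poisson GLM")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("Poisson response must be nonnegative integers")
    Xd = sm.add_constant(X.astype(float), has_constant="add")
    model = sm.GLM(y, Xd, family=sm.families.Poisson())
    res = model.fit()  # IRLS
    out = pd.DataFrame({
        "coef": res.params,
        "se": res.bse,
        "z": res.tvalues,
        "pvalue": res.pvalues,
    })
    out.attrs["deviance"] = float(res.deviance)
    out.attrs["converged"] = bool(res.converged)
    return out


def trend_rate_days_per_decade(
    years: np.ndarray, yearly_weeks: np.ndarray
) -> tuple[float, float]:
    """OLS slope of week-of-year vs year, as days per decade (slope, SE).

    days/decade = slope[weeks/year] x 7 x 10.  Negative = earlier.
    """
    y = np.asarray(yearly_weeks, float)
    x = np.asarray(years, float)
    keep = np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(y) < 10:
        raise ValueError("need >= 10 yearly values for a trend rate")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    dof = len(y) - 2
    s2 = float(r @ r) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return float(beta[1] * 70.0), float(np.sqrt(cov[1, 1]) * 70.0)
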