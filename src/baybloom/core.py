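"""Weekly-gridded time-series containers and calendar bookkeeping.

Everything downstream (imputation, SARIMAX, phenology, trends) operates on a
contiguous (year, week-of-year) grid with exactly 52 weeks per year.  Weeks
are day-of-year bins: week = ceil(day_of_year / 7), capped at 52 so that the
last one or two days of the year fold into week 52.  A 52-week year keeps the
grid commensurate with the period-52 seasonal models used throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

WEEKS_PER_YEAR = 52

#: variables whose observed values must be nonnegative (concentrations, depths)
NONNEGATIVE_VARS = frozenset(
    {"chl", "no32", "nh4", "po4", "sio4", "secchi", "light", "precip"}
)

#: canonical panel column order (after year, week)
PANEL_VARS = [
    "chl", "temp", "salinity", "secchi", "light", "precip", "strat",
    "no32", "nh4", "po4", "sio4",
]


class WeekIndex(NamedTuple):
    """A (year, week-of-year) grid point; week runs 1..52."""

    year: int
    week: int

    def to_ordinal(self) -> int:
        return self.year * WEEKS_PER_YEAR + (self.week - 1)

    @classmethod
    def from_ordinal(cls, k: int) -> "WeekIndex":
        return cls(k // WEEKS_PER_YEAR, k % WEEKS_PER_YEAR + 1)

    def shift(self, n: int) -> "WeekIndex":
        return WeekIndex.from_ordinal(self.to_ordinal() + n)


def validate_week(week: int) -> None:
    if not 1 <= week <= WEEKS_PER_YEAR:
        raise ValueError(f"week must be in 1..{WEEKS_PER_YEAR}, got {week}")


def date_to_week(date) -> WeekIndex:
    """Map a calendar date to its (year, week) bin.

    week = ceil(day_of_year / 7), capped at 52: days 365 and 366 fold into
    week 52.
    """
    ts = pd.Timestamp(date)
    week = min(int(np.ceil(ts.dayofyear / 7)), WEEKS_PER_YEAR)
    return WeekIndex(int(ts.year), week)


@dataclass
class WeeklySeries:
    """One variable on a contiguous weekly grid with an observed mask.

    ``mask[i]`` is True where the value was observed; values at masked-out
    weeks are NaN and carry no information.
    """

    name: str
    values: np.ndarray
    mask: np.ndarray
    start: WeekIndex
    unit: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        validate_week(self.start.week)
        if self.values.shape != self.mask.shape or self.values.ndim != 1:
            raise ValueError("values and mask must be 1-D arrays of equal length")
        obs = self.values[self.mask]
        if not np.all(np.isfinite(obs)):
            raise ValueError(f"{self.name}: observed values must be finite")
        if self.name in NONNEGATIVE_VARS and obs.size and np.any(obs < 0):
            raise ValueError(f"{self.name}: observed values must be >= 0")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def end(self) -> WeekIndex:
        return self.start.shift(len(self) - 1)

    def week_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Return parallel (years, weeks) arrays for the grid."""
        ords = self.start.to_ordinal() + np.arange(len(self))
        return ords // WEEKS_PER_YEAR, ords % WEEKS_PER_YEAR + 1

    def index_of(self, wi: WeekIndex) -> int:
        k = wi.to_ordinal() - self.start.to_ordinal()
        if not 0 <= k < len(self):
            raise IndexError(f"{wi} outside series span {self.start}..{self.end}")
        return k

    def is_complete(self) -> bool:
        return bool(self.mask.all())

    def to_frame(self) -> pd.DataFrame:
        years, weeks = self.week_grid()
        return pd.DataFrame({"year": years, "week": weeks, self.name: self.values})


@dataclass
class DecadeSpec:
    label: str
    first_year: int
    last_year: int

    def __post_init__(self) -> None:
        if self.last_year < self.first_year:
            raise ValueError("last_year must be >= first_year")

    @property
    def years(self) -> range:
        return range(self.first_year, self.last_year + 1)


@dataclass
class EnvironmentalPanel:
    """Aligned collection of WeeklySeries plus per-year covariates (e.g. GSI)."""

    series: dict[str, WeeklySeries]
    annual_covariates: dict[str, dict[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError("panel needs at least one series")
        ref = next(iter(self.series.values()))
        for name, s in self.series.items():
            if s.name != name:
                raise ValueError(f"series key {name!r} != series.name {s.name!r}")
            if s.start != ref.start or len(s) != len(ref):
                raise ValueError(f"series {name!r} not aligned with {ref.name!r}")

    def __getitem__(self, name: str) -> WeeklySeries:
        return self.series[name]

    def __contains__(self, name: str) -> bool:
        return name in self.series

    @property
    def start(self) -> WeekIndex:
        return next(iter(self.series.values())).start

    @property
    def n_weeks(self) -> int:
        return len(next(iter(self.series.values())))

    @property
    def names(self) -> list[str]:
        return list(self.series)

    def years(self) -> np.ndarray:
        ys, _ = next(iter(self.series.values())).week_grid()
        return np.unique(ys)

    def with_series(self, s: WeeklySeries) -> "EnvironmentalPanel":
        new = dict(self.series)
        new[s.name] = s
        return EnvironmentalPanel(new, dict(self.annual_covariates))


def align_to_weekly_grid(
    dated_records: Sequence[tuple], name: str = "value", unit: str = ""
) -> WeeklySeries:
    """Bin (date, value) records to the weekly grid.

    Multiple records falling in one week are averaged; weeks with no record
    between the first and last observed week are masked missing.
    """
    if len(dated_records) == 0:
        raise ValueError("no records")
    ords, vals = [], []
    for date, value in dated_records:
        v = float(value)
        if not np.isfinite(v):
            raise ValueError(f"non-finite value {value!r} at {date!r}")
        ords.append(date_to_week(date).to_ordinal())
        vals.append(v)
    ords = np.asarray(ords)
    vals = np.asarray(vals)
    lo, hi = int(ords.min()), int(ords.max())
    n = hi - lo + 1
    sums = np.zeros(n)
    counts = np.zeros(n)
    np.add.at(sums, ords - lo, vals)
    np.add.at(counts, ords - lo, 1.0)
    mask = counts > 0
    values = np.full(n, np.nan)
    values[mask] = sums[mask] / counts[mask]
    return WeeklySeries(name, values, mask, WeekIndex.from_ordinal(lo), unit=unit)


# ---------------------------------------------------------------------------
# Panel I/O
#
# Panel CSV layout: header `year,week,<var>,<var>,...`; empty cell = missing.
# Units are carried in an optional JSON sidecar `<path>.meta.json` so the CSV
# stays a plain rectangular table.


def write_panel(panel: EnvironmentalPanel, path) -> None:
    path = Path(path)
    ref = next(iter(panel.series.values()))
    years, weeks = ref.week_grid()
    df = pd.DataFrame({"year": years, "week": weeks})
    for name, s in panel.series.items():
        # %.17g round-trips IEEE doubles exactly; empty cell = missing
        df[name] = ["%.17g" % v if m else "" for v, m in zip(s.values, s.mask)]
    df.to_csv(path, index=False)
    meta = {
        "units": {name: s.unit for name, s in panel.series.items()},
        "annual_covariates": {
            k: {str(y): v for y, v in d.items()}
            for k, d in panel.annual_covariates.items()
        },
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def load_panel(path) -> EnvironmentalPanel:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("year", "week"):
        if col not in df.columns:
            raise ValueError(f"panel CSV missing required column {col!r}")
    years = df["year"].to_numpy(dtype=int)
    weeks = df["week"].to_numpy(dtype=int)
    ords = years * WEEKS_PER_YEAR + (weeks - 1)
    dup = pd.Series(ords).duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"duplicate (year, week) row: ({years[i]}, {weeks[i]})")
    if len(ords) > 1 and not np.all(np.diff(ords) == 1):
        i = int(np.flatnonzero(np.diff(ords) != 1)[0])
        raise ValueError(
            "non-contiguous grid: gap after "
            f"({years[i]}, {weeks[i]})"
        )
    start = WeekIndex(int(years[0]), int(weeks[0]))
    validate_week(start.week)

    units: Mapping[str, str] = {}
    covs: dict[str, dict[int, float]] = {}
    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        units = meta.get("units", {})
        covs = {
            k: {int(y): float(v) for y, v in d.items()}
            for k, d in meta.get("annual_covariates", {}).items()
        }

    series = {}
    for name in df.columns:
        if name in ("year", "week"):
            continue
        vals = df[name].to_numpy(dtype=float)
        mask = np.isfinite(vals)
        series[name] = WeeklySeries(name, vals, mask, start, unit=units.get(name, ""))
    return EnvironmentalPanel(series, covs)


def load_annual_covariates(path, name: str = "gsi") -> dict[int, float]:
    """Read a `year,<name>` CSV into a per-year mapping."""
    df = pd.read_csv(path)
    if "year" not in df.columns or name not in df.columns:
        raise ValueError(f"annual covariate CSV needs columns 'year' and {name!r}")
    return {int(y): float(v) for y, v in zip(df["year"], df[name])}


# ---------------------------------------------------------------------------
# Year slicing and decade bookkeeping


def slice_years(series: WeeklySeries, first_year: int, last_year: int) -> WeeklySeries:
    """Restrict a series to whole calendar years first_year..last_year."""
    if last_year < first_year:
        raise ValueError("last_year must be >= first_year")
    lo = WeekIndex(first_year, 1).to_ordinal()
    hi = WeekIndex(last_year, WEEKS_PER_YEAR).to_ordinal()
    s0 = series.start.to_ordinal()
    if lo < s0 or hi > series.end.to_ordinal():
        raise ValueError(
            f"requested years {first_year}-{last_year} outside series span "
            f"{series.start}..{series.end}"
        )
    i, j = lo - s0, hi - s0 + 1
    return WeeklySeries(
        series.name, series.values[i:j].copy(), series.mask[i:j].copy(),
        WeekIndex(first_year, 1), unit=series.unit,
    )


def slice_panel(panel: EnvironmentalPanel, first_year: int, last_year: int) -> EnvironmentalPanel:
    return EnvironmentalPanel(
        {n: slice_years(s, first_year, last_year) for n, s in panel.series.items()},
        dict(panel.annual_covariates),
    )


def assign_decades(years: Iterable[int], decades: Sequence[DecadeSpec]) -> dict[int, str | None]:
    """Label each year with the decade containing it (None if unlabeled)."""
    out: dict[int, str | None] = {}
    for y in years:
        label = None
        for d in decades:
            if d.first_year <= y <= d.last_year:
                label = d.label
                break
        out[int(y)] = label
    return out
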