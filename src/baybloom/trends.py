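"""Annual aggregation, decadal comparisons, trend fits, climatologies, and
the k-sample Anderson-Darling test.

The Anderson-Darling test is the rank-based k-sample version with midrank
tie handling.  Its p-value comes either from the asymptotic null law —
A^2 converges to sum_j chi2_{k-1,j} / (j(j+1)), whose tail probability is
evaluated by numerical inversion of the characteristic function (Imhof's
method) — or from a seeded permutation of the pooled sample.  The asymptotic
route avoids the short tabulated range of the classical critical-value
interpolation; the permutation route is exact up to Monte-Carlo error and is
the reference at small samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .core import WEEKS_PER_YEAR, DecadeSpec


@dataclass
class AnnualSummary:
    year: int
    cumulative: float
    mean: float
    sd: float
    cv_percent: float
    maximum: float
    minimum: float


@dataclass
class TrendFit:
    slope: float
    intercept: float
    r_squared: float
    pvalue: float
    slope_se: float
    transform: str


@dataclass
class ADResult:
    k: int
    sizes: tuple[int, ...]
    statistic: float          # standardized (A^2 - (k-1)) / sigma_N
    pvalue: float
    method: str               # "asymptotic" | "permutation"


def annual_summaries(values: np.ndarray, years: np.ndarray) -> pd.DataFrame:
    """Per-year cumulative/mean/SD/CV/max/min of a complete weekly series.

    Partial years (fewer than 52 weeks on the grid) are excluded.  SD is the
    sample standard deviation (n-1); CV = 100 * SD / mean.
    """
    values = np.asarray(values, float)
    years = np.asarray(years, int)
    rows = []
    for y in np.unique(years):
        v = values[years == y]
        if len(v) != WEEKS_PER_YEAR:
            continue
        mean = v.mean()
        sd = v.std(ddof=1)
        rows.append(AnnualSummary(
            year=int(y), cumulative=float(v.sum()), mean=float(mean),
            sd=float(sd), cv_percent=float(100.0 * sd / mean),
            maximum=float(v.max()), minimum=float(v.min()),
        ))
    if not rows:
        raise ValueError("no complete years in input")
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("year")


def decade_compare(
    summaries: pd.DataFrame,
    first: DecadeSpec,
    last: DecadeSpec,
    column: str = "cumulative",
    equal_var: bool = False,
) -> dict:
    """Two-sample t-test (Welch by default) on a per-year field between two
    decades, plus the percent change of the mean."""
    a = summaries.loc[summaries.index.isin(first.years), column].to_numpy(float)
    b = summaries.loc[summaries.index.isin(last.years), column].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 years per decade")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = len(a) + len(b) - 2.0
    else:
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        denom = va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
        df = (va + vb) ** 2 / denom if denom > 0 else len(a) + len(b) - 2.0
    return {
        "t": float(t), "df": float(df), "pvalue": float(p),
        "mean_first": float(a.mean()), "mean_last": float(b.mean()),
        "percent_change": float(100.0 * (b.mean() - a.mean()) / a.mean()),
    }


def loglinear_trend(years: np.ndarray, yearly_values: np.ndarray) -> TrendFit:
    """OLS of ln(value) on calendar year; slope is the exponential rate."""
    x = np.asarray(years, float)
    v = np.asarray(yearly_values, float)
    bad = np.flatnonzero(v <= 0)
    if bad.size:
        raise ValueError(f"nonpositive value in year {int(x[bad[0]])}; cannot log-transform")
    logv = np.log(v)
    if np.ptp(logv) == 0:  # constant input: flat fit, no explained variance
        return TrendFit(0.0, float(logv[0]), 0.0, 1.0, 0.0, "log")
    res = stats.linregress(x, logv)
    return TrendFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), pvalue=float(res.pvalue),
        slope_se=float(res.stderr), transform="log",
    )


def decadal_climatology(
    values: np.ndarray,
    years: np.ndarray,
    weeks: np.ndarray,
    decades: list[DecadeSpec],
) -> pd.DataFrame:
    """Per-decade mean weekly profile (52 rows, one column per decade)."""
    out = {}
    for d in decades:
        sel = (years >= d.first_year) & (years <= d.last_year)
        if not sel.any():
            raise ValueError(f"decade {d.label}: no data in range")
        prof = np.full(WEEKS_PER_YEAR, np.nan)
        for w in range(1, WEEKS_PER_YEAR + 1):
            vw = values[sel & (weeks == w)]
            if vw.size:
                prof[w - 1] = vw.mean()
        out[d.label] = prof
    return pd.DataFrame(out, index=pd.RangeIndex(1, WEEKS_PER_YEAR + 1, name="week"))


# ---------------------------------------------------------------------------
# k-sample Anderson-Darling


def _midrank_a2(counts: np.ndarray, l: np.ndarray, sizes: np.ndarray) -> float:
    """Ties-adjusted A^2_akN from per-sample counts over distinct pooled
    values (Scholz-Stephens midrank version)."""
    N = int(sizes.sum())
    cumf = np.cumsum(counts, axis=1)
    M = cumf - counts / 2.0
    B = np.cumsum(l) - l / 2.0
    den = B * (N - B) - N * l / 4.0
    valid = den > 0
    if not valid.any():
        return 0.0
    diff = N * M[:, valid] - np.outer(sizes, B[valid])
    inner = (diff**2 / den[valid]) * (l[valid] / N)
    return float((N - 1) / N * np.sum(inner.sum(axis=1) / sizes))


def _sigma_n(k: int, sizes: np.ndarray) -> float:
    """Finite-sample null SD of A^2_kN (Scholz-Stephens)."""
    N = int(sizes.sum())
    H = float(np.sum(1.0 / sizes))
    i = np.arange(1, N)
    h = float(np.sum(1.0 / i))
    # g = sum_{i=1}^{N-2} sum_{j=i+1}^{N-1} 1 / ((N - i) j)
    inv_j = 1.0 / np.arange(1, N)
    tail = np.cumsum(inv_j[::-1])[::-1]     # tail[i-1] = sum_{j>=i} 1/j
    ii = np.arange(1, N - 1)
    g = float(np.sum(tail[ii] / (N - ii)))
    a = (4 * g - 6) * (k - 1) + (10 - 6 * g) * H
    b = (2 * g - 4) * k**2 + 8 * h * k + (2 * g - 14 * h - 4) * H - 8 * h + 4 * g - 6
    c = (6 * h + 2 * g - 2) * k**2 + (4 * h - 4 * g + 6) * k + (2 * h - 6) * H + 4 * h
    d = (2 * h + 6) * k**2 - 4 * h * k
    var = (a * N**3 + b * N**2 + c * N + d) / ((N - 1.0) * (N - 2.0) * (N - 3.0))
    return float(np.sqrt(max(var, 0.0)))


_AD_J = 2000  # truncation of the asymptotic weight sequence


def _asymptotic_sf(x: float, k: int) -> float:
    """P(Q > x) for Q = sum_j chi2_{k-1} / (j (j+1)), by Imhof's method."""
    j = np.arange(1, _AD_J + 1)
    lam = 1.0 / (j * (j + 1.0))
    x = x - (k - 1.0) / (_AD_J + 1.0)  # mean of the truncated tail
    if x <= 0:
        return 1.0
    df = k - 1.0

    def integrand(u: float) -> float:
        theta = 0.5 * df * np.sum(np.arctan(lam * u)) - 0.5 * x * u
        log_rho = 0.25 * df * np.sum(np.log1p((lam * u) ** 2))
        if log_rho > 600:
            return 0.0
        return np.sin(theta) / (u * np.exp(log_rho))

    val, _ = integrate.quad(integrand, 0.0, np.inf, limit=800)
    return float(min(max(0.5 + val / np.pi, 0.0), 1.0))


def ad_ksample(
    samples: list[np.ndarray],
    method: str = "asymptotic",
    n_permutations: int = 2000,
    seed: int = 0,
) -> ADResult:
    """k-sample Anderson-Darling test that the samples share one distribution.

    ``method="asymptotic"`` maps the standardized statistic onto the limiting
    null law; ``"permutation"`` reshuffles pooled values n_permutations times
    (p = (1 + #{T* >= T}) / (B + 1)).
    """
    if len(samples) < 2:
        raise ValueError("need k >= 2 samples")
    samples = [np.asarray(s, float) for s in samples]
    sizes = np.array([len(s) for s in samples])
    if np.any(sizes < 5):
        raise ValueError("each sample needs n >= 5")
    k = len(samples)
    pooled = np.concatenate(samples)
    N = len(pooled)
    z, vidx = np.unique(pooled, return_inverse=True)
    l = np.bincount(vidx).astype(float)

    if len(z) == 1:
        return ADResult(k, tuple(sizes), 0.0, 1.0, method)

    starts = np.concatenate([[0], np.cumsum(sizes)])

    def counts_for(order: np.ndarray) -> np.ndarray:
        f = np.zeros((k, len(z)))
        for i in range(k):
            idx = vidx[order[starts[i]: starts[i + 1]]]
            f[i] = np.bincount(idx, minlength=len(z))
        return f

    identity = np.arange(N)
    a2 = _midrank_a2(counts_for(identity), l, sizes)
    sigma = _sigma_n(k, sizes)
    tkn = (a2 - (k - 1.0)) / sigma if sigma > 0 else 0.0

    if method == "asymptotic":
        sigma_inf = np.sqrt(2.0 * (k - 1.0) * (np.pi**2 / 3.0 - 3.0))
        p = _asymptotic_sf(tkn * sigma_inf + (k - 1.0), k)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(N)
            if _midrank_a2(counts_for(perm), l, sizes) >= a2 - 1e-12:
                count += 1
        p = (1.0 + count) / (n_permutations + 1.0)
    else:
        raise ValueError("method must be 'asymptotic' or 'permutation'")
    return ADResult(k, tuple(int(s) for s in sizes), float(tkn), float(p), method)


def pairwise_decade_tests(
    samples_by_decade: dict[str, np.ndarray],
    method: str = "asymptotic",
    n_permutations: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], ADResult]]:
    """Two-sample AD test for every pair of decades.

    Returns a symmetric p-value matrix (diagonal NaN) and the full results
    keyed by label pair.  p-values are reported per pair, unadjusted.
    """
    labels = list(samples_by_decade)
    if len(labels) < 2:
        raise ValueError("need >= 2 decades")
    pmat = pd.DataFrame(np.nan, index=labels, columns=labels)
    results: dict[tuple[str, str], ADResult] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            res = ad_ksample(
                [samples_by_decade[a], samples_by_decade[b]],
                method=method, n_permutations=n_permutations, seed=seed,
            )
            results[(a, b)] = results[(b, a)] = res
            pmat.loc[a, b] = pmat.loc[b, a] = res.pvalue
    return pmat, results
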