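"""Bivariate Granger-causality screening between drivers and chlorophyll.

x Granger-causes y if past x improves the prediction of y beyond y's own
past: an F-test comparing the restricted regression (y on its own lags
1..L) against the unrestricted one (adding x lags 1..L).  The lag order L is
chosen by AIC on the *restricted* model only, so the selection does not peek
at x and the test keeps its nominal size under the null.

For decadal-scale screening the default preprocessing takes annual means of
the gap-filled weekly series and first-differences them, which removes the
shared long-term trends that otherwise produce spurious causality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import EnvironmentalPanel


@dataclass
class GrangerResult:
    cause: str
    effect: str
    lag: int
    fstat: float
    pvalue: float
    n_effective: int


def _lag_matrix(v: np.ndarray, lags: int, max_lag: int) -> np.ndarray:
    n = len(v)
    return np.column_stack([v[max_lag - l : n - l] for l in range(1, lags + 1)])


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def granger_test(
    x: np.ndarray,
    y: np.ndarray,
    max_lag: int = 4,
    lag_rule: str = "aic",
    cause: str = "x",
    effect: str = "y",
) -> GrangerResult:
    """Test whether x Granger-causes y.

    ``lag_rule`` is "aic" (L chosen on the restricted autoregression of y,
    over 1..max_lag) or "fixed" (L = max_lag).  Both series are mean-centered
    and an intercept is included.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance series")
    if len(y) <= 3 * max_lag:
        raise ValueError(f"series too short for max_lag={max_lag}")
    x = x - x.mean()
    y = y - y.mean()

    if lag_rule == "fixed":
        L = max_lag
    elif lag_rule == "aic":
        # common estimation window (trim max_lag) for comparable likelihoods
        yy = y[max_lag:]
        n = len(yy)
        best, L = np.inf, 1
        for l in range(1, max_lag + 1):
            X = np.column_stack([np.ones(n), _lag_matrix(y, l, max_lag)])
            rss = _ols_rss(X, yy)
            aic = n * np.log(rss / n) + 2 * (l + 1)
            if aic < best - 1e-12:
                best, L = aic, l
    else:
        raise ValueError("lag_rule must be 'aic' or 'fixed'")

    yy = y[L:]
    n = len(yy)
    Xr = np.column_stack([np.ones(n), _lag_matrix(y, L, L)])
    Xu = np.column_stack([Xr, _lag_matrix(x, L, L)])
    df2 = n - Xu.shape[1]
    if df2 <= 0:
        raise ValueError("insufficient length for the unrestricted regression")
    rss_r = _ols_rss(Xr, yy)
    rss_u = _ols_rss(Xu, yy)
    F = max((rss_r - rss_u), 0.0) / L / (rss_u / df2)
    p = float(stats.f.sf(F, L, df2))
    return GrangerResult(cause, effect, L, float(F), p, n)


def annual_means(values: np.ndarray, years: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uy = np.unique(years)
    return uy, np.array([values[years == y].mean() for y in uy])


def granger_screen(
    panel: EnvironmentalPanel,
    effect: str,
    causes: list[str],
    preprocessing: str = "annual_diff",
    max_lag: int | None = None,
    lag_rule: str = "aic",
) -> list[GrangerResult]:
    """Run granger_test for each candidate cause against one effect series.

    ``preprocessing``: "annual_diff" (annual means, first-differenced;
    decadal-trend screening) or "weekly" (raw weekly values).  Requires
    complete (imputed) series.  p-values are reported per pair without
    multiplicity adjustment.
    """
    if effect not in panel:
        raise ValueError(f"effect {effect!r} not in panel")
    for c in causes:
        if c not in panel:
            raise ValueError(f"cause {c!r} not in panel")
    if preprocessing not in ("annual_diff", "weekly"):
        raise ValueError("preprocessing must be 'annual_diff' or 'weekly'")
    if max_lag is None:
        max_lag = 4 if preprocessing == "annual_diff" else 8

    years, _ = panel[effect].week_grid()

    def prep(name: str) -> np.ndarray:
        s = panel[name]
        if not s.is_complete():
            raise ValueError(f"{name!r} has missing weeks; impute first")
        if preprocessing == "weekly":
            return s.values
        _, am = annual_means(s.values, years)
        return np.diff(am)

    ye = prep(effect)
    return [
        granger_test(prep(c), ye, max_lag=max_lag, lag_rule=lag_rule,
                     cause=c, effect=effect)
        for c in causes
    ]
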