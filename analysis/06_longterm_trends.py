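#!/usr/bin/env python
"""Long-term trend statistics on the gap-filled chlorophyll: annual
summaries (cumulative, CV, max, min), first-vs-last-decade Welch t-tests,
log-linear fits of annual extremes, decadal weekly climatologies, and
pairwise k-sample Anderson-Darling comparisons of the decadal patterns.

Reads results/ensemble.csv; writes annual_summaries.csv, decade_tests.csv,
trend_fits.csv, climatology.csv and ad_matrix.csv under results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from baybloom import (
    DecadeSpec,
    annual_summaries,
    decadal_climatology,
    decade_compare,
    loglinear_trend,
    pairwise_decade_tests,
)
from baybloom.core import WEEKS_PER_YEAR


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    df = pd.read_csv(args.outdir / "ensemble.csv")
    members = df[[c for c in df.columns if c.startswith("member_")]].to_numpy().T
    chl = members.mean(axis=0)
    years = df["year"].to_numpy()
    weeks = df["week"].to_numpy()

    summ = annual_summaries(chl, years)
    summ.to_csv(args.outdir / "annual_summaries.csv")
    print(f"mean annual CV: {summ['cv_percent'].mean():.0f}%")

    first = DecadeSpec("first", int(years.min()), int(years.min()) + 9)
    last = DecadeSpec("last", int(years.max()) - 9, int(years.max()))
    rows = []
    for col in ("cumulative", "maximum", "cv_percent"):
        d = decade_compare(summ, first, last, col)
        d["field"] = col
        rows.append(d)
        print(f"{col}: {d['percent_change']:+.0f}% "
              f"(Welch t = {d['t']:.2f}, p = {d['pvalue']:.2g})")
    pd.DataFrame(rows).to_csv(args.outdir / "decade_tests.csv", index=False)

    fits = []
    for col in ("maximum", "minimum"):
        f = loglinear_trend(summ.index.to_numpy(), summ[col].to_numpy())
        fits.append({"field": col, **f.__dict__})
        print(f"annual {col}: log-linear slope {f.slope:+.4f} per year, "
              f"R^2 = {f.r_squared:.2f}, p = {f.pvalue:.2g}")
    pd.DataFrame(fits).to_csv(args.outdir / "trend_fits.csv", index=False)

    decades = [DecadeSpec(str(y), y, y + 9)
               for y in range(int(years.min()), int(years.max()) - 8, 10)]
    clim = decadal_climatology(chl, years, weeks, decades)
    clim.to_csv(args.outdir / "climatology.csv")
    pmat, _ = pairwise_decade_tests(
        {d.label: clim[d.label].to_numpy() for d in decades}
    )
    pmat.to_csv(args.outdir / "ad_matrix.csv")
    print("pairwise decadal AD p-values:")
    print(pmat.round(4).to_string())


if __name__ == "__main__":
    main()
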