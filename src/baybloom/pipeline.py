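"""Config-driven orchestration: synth/load -> impute -> SARIMAX-MC ->
Granger -> phenology -> trends.

Every stage reads and writes plain CSV under the output directory, and a JSON
manifest records the config echo, seeds, stage timings and warnings, so a run
is fully reproducible and resumable.  Stage seeds derive from the master seed
by hashing the stage name (blake2s), so adding or reordering stages never
perturbs another stage's randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    DecadeSpec, EnvironmentalPanel, load_panel, write_panel,
)
from .dlm import DLMSpec, ImputationEnsemble, impute_panel
from .granger import granger_screen
from .phenology import (
    SeasonWindows, phenology_over_ensemble, trend_rate_days_per_decade,
)
from .sarimax import ExogSpec, MCSummary, SarimaxOrder, run_mc
from .synth import SynthConfig, apply_missingness, generate_panel
from .trends import (
    annual_summaries, decade_compare, decadal_climatology, loglinear_trend,
    pairwise_decade_tests,
)

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: blake2s(master:stage) mod 2^31."""
    digest = hashlib.blake2s(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    m: int = 100
    panel_csv: str | None = None       # if None, generate synthetically
    synth: SynthConfig = field(default_factory=SynthConfig)
    dlm: DLMSpec = field(default_factory=DLMSpec)
    order: SarimaxOrder = field(default_factory=SarimaxOrder)
    exog: ExogSpec = field(default_factory=ExogSpec)
    granger_causes: tuple[str, ...] = (
        "no32", "nh4", "po4", "sio4", "temp", "salinity", "secchi",
        "light", "precip", "strat",
    )
    granger_resolution: str = "annual_diff"
    granger_max_lag: int | None = None  # None: module default, clamped to length
    windows: SeasonWindows = field(default_factory=SeasonWindows)
    threshold_factor: float = 1.05
    decades: tuple[DecadeSpec, ...] = ()
    sarimax_transform: str = "log"     # scale of the chl series fed to SARIMAX

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "synth" in raw:
            kwargs["synth"] = SynthConfig(**raw.pop("synth"))
        if "dlm" in raw:
            kwargs["dlm"] = DLMSpec(**raw.pop("dlm"))
        if "order" in raw:
            kwargs["order"] = SarimaxOrder(*raw.pop("order"))
        if "exog" in raw:
            kwargs["exog"] = ExogSpec(tuple(tuple(t) for t in raw.pop("exog")))
        if "windows" in raw:
            w = raw.pop("windows")
            kwargs["windows"] = SeasonWindows(tuple(w[0]), tuple(w[1]))
        if "decades" in raw:
            kwargs["decades"] = tuple(DecadeSpec(*d) for d in raw.pop("decades"))
        for key in ("granger_causes",):
            if key in raw:
                raw[key] = tuple(raw[key])
        kwargs.update(raw)
        return cls(**kwargs)


def _default_decades(panel: EnvironmentalPanel) -> tuple[DecadeSpec, ...]:
    years = panel.years()
    return (
        DecadeSpec("first", int(years.min()), int(years.min()) + 9),
        DecadeSpec("last", int(years.max()) - 9, int(years.max())),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "m": config.m,
        "stages": {},
        "warnings": [],
    }
    t_all = time.time()

    def _finish(stage: str, t0: float) -> None:
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "seed": stage_seed(config.seed, stage),
        }
        logger.info("stage %-10s done in %.2fs", stage, time.time() - t0)

    try:
        # -- input panel ---------------------------------------------------
        t0 = time.time()
        if config.panel_csv is not None:
            panel = load_panel(config.panel_csv)
            truth = None
        else:
            synth = dataclasses.replace(
                config.synth, seed=stage_seed(config.seed, "synth")
            )
            full_panel, truth = generate_panel(synth)
            panel = apply_missingness(
                full_panel, synth, seed=stage_seed(config.seed, "mask")
            )
            write_panel(panel, out / "panel.csv")
        _finish("input", t0)

        # -- imputation ------------------------------------------------------
        t0 = time.time()
        ensemble, completed = impute_panel(
            panel, specs={"chl": config.dlm}, M=config.m,
            seed=stage_seed(config.seed, "impute"),
        )
        members = pd.DataFrame(
            ensemble.members.T,
            columns=[f"member_{i}" for i in range(ensemble.m)],
        )
        years, weeks = panel["chl"].week_grid()
        members.insert(0, "week", weeks)
        members.insert(0, "year", years)
        members.to_csv(out / "ensemble.csv", index=False)
        write_panel(completed, out / "panel_completed.csv")
        _finish("impute", t0)

        # -- SARIMAX Monte Carlo ---------------------------------------------
        t0 = time.time()
        if config.sarimax_transform == "log":
            sm_members = np.log(ensemble.members)
            sm_ens = ImputationEnsemble(
                name="log_chl", members=sm_members, mask=ensemble.mask,
                start=ensemble.start, seed=ensemble.seed, spec=ensemble.spec,
            )
        else:
            sm_ens = ensemble
        mc = run_mc(sm_ens, completed, config.order, config.exog)
        mc.table.to_csv(out / "mc_summary.csv")
        if mc.n_dropped:
            manifest["warnings"].append(f"sarimax: dropped {mc.n_dropped} fits")
        _finish("sarimax", t0)

        # -- Granger ---------------------------------------------------------
        t0 = time.time()
        causes = [c for c in config.granger_causes if c in completed]
        if config.granger_resolution == "annual_diff":
            n_points = len(panel.years()) - 1
            default_lag = 4
        else:
            n_points = panel.n_weeks
            default_lag = 8
        max_lag = min(config.granger_max_lag or default_lag, max((n_points - 2) // 3, 1))
        gres = granger_screen(
            completed, "chl", causes,
            preprocessing=config.granger_resolution, max_lag=max_lag,
        )
        pd.DataFrame([
            {"cause": g.cause, "effect": g.effect, "lag": g.lag,
             "F": g.fstat, "p": g.pvalue, "n": g.n_effective}
            for g in gres
        ]).to_csv(out / "granger.csv", index=False)
        _finish("granger", t0)

        # -- phenology ---------------------------------------------------------
        t0 = time.time()
        per_member, summary = phenology_over_ensemble(
            ensemble, config.windows, config.threshold_factor
        )
        per_member.to_csv(out / "phenology_members.csv", index=False)
        summary.to_csv(out / "phenology_summary.csv")
        ws_start = summary["winter_spring_start_median"]
        rate = rate_se = float("nan")
        if ws_start.notna().sum() >= 10:
            rate, rate_se = trend_rate_days_per_decade(
                summary.index.to_numpy(), ws_start.to_numpy()
            )
        manifest["winter_spring_start_days_per_decade"] = {
            "rate": rate, "se": rate_se,
        }
        _finish("phenology", t0)

        # -- trends ------------------------------------------------------------
        t0 = time.time()
        chl_mean = ensemble.mean_series()
        summ = annual_summaries(chl_mean, years)
        summ.to_csv(out / "annual_summaries.csv")
        decades = config.decades or _default_decades(panel)
        tests = []
        for col in ("cumulative", "cv_percent", "maximum"):
            d = decade_compare(summ, decades[0], decades[-1], column=col)
            d["field"] = col
            tests.append(d)
        pd.DataFrame(tests).to_csv(out / "decade_tests.csv", index=False)
        fits = []
        for col in ("maximum", "minimum"):
            f = loglinear_trend(summ.index.to_numpy(), summ[col].to_numpy())
            fits.append({"field": col, **f.__dict__})
        pd.DataFrame(fits).to_csv(out / "trend_fits.csv", index=False)
        clim = decadal_climatology(chl_mean, years, weeks, list(decades))
        clim.to_csv(out / "climatology.csv")
        pmat, _ = pairwise_decade_tests(
            {d.label: clim[d.label].to_numpy() for d in decades},
            seed=stage_seed(config.seed, "adtest"),
        )
        pmat.to_csv(out / "ad_matrix.csv")
        _finish("trends", t0)
    except Exception as err:
        stage = len(manifest["stages"])
        raise RuntimeError(
            f"pipeline failed after {list(manifest['stages'])} "
            f"(partial outputs in {out})"
        ) from err

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
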