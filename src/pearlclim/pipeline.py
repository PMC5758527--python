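"""End-to-end orchestration: morphometrics through suitability mapping.

``run_pipeline`` sequences the stages in analysis order — shell filtering and
aggregation, site climate extraction, temperature calibration (with CV,
Moran's I and outlier handling), growth (optional), thresholds, gridded
projection/classification, and per-population reconstruction — writing every
report as CSV plus a machine-readable JSON manifest recording inputs, seeds
and stage outcomes. A stage failure halts the run with a stage-labelled
error; outputs of completed stages are preserved.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import calibration as cal_mod
from . import climate as climate_mod
from . import growth as growth_mod
from . import io as io_mod
from . import morphometry as morpho_mod
from . import suitability as suit_mod
from .errors import PearlclimError

logger = logging.getLogger("pearlclim.pipeline")

DEFAULT_PERIODS = ((1901, 1920), (1991, 2010))


@dataclass
class RunConfig:
    """File paths and knobs for one pipeline run."""

    shells_csv: str
    climate_path: str  # long-format CSV (.csv) or NetCDF (.nc)
    out_dir: str
    rings_csv: str | None = None
    mask_csv: str | None = None
    window_years: int = 20
    summer_months: tuple[int, ...] = climate_mod.SUMMER_MONTHS
    exclude_ids: tuple[str, ...] = ()
    cv_k: int = 5
    seed: int = 0
    periods: tuple[tuple[int, int], ...] = DEFAULT_PERIODS
    reconstruct_years: tuple[int, int] = (1901, 2010)
    threshold_overrides: dict | None = None

    def __post_init__(self) -> None:
        if self.window_years not in climate_mod.MST_WINDOWS:
            raise ValueError(
                f"window_years must be one of {climate_mod.MST_WINDOWS}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "periods" in raw:
            raw["periods"] = tuple(tuple(p) for p in raw["periods"])
        if "summer_months" in raw:
            raw["summer_months"] = tuple(raw["summer_months"])
        if "exclude_ids" in raw:
            raw["exclude_ids"] = tuple(str(i) for i in raw["exclude_ids"])
        if "reconstruct_years" in raw:
            raw["reconstruct_years"] = tuple(raw["reconstruct_years"])
        return cls(**raw)


def _load_grid(path: str) -> climate_mod.ClimateGrid:
    p = Path(path)
    if p.suffix in {".nc", ".nc4", ".cdf"}:
        return climate_mod.ClimateGrid.from_netcdf(p)
    return climate_mod.ClimateGrid.from_long_csv(p)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            "shells": str(config.shells_csv),
            "climate": str(config.climate_path),
            "rings": str(config.rings_csv) if config.rings_csv else None,
            "mask": str(config.mask_csv) if config.mask_csv else None,
        },
        "settings": {
            "window_years": config.window_years,
            "summer_months": list(config.summer_months),
            "exclude_ids": list(config.exclude_ids),
            "cv_k": config.cv_k,
            "periods": [list(p) for p in config.periods],
        },
        "stages": {},
    }

    # -- stage 1: morphometrics ------------------------------------------
    records, status_map = io_mod.read_shells_csv(config.shells_csv)
    kept = morpho_mod.filter_shells(records)
    by_pop: dict[str, list] = {}
    for r in kept:
        by_pop.setdefault(r.population_id, []).append(r)
    populations = [
        morpho_mod.aggregate_population(recs, status=status_map.get(pid, "unknown"))
        for pid, recs in sorted(by_pop.items())
    ]
    io_mod.write_populations_csv(populations, out / "populations.csv")
    manifest["stages"]["morphometrics"] = {
        "status": "complete",
        "n_shells_in": len(records),
        "n_shells_kept": len(kept),
        "n_populations": len(populations),
    }

    # -- stage 2: climate extraction --------------------------------------
    grid = _load_grid(config.climate_path)
    sites = [
        climate_mod.site_climate(
            grid, p.latitude_deg, p.longitude_deg, p.year_collected,
            population_id=p.population_id, k=config.window_years,
        )
        for p in populations
    ]
    site_frame = climate_mod.site_climates_to_frame(sites)
    site_frame.to_csv(out / "site_climate.csv", index=False)
    manifest["stages"]["climate"] = {"status": "complete", "n_sites": len(sites)}

    # -- stage 3: calibration ---------------------------------------------
    mst_col = f"mst_{config.window_years}"
    pop_frame = io_mod.populations_to_frame(populations)
    model = pop_frame.merge(site_frame[["population_id", mst_col]],
                            on="population_id")
    model = model[
        model["status"].isin(["viable", "declining"])
        & model["sufficient_n"]
        & np.isfinite(model[mst_col])
    ]
    outliers = cal_mod.flag_outliers(
        model.rename(columns={mst_col: "x", "mean_sci": "y"}),
        exclude_ids=config.exclude_ids,
    )
    model = model[model["population_id"].isin(outliers.retained_ids)]
    if len(model) < 5:
        raise PearlclimError("stage 'calibration' failed: fewer than 5 usable sites")
    cal = cal_mod.fit_calibration(model[mst_col], model["mean_sci"])
    cv = cal_mod.kfold_cv(
        model[mst_col].to_numpy(), model["mean_sci"].to_numpy(),
        k=config.cv_k, seed=config.seed,
    )
    moran = cal_mod.morans_i(model["mean_sci"], model["lat"], model["lon"])
    ranking = cal_mod.compare_predictors(
        site_frame[site_frame["population_id"].isin(model["population_id"])]
        .drop(columns="population_id"),
        model["mean_sci"].to_numpy(),
    )
    ranking.to_csv(out / "predictor_ranking.csv", index=False)
    cv.fold_metrics.to_csv(out / "cv_folds.csv", index=False)
    pd.DataFrame(
        [{
            "intercept": cal.intercept, "slope": cal.slope, "pearson_r": cal.pearson_r,
            "f_stat": cal.f_stat, "df_num": cal.df_num, "df_den": cal.df_den,
            "p": cal.p, "n": cal.n, "residual_sd": cal.residual_sd,
            "pooled_mape": cv.pooled_mape, "pooled_tofallis": cv.pooled_tofallis,
            "pooled_minmax": cv.pooled_minmax,
            "moran_i": moran.observed_i, "moran_expected": moran.expected_i,
            "moran_variance": moran.variance, "moran_z": moran.z_score,
            "moran_p": moran.p,
        }]
    ).to_csv(out / "calibration.csv", index=False)
    manifest["stages"]["calibration"] = {
        "status": "complete", "n_model": int(cal.n),
        "slope": cal.slope, "intercept": cal.intercept,
        "excluded": outliers.excluded_ids, "flagged": outliers.flagged_ids,
    }

    # -- stage 4: growth (optional) ---------------------------------------
    pop_mean_k: dict[str, float] = {}
    if config.rings_csv and Path(config.rings_csv).exists():
        rings_df = pd.read_csv(config.rings_csv)
        fits_by_pop: dict[str, list] = {}
        for sid, grp in rings_df.sort_values("ring_index").groupby("shell_id"):
            series = growth_mod.GrowthRingSeries(
                str(sid), tuple(grp["cumulative_length_mm"].to_numpy(float))
            )
            pid = str(grp["population_id"].iloc[0]) if "population_id" in grp else str(sid)
            fit = growth_mod.estimate_growth(series)
            if isinstance(fit, growth_mod.GrowthFit):
                fits_by_pop.setdefault(pid, []).append(fit)
        pop_mean_k = growth_mod.mean_k_by_population(fits_by_pop)
        pd.DataFrame(
            [{"population_id": pid, "mean_k": k} for pid, k in pop_mean_k.items()]
        ).to_csv(out / "growth.csv", index=False)
        manifest["stages"]["growth"] = {
            "status": "complete", "n_populations": len(pop_mean_k)
        }
    else:
        logger.warning("growth stage skipped: no rings file")
        manifest["stages"]["growth"] = {"status": "skipped", "reason": "no rings file"}

    # -- stage 5: thresholds ----------------------------------------------
    if config.threshold_overrides:
        thresholds = suit_mod.ThresholdSet(**config.threshold_overrides)
    else:
        viable = [p for p in populations if p.status == "viable" and p.sufficient_n]
        declining = [p for p in populations if p.status == "declining" and p.sufficient_n]
        thresholds = suit_mod.derive_thresholds(viable, declining)
    pd.DataFrame(
        [{"a1": thresholds.a1, "a2": thresholds.a2, "a3": thresholds.a3,
          "a4": thresholds.a4, "sem_declining": thresholds.sem_declining}]
    ).to_csv(out / "thresholds.csv", index=False)
    manifest["stages"]["thresholds"] = {
        "status": "complete", "a1": thresholds.a1, "a3": thresholds.a3,
    }

    # -- stage 6: projection / classification ------------------------------
    if config.mask_csv and Path(config.mask_csv).exists():
        mask = io_mod.read_mask_csv(config.mask_csv, grid)
    else:
        mask = np.ones((len(grid.lat_centers), len(grid.lon_centers)), bool)
    maps = []
    for period in config.periods:
        sci_grid = suit_mod.project_sci(grid, mask, tuple(period), cal,
                                        months=config.summer_months)
        smap = suit_mod.classify_cells(sci_grid, thresholds)
        smap.to_frame().to_csv(out / f"suitability_{smap.period}.csv", index=False)
        maps.append(smap)
    shares = suit_mod.area_summary(maps)
    shares.to_csv(out / "area_summary.csv")
    manifest["stages"]["suitability"] = {
        "status": "complete",
        "periods": [m.period for m in maps],
        "viable_share": {m.period: float(shares.loc[m.period, "viable"])
                         for m in maps},
    }

    # -- stage 7: reconstruction -------------------------------------------
    cal_age = cal_mod.LinearCalibration(
        intercept=632.846, slope=-19.122, pearson_r=-0.80, f_stat=48.7,
        df_num=1, df_den=28, p=1e-5, n=30, residual_sd=float("nan"),
    )
    years = range(config.reconstruct_years[0], config.reconstruct_years[1] + 1)
    recon_frames = []
    for p in populations:
        ts = suit_mod.reconstruct_timeseries(p, grid, years, cal, cal_age,
                                             k=config.window_years)
        ts.insert(0, "population_id", p.population_id)
        recon_frames.append(ts)
    recon = pd.concat(recon_frames, ignore_index=True)
    recon.to_csv(out / "reconstruction.csv", index=False)
    manifest["stages"]["reconstruction"] = {
        "status": "complete", "n_rows": int(len(recon))
    }

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
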