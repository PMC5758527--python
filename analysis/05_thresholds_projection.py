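#!/usr/bin/env python
"""Suitability thresholds, gridded projection and century reconstruction.

Derives the A1-A4 convexity thresholds from the viable/declining groups,
projects mean SCI onto the range mask for the cold (1901-1920) and warm
(1991-2010) periods plus a warmed scenario-style late-century grid,
classifies every cell, summarises area shifts, and reconstructs the
1901-2010 SCI / maximum-age series per population. Writes per-period
suitability tables, ``results/area_summary.csv`` and
``results/reconstruction.csv``.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from pearlclim import calibration as cal_mod
from pearlclim import climate as cl
from pearlclim import io as io_mod
from pearlclim import suitability as s

ROOT = Path(__file__).resolve().parent.parent / "results"
SCENARIO_WARMING_C = {"rcp26": 1.0, "rcp45": 1.8, "rcp85": 3.7}


def main() -> None:
    grid = cl.ClimateGrid.from_long_csv(ROOT / "world" / "climate.csv")
    populations = io_mod.read_populations_csv(ROOT / "populations.csv")
    mask = io_mod.read_mask_csv(ROOT / "world" / "mask.csv", grid)
    crow = pd.read_csv(ROOT / "calibration.csv").iloc[0]
    cal = cal_mod.LinearCalibration(
        intercept=float(crow.intercept), slope=float(crow.slope),
        pearson_r=float(crow.pearson_r), f_stat=float(crow.f_stat),
        df_num=1, df_den=int(crow.df_den), p=float(crow.p), n=int(crow.n),
        residual_sd=float(crow.residual_sd),
    )
    arow = pd.read_csv(ROOT / "age_calibration.csv").iloc[0]
    cal_age = cal_mod.LinearCalibration(
        intercept=float(arow.intercept), slope=float(arow.slope),
        pearson_r=float(arow.pearson_r), f_stat=float("nan"), df_num=1,
        df_den=int(arow.n) - 2, p=float("nan"), n=int(arow.n),
        residual_sd=float("nan"),
    )

    viable = [p for p in populations if p.status == "viable"]
    declining = [p for p in populations if p.status == "declining"]
    ts = s.derive_thresholds(viable, declining)
    print(f"thresholds: viable <= {ts.a3:.2f} < declining <= {ts.a1:.2f} "
          f"< unsuitable (A2={ts.a2:.2f}, A4={ts.a4:.2f}, "
          f"s.e.m.={ts.sem_declining:.3f})")
    pd.DataFrame([dataclasses.asdict(ts)]).to_csv(ROOT / "thresholds.csv",
                                                  index=False)

    maps = []
    for period in ((1901, 1920), (1991, 2010)):
        smap = s.classify_cells(s.project_sci(grid, mask, period, cal), ts)
        smap.to_frame().to_csv(ROOT / f"suitability_{smap.period}.csv",
                               index=False)
        maps.append(smap)

    # scenario-style late-century grids: uniform warming offsets applied to
    # the 1991-2010 baseline (a stand-in for downscaled scenario products)
    for scen, delta in SCENARIO_WARMING_C.items():
        warmed = cl.ClimateGrid(grid.lat_centers, grid.lon_centers, grid.years,
                                grid.data + delta, grid.resolution_deg)
        smap = s.classify_cells(
            s.project_sci(warmed, mask, (1991, 2010), cal,
                          label=f"2061-2080_{scen}"), ts
        )
        smap.to_frame().to_csv(ROOT / f"suitability_{smap.period}.csv",
                               index=False)
        maps.append(smap)

    shares = s.area_summary(maps)
    shares.to_csv(ROOT / "area_summary.csv")
    print("area shares (cos-latitude weighted):")
    print(shares.round(3).to_string())
    v = shares["viable"]
    print(f"viable share {v.iloc[0]:.1%} (1901-1920) -> {v.iloc[1]:.1%} "
          f"(1991-2010) -> {v.iloc[-1]:.1%} (extreme scenario)")

    frames = []
    for p in populations:
        rec = s.reconstruct_timeseries(p, grid, range(1901, 2011), cal, cal_age)
        rec.insert(0, "population_id", p.population_id)
        frames.append(rec)
    recon = pd.concat(frames, ignore_index=True)
    recon.to_csv(ROOT / "reconstruction.csv", index=False)
    early = recon[recon["year"] <= 1920]["sci"].mean()
    late = recon[recon["year"] >= 1991]["sci"].mean()
    print(f"reconstruction: mean SCI {early:.2f} (1901-1920) -> {late:.2f} "
          f"(1991-2010); mean A_max "
          f"{recon[recon['year'] <= 1920]['a_max'].mean():.0f} -> "
          f"{recon[recon['year'] >= 1991]['a_max'].mean():.0f} years")


if __name__ == "__main__":
    main()
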