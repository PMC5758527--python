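"""CSV readers/writers for the tabular interchange formats.

All tables are comma-separated, UTF-8, header required, decimal point.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .climate import ClimateGrid
from .growth import GrowthRingSeries
from .morphometry import PopulationSample, ShellRecord

SHELL_COLUMNS = [
    "shell_id", "population_id", "length_mm", "height_mm", "width_mm",
    "year", "lat", "lon", "altitude_m", "status",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_shells_csv(path) -> tuple[list[ShellRecord], dict[str, str]]:
    """Read a shell-measurement table; returns records and per-population status."""
    df = pd.read_csv(path)
    _require_columns(df, SHELL_COLUMNS[:-1], path)
    records = [
        ShellRecord(
            shell_id=str(r.shell_id),
            population_id=str(r.population_id),
            length_mm=float(r.length_mm),
            height_mm=float(r.height_mm),
            width_mm=float(r.width_mm),
            year_collected=int(r.year),
            latitude_deg=float(r.lat),
            longitude_deg=float(r.lon),
            altitude_m=float(r.altitude_m),
        )
        for r in df.itertuples()
    ]
    status = {}
    if "status" in df.columns:
        status = (
            df.groupby("population_id")["status"].first().astype(str).to_dict()
        )
    return records, status


def write_shells_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def populations_to_frame(populations: Sequence[PopulationSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "population_id": p.population_id,
                "n_shells": p.n_shells,
                "mean_sci": p.mean_sci,
                "sem_sci": p.sem_sci,
                "mean_length_mm": p.mean_length_mm,
                "mean_height_mm": p.mean_height_mm,
                "mean_width_mm": p.mean_width_mm,
                "status": p.status,
                "period": p.period,
                "lat": p.latitude_deg,
                "lon": p.longitude_deg,
                "altitude_m": p.altitude_m,
                "year": p.year_collected,
                "max_age_years": p.max_age_years,
                "sufficient_n": p.sufficient_n,
            }
            for p in populations
        ]
    )


def write_populations_csv(populations: Sequence[PopulationSample], path) -> None:
    populations_to_frame(populations).to_csv(path, index=False)


def read_populations_csv(path) -> list[PopulationSample]:
    df = pd.read_csv(path)
    _require_columns(df, ["population_id", "n_shells", "mean_sci"], path)
    return [
        PopulationSample(
            population_id=str(r.population_id),
            n_shells=int(r.n_shells),
            mean_sci=float(r.mean_sci),
            sem_sci=float(getattr(r, "sem_sci", np.nan)),
            mean_length_mm=float(getattr(r, "mean_length_mm", np.nan)),
            mean_height_mm=float(getattr(r, "mean_height_mm", np.nan)),
            mean_width_mm=float(getattr(r, "mean_width_mm", np.nan)),
            status=str(getattr(r, "status", "unknown")),
            period=str(getattr(r, "period", "recent")),
            latitude_deg=float(getattr(r, "lat", np.nan)),
            longitude_deg=float(getattr(r, "lon", np.nan)),
            altitude_m=float(getattr(r, "altitude_m", np.nan)),
            year_collected=int(getattr(r, "year", 0)),
            sufficient_n=bool(getattr(r, "sufficient_n", True)),
        )
        for r in df.itertuples()
    ]


def read_rings_csv(path, fmt: str = "cumulative") -> list[GrowthRingSeries]:
    """Read ring series: columns shell_id, ring_index, then cumulative_length_mm
    or increment_mm depending on ``fmt``."""
    df = pd.read_csv(path)
    value_col = "cumulative_length_mm" if fmt == "cumulative" else "increment_mm"
    _require_columns(df, ["shell_id", "ring_index", value_col], path)
    out = []
    for sid, grp in df.sort_values("ring_index").groupby("shell_id", sort=True):
        vals = grp[value_col].to_numpy(float)
        if fmt == "cumulative":
            out.append(GrowthRingSeries(str(sid), tuple(vals)))
        else:
            out.append(GrowthRingSeries.from_increments(str(sid), vals))
    return out


def write_rings_csv(series_by_pop: dict[str, list[GrowthRingSeries]], path) -> None:
    rows = []
    for pid, series_list in series_by_pop.items():
        for s in series_list:
            for i, length in enumerate(s.lengths_mm, start=1):
                rows.append(
                    {"population_id": pid, "shell_id": s.shell_id,
                     "ring_index": i, "cumulative_length_mm": length}
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mask_csv(path, grid: ClimateGrid) -> np.ndarray:
    """Read a cell mask as (lat_center, lon_center) rows aligned to a grid."""
    df = pd.read_csv(path)
    _require_columns(df, ["lat_center", "lon_center"], path)
    mask = np.zeros((len(grid.lat_centers), len(grid.lon_centers)), bool)
    li = np.searchsorted(grid.lat_centers, df["lat_center"].to_numpy())
    oi = np.searchsorted(grid.lon_centers, df["lon_center"].to_numpy())
    ok = (li < mask.shape[0]) & (oi < mask.shape[1])
    mask[li[ok], oi[ok]] = True
    return mask


def write_mask_csv(mask: np.ndarray, grid: ClimateGrid, path) -> None:
    ii, jj = np.nonzero(mask)
    pd.DataFrame(
        {"lat_center": grid.lat_centers[ii], "lon_center": grid.lon_centers[jj]}
    ).to_csv(path, index=False)
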