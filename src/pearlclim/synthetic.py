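"""Synthetic shell, climate and growth-ring data with the structure the
analysis assumes.

The generator emulates the layout of a continental shell-measurement survey:
a regular 0.5-degree monthly temperature grid with a latitudinal gradient and
a 20th-century warming trend; recent and historical population samples whose
true mean convexity follows the temperature calibration
SCI = 18.207 + 0.666 * MST20 plus population-level noise; per-shell L/H/W
drawn with allometric covariation; and Bertalanffy ring series whose growth
constant increases with summer temperature. Structure is the goal, not
geographic realism.

All randomness flows from ``WorldSpec.seed`` through independent child
generators per product, so the same spec always yields byte-identical
outputs and the products can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import morphometry
from .climate import ClimateGrid, mst_window
from .growth import GrowthRingSeries
from .morphometry import PopulationSample, ShellRecord

#: temperature calibration used generatively (SCI = intercept + slope * MST20)
SCI_INTERCEPT = 18.207
SCI_SLOPE = 0.666
#: longevity calibration used generatively (Amax = intercept + slope * SCI)
AGE_INTERCEPT = 632.846
AGE_SLOPE = -19.122

_SUMMER_SHAPE = (1.0 + 2.0 * math.cos(math.pi / 6)) / 3.0  # mean summer cosine


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of a synthetic world; every product is a pure function of it."""

    seed: int = 0
    # populations
    n_recent: int = 49
    n_historical: int = 13
    recent_years: tuple[int, int] = (1984, 2013)
    historical_years: tuple[int, int] = (1901, 1940)
    shells_recent: tuple[int, int] = (11, 40)
    shells_historical: tuple[int, int] = (5, 15)
    altitude_range_m: tuple[float, float] = (10.0, 180.0)
    # grid geometry
    lat_range: tuple[float, float] = (45.0, 70.0)
    lon_range: tuple[float, float] = (5.0, 25.0)
    resolution_deg: float = 0.5
    years: tuple[int, int] = (1881, 2013)
    # climate: summer-mean profile and seasonality
    mst_ref_c: float = 18.0      # MST at the reference latitude, start of span
    lat_ref_deg: float = 45.0
    lapse_c_per_deg: float = 0.28
    trend_c_per_decade: float = 0.10
    interannual_sd_c: float = 0.8
    seasonal_amplitude_c: float = 9.0
    # shells
    mean_length_mm: float = 80.0
    length_sd_mm: float = 10.0
    height_ratio: float = 0.5
    height_ratio_sd: float = 0.03
    sci_noise_sd: float = 1.1    # population-level noise on the true mean SCI
    width_noise_frac: float = 0.05
    # status labelling rule applied to the true population mean SCI
    viable_max_sci: float = 28.37
    # growth
    mst_window_years: int = 20
    l_inf_range_mm: tuple[float, float] = (95.0, 140.0)
    k_intercept: float = -0.01
    k_slope_per_deg: float = 0.006
    k_noise_sd: float = 0.004
    n_rings: int = 20
    ring_noise_sd_mm: float = 0.3
    shells_per_growth_sample: int = 5

    def __post_init__(self) -> None:
        for name in ("interannual_sd_c", "sci_noise_sd", "k_noise_sd",
                     "ring_noise_sd_mm", "length_sd_mm", "height_ratio_sd",
                     "width_noise_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _rng(spec: WorldSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stream]))


def mst_profile(spec: WorldSpec, lat: np.ndarray, year: np.ndarray) -> np.ndarray:
    """Noise-free target mean summer temperature by latitude and year."""
    return (
        spec.mst_ref_c
        - spec.lapse_c_per_deg * (np.asarray(lat) - spec.lat_ref_deg)
        + spec.trend_c_per_decade * (np.asarray(year) - spec.years[0]) / 10.0
    )


def generate_climate(spec: WorldSpec) -> ClimateGrid:
    """Monthly grid: annual sinusoid (peak July) + latitude/trend profile + noise.

    The sinusoid is centred so that the June-August mean equals the target
    summer profile exactly when noise is zero; interannual noise is drawn
    independently per (year, month, cell) with sd ``interannual_sd_c``, so
    months and seasons are imperfect proxies of one another, as in real
    station-based grids.
    """
    res = spec.resolution_deg
    lats = np.arange(spec.lat_range[0] + res / 2, spec.lat_range[1], res)
    lons = np.arange(spec.lon_range[0] + res / 2, spec.lon_range[1], res)
    years = np.arange(spec.years[0], spec.years[1] + 1)
    months = np.arange(1, 13)

    mst = mst_profile(spec, lats[None, :], years[:, None])  # (year, lat)
    annual_mean = mst - _SUMMER_SHAPE * spec.seasonal_amplitude_c
    season = spec.seasonal_amplitude_c * np.cos(2 * np.pi * (months - 7) / 12.0)
    data = (
        annual_mean[:, None, :, None]
        + season[None, :, None, None]
        + np.zeros((1, 1, 1, len(lons)))
    )
    if spec.interannual_sd_c > 0:
        noise = _rng(spec, 1).normal(
            0.0, spec.interannual_sd_c, size=(len(years), 12, len(lats), len(lons))
        )
        data = data + noise
    return ClimateGrid(lats, lons, years, data, res)


def generate_populations(
    spec: WorldSpec, grid: ClimateGrid
) -> tuple[list[PopulationSample], pd.DataFrame, pd.DataFrame]:
    """Populations + shell table + truth table.

    Returns ``(populations, shells, truth)``: aggregated PopulationSamples
    (computed from the generated shells with the morphometry module, so they
    satisfy its invariants by construction), the per-shell measurement table,
    and the generator's truth (site MST20 and true mean SCI per population).
    One population per grid cell at most, so site coordinates are distinct.
    """
    rng = _rng(spec, 2)
    n_total = spec.n_recent + spec.n_historical
    n_cells = len(grid.lat_centers) * len(grid.lon_centers)
    if n_total > n_cells:
        raise ValueError("more populations than grid cells")
    cells = rng.choice(n_cells, size=n_total, replace=False)
    ci, cj = np.unravel_index(cells, (len(grid.lat_centers), len(grid.lon_centers)))

    populations: list[PopulationSample] = []
    shell_rows: list[dict] = []
    truth_rows: list[dict] = []
    for idx in range(n_total):
        recent = idx < spec.n_recent
        pid = f"{'R' if recent else 'H'}{idx:03d}"
        lo, hi = spec.recent_years if recent else spec.historical_years
        year = int(rng.integers(lo, hi + 1))
        lat = float(grid.lat_centers[ci[idx]])
        lon = float(grid.lon_centers[cj[idx]])
        alt = float(rng.uniform(*spec.altitude_range_m))
        mst20 = mst_window(grid, (int(ci[idx]), int(cj[idx])), year,
                           spec.mst_window_years)
        true_sci = SCI_INTERCEPT + SCI_SLOPE * mst20 + rng.normal(0, spec.sci_noise_sd)

        n_lo, n_hi = spec.shells_recent if recent else spec.shells_historical
        n_shells = int(rng.integers(n_lo, n_hi + 1))
        sigma2 = math.log(1 + (spec.length_sd_mm / spec.mean_length_mm) ** 2)
        mu = math.log(spec.mean_length_mm) - sigma2 / 2
        lengths = rng.lognormal(mu, math.sqrt(sigma2), n_shells)
        heights = lengths * rng.normal(spec.height_ratio, spec.height_ratio_sd,
                                       n_shells)
        widths = (true_sci / 100.0) * lengths * (
            1 + rng.normal(0, spec.width_noise_frac, n_shells)
        )
        heights = np.clip(heights, 1e-3, lengths)
        widths = np.clip(widths, 1e-3, 0.999 * lengths)

        records = []
        for s in range(n_shells):
            rec = ShellRecord(
                shell_id=f"{pid}-{s:03d}",
                population_id=pid,
                length_mm=float(lengths[s]),
                height_mm=float(heights[s]),
                width_mm=float(widths[s]),
                year_collected=year,
                latitude_deg=lat,
                longitude_deg=lon,
                altitude_m=alt,
            )
            records.append(rec)
            shell_rows.append(
                {
                    "shell_id": rec.shell_id,
                    "population_id": pid,
                    "length_mm": rec.length_mm,
                    "height_mm": rec.height_mm,
                    "width_mm": rec.width_mm,
                    "year": year,
                    "lat": lat,
                    "lon": lon,
                    "altitude_m": alt,
                }
            )
        status = (
            ("viable" if true_sci <= spec.viable_max_sci else "declining")
            if recent
            else "historical"
        )
        pop = morphometry.aggregate_population(records, status=status)
        populations.append(pop)
        for row in shell_rows[-n_shells:]:
            row["status"] = status
        truth_rows.append(
            {
                "population_id": pid,
                "mst20": float(mst20),
                "true_sci": float(true_sci),
                "status": status,
                "year": year,
                "lat": lat,
                "lon": lon,
            }
        )
    return populations, pd.DataFrame(shell_rows), pd.DataFrame(truth_rows)


def generate_growth(
    spec: WorldSpec, site_mst: Mapping[str, float]
) -> tuple[dict[str, list[GrowthRingSeries]], pd.DataFrame]:
    """Bertalanffy ring series per population; K rises with site temperature.

    ``site_mst`` maps population id to its mean summer temperature. Each
    population gets ``shells_per_growth_sample`` shells with
    K = k_intercept + k_slope * MST + noise, L_inf uniform in range, and
    Gaussian measurement noise on cumulative lengths (monotonicity enforced).
    """
    rng = _rng(spec, 3)
    series: dict[str, list[GrowthRingSeries]] = {}
    rows = []
    t = np.arange(1, spec.n_rings + 1)
    for pid, mst in site_mst.items():
        series[pid] = []
        for s in range(spec.shells_per_growth_sample):
            k = spec.k_intercept + spec.k_slope_per_deg * mst
            k += rng.normal(0, spec.k_noise_sd)
            k = max(k, 0.01)
            l_inf = rng.uniform(*spec.l_inf_range_mm)
            lengths = l_inf * (1 - np.exp(-k * t))
            if spec.ring_noise_sd_mm > 0:
                lengths = lengths + rng.normal(0, spec.ring_noise_sd_mm, t.size)
                # noise can break monotonicity; restore it with a negligible ramp
                lengths = np.maximum.accumulate(lengths) + 1e-6 * t
            series[pid].append(GrowthRingSeries(f"{pid}-G{s}", tuple(lengths)))
            rows.append({"population_id": pid, "shell_id": f"{pid}-G{s}",
                         "true_k": k, "true_l_inf": l_inf})
    return series, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Small direct designs used for parameter-recovery experiments
# ---------------------------------------------------------------------------

def generate_calibration_dataset(
    rng: np.random.Generator,
    n: int = 49,
    mst_range: tuple[float, float] = (11.0, 18.0),
    noise_sd: float = 1.1,
    intercept: float = SCI_INTERCEPT,
    slope: float = SCI_SLOPE,
) -> tuple[np.ndarray, np.ndarray]:
    """Sites with MST20 ~ Uniform(range) and SCI from the calibration + noise."""
    x = rng.uniform(*mst_range, size=n)
    y = intercept + slope * x + rng.normal(0, noise_sd, size=n)
    return x, y


def generate_age_dataset(
    rng: np.random.Generator,
    n: int = 30,
    sci_range: tuple[float, float] = (24.0, 31.0),
    noise_sd: float = 29.0,
    intercept: float = AGE_INTERCEPT,
    slope: float = AGE_SLOPE,
) -> tuple[np.ndarray, np.ndarray]:
    """Populations with SCI ~ Uniform(range) and max age from the calibration."""
    x = rng.uniform(*sci_range, size=n)
    y = intercept + slope * x + rng.normal(0, noise_sd, size=n)
    return x, y
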