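"""Climate-suitability thresholds, gridded projection and reconstruction.

The SCI thresholds partition predicted mean shell convexity into three
classes:

* viable:     SCI <= A3, where A3 = (A2 + A4) / 2 (midpoint of the group means),
* declining:  A3 < SCI <= A1, where A1 = A2 + 1.96 * s.e.m. of the declining
  group (its 95% upper confidence bound),
* unsuitable: SCI > A1.

A2 and A4 are the unweighted means of per-population mean SCI in the
declining and viable groups. No lower viability bound is imposed: the species
is cold-adapted and its densest populations are northern. Boundaries are
inclusive on the cool side. Projection applies the temperature calibration
to each masked grid cell's period mean summer temperature; class shares are
area-weighted by cos(latitude).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibration import LinearCalibration
from .climate import ClimateGrid, SUMMER_MONTHS, locate_cell, mst_window
from .errors import MaskMismatchError, MissingClimateError, ThresholdDerivationError
from .morphometry import PopulationSample

logger = logging.getLogger("pearlclim.suitability")

CLASS_NAMES = ("viable", "declining", "unsuitable", "no_data")
VIABLE, DECLINING, UNSUITABLE, NO_DATA = range(4)


@dataclass(frozen=True)
class ThresholdSet:
    """Derived SCI class boundaries (see module docstring)."""

    a1: float  # declining/unsuitable boundary (95% upper bound of declining mean)
    a2: float  # mean SCI, declining populations
    a3: float  # viable/declining boundary (midpoint)
    a4: float  # mean SCI, viable populations
    sem_declining: float

    def __post_init__(self) -> None:
        if not (self.a4 < self.a3 <= self.a2 <= self.a1):
            raise ThresholdDerivationError(
                f"threshold ordering violated: a4={self.a4:.3f}, a3={self.a3:.3f}, "
                f"a2={self.a2:.3f}, a1={self.a1:.3f}"
            )


@dataclass
class SciGrid:
    """Per-cell predicted mean SCI for one period/scenario."""

    period: str
    lat_centers: np.ndarray
    lon_centers: np.ndarray
    mask: np.ndarray  # bool (n_lat, n_lon), the digital range model
    sci: np.ndarray  # float (n_lat, n_lon); NaN outside mask or where no data


@dataclass
class SuitabilityMap:
    """Classified suitability grid for one period/scenario."""

    period: str
    lat_centers: np.ndarray
    lon_centers: np.ndarray
    mask: np.ndarray
    sci: np.ndarray
    classes: np.ndarray  # int codes (VIABLE/DECLINING/UNSUITABLE/NO_DATA); -1 outside mask

    def to_frame(self) -> pd.DataFrame:
        """Per-masked-cell table (lat, lon, sci, class)."""
        ii, jj = np.nonzero(self.mask)
        return pd.DataFrame(
            {
                "lat_center": self.lat_centers[ii],
                "lon_center": self.lon_centers[jj],
                "sci": self.sci[ii, jj],
                "class": [CLASS_NAMES[c] for c in self.classes[ii, jj]],
            }
        )


def _mean_sci(populations: Iterable[PopulationSample | float]) -> np.ndarray:
    return np.array(
        [p.mean_sci if isinstance(p, PopulationSample) else float(p)
         for p in populations],
        dtype=float,
    )


def derive_thresholds(
    viable: Sequence[PopulationSample | float],
    declining: Sequence[PopulationSample | float],
) -> ThresholdSet:
    """Derive the A1-A4 SCI thresholds from the two population groups."""
    v = _mean_sci(viable)
    d = _mean_sci(declining)
    if v.size < 2 or d.size < 2:
        raise ThresholdDerivationError("each group needs >= 2 populations")
    a4 = float(v.mean())
    a2 = float(d.mean())
    if a4 >= a2:
        raise ThresholdDerivationError(
            f"groups not separable: viable mean {a4:.3f} >= declining mean {a2:.3f}"
        )
    sem = float(np.std(d, ddof=1) / np.sqrt(d.size))
    if sem == 0:
        warnings.warn("declining s.e.m. is zero: declining/unsuitable boundary "
                      "collapses onto the group mean")
    return ThresholdSet(
        a1=a2 + 1.96 * sem, a2=a2, a3=(a2 + a4) / 2.0, a4=a4, sem_declining=sem
    )


def project_sci(
    grid: ClimateGrid,
    mask: np.ndarray,
    period: tuple[int, int],
    cal: LinearCalibration,
    months: Sequence[int] = SUMMER_MONTHS,
    label: str | None = None,
) -> SciGrid:
    """Predict per-cell mean SCI from the period's mean summer temperature.

    The period MST is the mean over all summer months of the period years
    (equal to the mean of per-year summer means when coverage is complete).
    Cells with any missing month become no-data (NaN).
    """
    y0, y1 = period
    mask = np.asarray(mask, bool)
    if mask.shape != grid.data.shape[2:]:
        raise MaskMismatchError(
            f"mask shape {mask.shape} != grid {grid.data.shape[2:]}"
        )
    if y0 < grid.years[0] or y1 > grid.years[-1]:
        raise MissingClimateError(
            f"period {y0}-{y1} outside grid span {grid.years[0]}-{grid.years[-1]}"
        )
    yi = np.arange(y0 - grid.years[0], y1 - grid.years[0] + 1)
    mi = np.asarray(months) - 1
    block = grid.data[np.ix_(yi, mi)]  # (years, months, lat, lon)
    mst = block.mean(axis=(0, 1))
    mst[np.any(~np.isfinite(block), axis=(0, 1))] = np.nan
    sci = cal.predict(mst)
    sci[~mask] = np.nan
    return SciGrid(
        period=label or f"{y0}-{y1}",
        lat_centers=grid.lat_centers,
        lon_centers=grid.lon_centers,
        mask=mask,
        sci=sci,
    )


def classify_cells(sci_grid: SciGrid, thresholds: ThresholdSet) -> SuitabilityMap:
    """Assign suitability classes: viable <= a3 < declining <= a1 < unsuitable."""
    sci = sci_grid.sci
    classes = np.full(sci.shape, -1, dtype=int)
    inside = sci_grid.mask
    with np.errstate(invalid="ignore"):
        classes[inside & (sci <= thresholds.a3)] = VIABLE
        classes[inside & (sci > thresholds.a3) & (sci <= thresholds.a1)] = DECLINING
        classes[inside & (sci > thresholds.a1)] = UNSUITABLE
    classes[inside & ~np.isfinite(sci)] = NO_DATA
    return SuitabilityMap(
        period=sci_grid.period,
        lat_centers=sci_grid.lat_centers,
        lon_centers=sci_grid.lon_centers,
        mask=inside,
        sci=sci,
        classes=classes,
    )


def area_summary(maps: Sequence[SuitabilityMap]) -> pd.DataFrame:
    """Area-weighted class shares per period (weights: cos of cell latitude).

    Shares are fractions of the total masked area; over the three suitability
    classes they sum to 1 for fully covered masks (no-data is reported as its
    own column).
    """
    if not maps:
        raise ValueError("area_summary: no maps")
    ref = maps[0].mask
    rows = []
    for m in maps:
        if m.mask.shape != ref.shape or not np.array_equal(m.mask, ref):
            raise MaskMismatchError("maps do not share the same mask")
        w = np.cos(np.radians(m.lat_centers))[:, None] * np.ones_like(m.mask, float)
        total = w[m.mask].sum()
        row = {"period": m.period}
        for code, name in enumerate(CLASS_NAMES):
            row[name] = float(w[m.mask & (m.classes == code)].sum() / total)
        rows.append(row)
    return pd.DataFrame(rows).set_index("period")


def reconstruct_timeseries(
    population: PopulationSample,
    grid: ClimateGrid,
    years: Sequence[int],
    cal_sci: LinearCalibration,
    cal_age: LinearCalibration,
    k: int = 20,
) -> pd.DataFrame:
    """Reconstruct yearly mean SCI and maximum age at a population's site.

    For each year y: SCI(y) is the temperature calibration applied to the
    k-year mean summer temperature ending in y-1, and A_max(y) the longevity
    calibration applied to SCI(y). Years whose window is not covered by the
    grid are dropped (with a warning when any are).
    """
    cell = locate_cell(grid, population.latitude_deg, population.longitude_deg)
    rows = []
    skipped = 0
    for y in years:
        try:
            mst = mst_window(grid, cell, int(y), k)
        except MissingClimateError:
            skipped += 1
            continue
        sci = float(cal_sci.predict(mst))
        rows.append(
            {"year": int(y), "mst": mst, "sci": sci,
             "a_max": float(cal_age.predict(sci))}
        )
    if skipped:
        logger.warning(
            "reconstruct_timeseries: %s: %d of %d years lacked the %d-year lead-in",
            population.population_id, skipped, len(list(years)), k,
        )
    return pd.DataFrame(rows)
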