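"""Von Bertalanffy growth estimation from annual shell ring series.

Ring series are cumulative shell lengths at successive annual rings,
L_t = L_inf * (1 - exp(-K t)). The recursive (Ford-Walford) form
L_{t+1} = a + b L_t with b = exp(-K) is fitted by least squares; K = -ln b
and L_inf = a / (1 - b). A logarithmic trend of annual increments on ln(age)
serves as the fallback when the Ford-Walford slope is outside (0, 1).
Population maximum age comes from inverting the growth curve at the longest
shell in the sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    AgeUndefinedError,
    InsufficientDataError,
    NonAsymptoticGrowthError,
)
from .morphometry import CorrelationResult, rank_correlation

logger = logging.getLogger("pearlclim.growth")

#: sampling protocol minimum ring count per shell
MIN_RINGS = 16


@dataclass(frozen=True)
class GrowthRingSeries:
    """Cumulative shell length (mm) at successive annual rings, t = 1..T."""

    shell_id: str
    lengths_mm: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.lengths_mm, float)
        if arr.size < 2:
            raise InsufficientDataError(f"series {self.shell_id}: needs >= 2 rings")
        if np.any(np.diff(arr) <= 0):
            raise ValueError(f"series {self.shell_id}: lengths must strictly increase")
        object.__setattr__(self, "lengths_mm", tuple(float(v) for v in arr))

    @property
    def n_rings(self) -> int:
        return len(self.lengths_mm)

    @property
    def meets_ring_minimum(self) -> bool:
        return self.n_rings >= MIN_RINGS

    @classmethod
    def from_increments(cls, shell_id: str, increments_mm: Sequence[float]
                        ) -> "GrowthRingSeries":
        return cls(shell_id, tuple(np.cumsum(np.asarray(increments_mm, float))))


@dataclass(frozen=True)
class GrowthFit:
    """Bertalanffy growth constants from a Ford-Walford fit."""

    k_const: float
    l_inf_mm: float
    r_squared: float
    method: str = "ford_walford"


@dataclass(frozen=True)
class LogTrendFit:
    """Fallback increment model: delta_L(t) = intercept + slope * ln(t)."""

    intercept: float
    slope: float
    r_squared: float
    method: str = "log_trend"


def ford_walford(series: GrowthRingSeries) -> GrowthFit:
    """Estimate K and L_inf from the L_{t+1}-on-L_t regression."""
    lengths = np.asarray(series.lengths_mm)
    if lengths.size < 5:
        raise InsufficientDataError(
            f"series {series.shell_id}: Ford-Walford needs >= 4 length pairs"
        )
    lt, lt1 = lengths[:-1], lengths[1:]
    res = stats.linregress(lt, lt1)
    b, a = res.slope, res.intercept
    if not (0.0 < b < 1.0):
        raise NonAsymptoticGrowthError(
            f"series {series.shell_id}: Ford-Walford slope {b:.4f} outside (0, 1)"
        )
    return GrowthFit(
        k_const=float(-math.log(b)),
        l_inf_mm=float(a / (1.0 - b)),
        r_squared=float(res.rvalue**2),
    )


def age_from_length(fit: GrowthFit, length_mm: float) -> float:
    """Invert the growth curve: t = -ln(1 - L/L_inf) / K."""
    if length_mm >= fit.l_inf_mm:
        raise AgeUndefinedError(
            f"length {length_mm:.1f} mm >= asymptotic length {fit.l_inf_mm:.1f} mm"
        )
    if length_mm < 0:
        raise ValueError("negative length")
    return float(-math.log(1.0 - length_mm / fit.l_inf_mm) / fit.k_const)


def log_trend_age(series: GrowthRingSeries) -> LogTrendFit:
    """Fit annual increments against ln(age); fallback growth description.

    The increment at age 1 is the first ring length. Non-positive increments
    (measurement noise artefacts) are excluded with a warning.
    """
    lengths = np.asarray(series.lengths_mm)
    if lengths.size < 5:
        raise InsufficientDataError("log_trend_age: needs >= 5 rings")
    increments = np.diff(lengths, prepend=0.0)
    t = np.arange(1, lengths.size + 1, dtype=float)
    ok = increments > 0
    if not ok.all():
        logger.warning(
            "series %s: excluding %d non-positive increments",
            series.shell_id, int((~ok).sum()),
        )
    res = stats.linregress(np.log(t[ok]), increments[ok])
    return LogTrendFit(float(res.intercept), float(res.slope), float(res.rvalue**2))


def estimate_growth(series: GrowthRingSeries) -> GrowthFit | LogTrendFit:
    """Ford-Walford fit with the logarithmic-trend fallback."""
    try:
        return ford_walford(series)
    except NonAsymptoticGrowthError:
        logger.warning("series %s: Ford-Walford failed, using log trend",
                       series.shell_id)
        return log_trend_age(series)


def mean_k_by_population(
    fits_by_population: Mapping[str, Sequence[GrowthFit]]
) -> dict[str, float]:
    """Per-population mean growth constant over its fitted shells."""
    return {
        pid: float(np.mean([f.k_const for f in fits]))
        for pid, fits in fits_by_population.items()
        if fits
    }


def growth_vs_sci(
    fits: Sequence[GrowthFit | float], scis: Sequence[float]
) -> CorrelationResult:
    """Spearman correlation of per-population mean K against mean SCI."""
    ks = [f.k_const if isinstance(f, GrowthFit) else float(f) for f in fits]
    return rank_correlation(ks, scis)
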