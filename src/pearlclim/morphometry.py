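"""Shell morphometrics and population-level statistics.

The unit of inference throughout is the *population mean*: per-shell convexity
indices are averaged within a population sample, and all cross-population
tests (t-tests, ANCOVA-style general linear models, separate-slopes models,
correlations) operate on those means.

Conventions
-----------
* SCI (shell convexity index) = 100 * width / length, dimensionless.
* SCI_I (integrated convexity) = 100 * width / sqrt(pi * length * height);
  the sagittal area is taken as pi * L * H, so the constant scale factor is
  absorbed into the index.
* Shells shorter than 50 mm are excluded before aggregation (ontogenetic
  heterogeneity filter); the boundary itself (L = 50 mm) is retained.
* Population status ("viable" / "declining") is an input label from field
  assessment, never computed here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .errors import (
    DegenerateDistributionError,
    InsufficientDataError,
    InvalidMeasurementError,
    ModelFitError,
    UndefinedCorrelationError,
)

logger = logging.getLogger("pearlclim.morphometry")

MIN_SHELL_LENGTH_MM = 50.0
#: minimum sample sizes by collection period
MIN_N_HISTORICAL = 5
MIN_N_RECENT = 11
#: first collection year counted as "recent" (historical samples are ~1840-1940)
RECENT_FROM_YEAR = 1950
#: altitude split used for lowland / mountain sub-analyses (metres a.s.l.)
LOWLAND_BELOW_M = 200.0
MOUNTAIN_ABOVE_M = 300.0


@dataclass(frozen=True)
class ShellRecord:
    """A single measured shell: three caliper dimensions plus site metadata."""

    shell_id: str
    population_id: str
    length_mm: float
    height_mm: float
    width_mm: float
    year_collected: int
    latitude_deg: float = float("nan")
    longitude_deg: float = float("nan")
    altitude_m: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.length_mm >= self.height_mm > 0):
            raise InvalidMeasurementError(
                f"shell {self.shell_id}: require L >= H > 0 "
                f"(L={self.length_mm}, H={self.height_mm})"
            )
        if not (0 < self.width_mm < self.length_mm):
            raise InvalidMeasurementError(
                f"shell {self.shell_id}: require 0 < W < L "
                f"(W={self.width_mm}, L={self.length_mm})"
            )


@dataclass
class PopulationSample:
    """Per-population aggregate of shell measurements."""

    population_id: str
    n_shells: int
    mean_sci: float
    sem_sci: float
    mean_length_mm: float
    mean_height_mm: float
    mean_width_mm: float
    status: str = "unknown"  # viable | declining | historical | unknown
    period: str = "recent"  # historical | recent
    latitude_deg: float = float("nan")
    longitude_deg: float = float("nan")
    altitude_m: float = float("nan")
    year_collected: int = 0
    max_age_years: float | None = None
    #: whether n_shells meets the period-specific minimum for inference
    sufficient_n: bool = True


class GlmTerm(NamedTuple):
    name: str
    ss: float
    df: int
    f_stat: float
    p: float


@dataclass
class GlmResult:
    """Minimal-adequate general linear model with Type III per-term tests."""

    terms: list[GlmTerm]
    r_squared: float
    retained_terms: list[str]
    formula: str = ""


class TTestResult(NamedTuple):
    t_stat: float
    df: int
    p: float


class SeparateSlopesResult(NamedTuple):
    f_stat: float
    df_num: int
    df_den: int
    p: float


class CorrelationResult(NamedTuple):
    statistic: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# Shell indices
# ---------------------------------------------------------------------------

def compute_sci(shell: ShellRecord) -> float:
    """Shell convexity index, 100 * W / L."""
    if shell.length_mm <= 0:
        raise InvalidMeasurementError(f"shell {shell.shell_id}: non-positive length")
    return 100.0 * shell.width_mm / shell.length_mm


def compute_sci_integrated(shell: ShellRecord) -> float:
    """Integrated convexity index, 100 * W / sqrt(pi * L * H).

    The sagittal area is taken as pi * L * H; a true ellipse would carry a
    factor 1/4, but the constant only rescales the index and is omitted.
    """
    if shell.length_mm <= 0 or shell.height_mm <= 0:
        raise InvalidMeasurementError(
            f"shell {shell.shell_id}: non-positive length or height"
        )
    sa = math.pi * shell.length_mm * shell.height_mm
    return 100.0 * shell.width_mm / math.sqrt(sa)


def filter_shells(
    records: Sequence[ShellRecord], min_length_mm: float = MIN_SHELL_LENGTH_MM
) -> list[ShellRecord]:
    """Drop shells shorter than ``min_length_mm`` (boundary retained)."""
    kept = [r for r in records if r.length_mm >= min_length_mm]
    removed = len(records) - len(kept)
    if removed:
        logger.info("filter_shells: removed %d of %d shells (< %.1f mm)",
                    removed, len(records), min_length_mm)
    if not kept and records:
        logger.warning("filter_shells: all %d shells below %.1f mm; empty result",
                       len(records), min_length_mm)
    return kept


def aggregate_population(
    records: Sequence[ShellRecord],
    *,
    population_id: str | None = None,
    status: str = "unknown",
    recent_from_year: int = RECENT_FROM_YEAR,
) -> PopulationSample:
    """Aggregate shells of one population to its sample means.

    The population mean SCI is the arithmetic mean of per-shell indices (not
    the index of mean dimensions); the s.e.m. uses the sample (ddof=1)
    standard deviation and is NaN for a single shell.
    """
    if not records:
        raise InsufficientDataError("aggregate_population: no shells")
    pid = population_id or records[0].population_id
    scis = np.array([compute_sci(r) for r in records], dtype=float)
    n = len(records)
    sem = float(np.std(scis, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    year = int(round(float(np.median([r.year_collected for r in records]))))
    period = "recent" if year >= recent_from_year else "historical"
    min_n = MIN_N_RECENT if period == "recent" else MIN_N_HISTORICAL
    sufficient = n >= min_n
    if not sufficient:
        logger.warning(
            "population %s: n=%d below the %s minimum (%d); flagged for exclusion",
            pid, n, period, min_n,
        )
    if period == "historical" and status == "unknown":
        status = "historical"
    return PopulationSample(
        population_id=pid,
        n_shells=n,
        mean_sci=float(scis.mean()),
        sem_sci=sem,
        mean_length_mm=float(np.mean([r.length_mm for r in records])),
        mean_height_mm=float(np.mean([r.height_mm for r in records])),
        mean_width_mm=float(np.mean([r.width_mm for r in records])),
        status=status,
        period=period,
        latitude_deg=float(np.mean([r.latitude_deg for r in records])),
        longitude_deg=float(np.mean([r.longitude_deg for r in records])),
        altitude_m=float(np.mean([r.altitude_m for r in records])),
        year_collected=year,
        sufficient_n=sufficient,
    )


def split_by_altitude(
    populations: Iterable[PopulationSample],
) -> tuple[list[PopulationSample], list[PopulationSample]]:
    """Return (lowland, mountain) subsets: altitude < 200 m and > 300 m.

    Sites in the 200-300 m band belong to neither subset.
    """
    pops = list(populations)
    lowland = [p for p in pops if p.altitude_m < LOWLAND_BELOW_M]
    mountain = [p for p in pops if p.altitude_m > MOUNTAIN_ABOVE_M]
    return lowland, mountain


# ---------------------------------------------------------------------------
# Inter-population inference
# ---------------------------------------------------------------------------

def compare_group_means(
    group_a: Sequence[PopulationSample], group_b: Sequence[PopulationSample]
) -> TTestResult:
    """Pooled-variance two-sample t-test on per-population mean SCI.

    Degrees of freedom are n_a + n_b - 2 (Student, not Welch).
    """
    a = np.array([p.mean_sci for p in group_a], dtype=float)
    b = np.array([p.mean_sci for p in group_b], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("compare_group_means: each group needs >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(t), len(a) + len(b) - 2, float(p))


def _lilliefors_statistic(x: np.ndarray) -> float:
    """KS distance of standardized data against N(0,1), parameters estimated."""
    n = x.size
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = ndtr(z)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    return float(max(d_plus, d_minus))


@lru_cache(maxsize=32)
def _lilliefors_null_table(n: int, n_draws: int, seed: int) -> tuple[float, ...]:
    """Monte-Carlo null distribution of the Lilliefors statistic at size n."""
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_draws, n))
    draws = (draws - draws.mean(axis=1, keepdims=True)) / draws.std(axis=1, ddof=1, keepdims=True)
    draws.sort(axis=1)
    cdf = ndtr(draws)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=1)
    d_minus = (cdf - (i - 1) / n).max(axis=1)
    return tuple(np.maximum(d_plus, d_minus))


def normality_check(
    values: Sequence[float], *, n_draws: int = 10_000, seed: int = 171
) -> CorrelationResult:
    """Lilliefors-corrected Kolmogorov-Smirnov normality test.

    The p-value is Monte-Carlo: the fraction of ``n_draws`` null samples
    (standard normal, parameters re-estimated) whose statistic is at least the
    observed one, with the +1 continuity correction. The null table is cached
    per sample size, so repeated checks at one n are cheap.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise InsufficientDataError("normality_check: need n >= 4")
    if np.ptp(x) == 0:
        raise DegenerateDistributionError("normality_check: constant input")
    d = _lilliefors_statistic(x)
    null = np.array(_lilliefors_null_table(x.size, n_draws, seed))
    p = (1 + int(np.sum(null >= d))) / (n_draws + 1)
    return CorrelationResult(d, float(p), int(x.size))


# ---------------------------------------------------------------------------
# General linear models on population means
# ---------------------------------------------------------------------------

_TERM_ALIASES = {
    "Intercept": "intercept",
    "mean_length_mm": "length",
    "C(group, Sum)": "population_group",
    "mean_length_mm:C(group, Sum)": "length:population_group",
    "Residual": "error",
}


def _populations_frame(populations: Sequence[PopulationSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "population_id": [p.population_id for p in populations],
            "mean_sci": [p.mean_sci for p in populations],
            "mean_length_mm": [p.mean_length_mm for p in populations],
            "mean_width_mm": [p.mean_width_mm for p in populations],
            "latitude_deg": [p.latitude_deg for p in populations],
            "altitude_m": [p.altitude_m for p in populations],
            "status": [p.status for p in populations],
            "period": [p.period for p in populations],
            "n_shells": [p.n_shells for p in populations],
        }
    )


def fit_width_glm(
    populations: Sequence[PopulationSample],
    group_factor: str = "status",
    alpha: float = 0.05,
) -> GlmResult:
    """ANCOVA of mean shell width on mean length and a two-level group factor.

    Fits ``width ~ length * group`` with Sum (effects) coding and Type III
    sums of squares, then simplifies to the minimal adequate model by
    sequential exclusion: the interaction first, then any non-significant
    main effect (largest p first), refitting after each removal.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    data = _populations_frame(populations).rename(columns={group_factor: "group"})
    levels = sorted(data["group"].unique())
    if len(levels) != 2:
        raise ModelFitError(f"fit_width_glm: need exactly 2 group levels, got {levels}")
    counts = data["group"].value_counts()
    if counts.min() < 3:
        raise InsufficientDataError(
            f"fit_width_glm: need >= 3 populations per level, got {counts.to_dict()}"
        )

    terms = ["mean_length_mm", "C(group, Sum)", "mean_length_mm:C(group, Sum)"]

    def _fit(current: list[str]):
        formula = "mean_width_mm ~ " + " + ".join(current) if current else "mean_width_mm ~ 1"
        fit = smf.ols(formula, data=data).fit()
        table = anova_lm(fit, typ=3)
        return formula, fit, table

    while True:
        formula, fit, table = _fit(terms)
        pvals = table["PR(>F)"]
        # interaction is always the first candidate for removal
        if "mean_length_mm:C(group, Sum)" in terms:
            if pvals["mean_length_mm:C(group, Sum)"] >= alpha:
                terms.remove("mean_length_mm:C(group, Sum)")
                continue
            break  # significant interaction: keep the full model
        candidates = {t: pvals[t] for t in terms if pvals[t] >= alpha}
        if not candidates or len(terms) == 0:
            break
        worst = max(candidates, key=candidates.get)
        terms.remove(worst)
        if not terms:
            formula, fit, table = _fit(terms)
            break

    result_terms = [
        GlmTerm(
            _TERM_ALIASES.get(idx, idx),
            float(row["sum_sq"]),
            int(row["df"]),
            float(row["F"]) if np.isfinite(row["F"]) else float("nan"),
            float(row["PR(>F)"]) if np.isfinite(row["PR(>F)"]) else float("nan"),
        )
        for idx, row in table.iterrows()
    ]
    return GlmResult(
        terms=result_terms,
        r_squared=float(fit.rsquared),
        retained_terms=[_TERM_ALIASES.get(t, t) for t in terms],
        formula=formula,
    )


def separate_slopes_test(
    populations: Sequence[PopulationSample],
) -> SeparateSlopesResult:
    """Test whether latitude affects mean SCI differently by collection period.

    Compares the full model (period-specific intercepts and slopes of
    mean SCI on latitude) against the single common line by an F-test with
    2 numerator degrees of freedom.
    """
    pops = list(populations)
    lat = np.array([p.latitude_deg for p in pops], dtype=float)
    sci = np.array([p.mean_sci for p in pops], dtype=float)
    if np.any(~np.isfinite(lat)):
        raise ModelFitError("separate_slopes_test: missing latitude")
    periods = np.array([p.period for p in pops])
    levels = sorted(set(periods))
    if len(levels) != 2:
        raise ModelFitError(f"separate_slopes_test: need 2 periods, got {levels}")
    for lev in levels:
        if np.sum(periods == lev) < 3:
            raise InsufficientDataError(
                f"separate_slopes_test: < 3 populations in period {lev!r}"
            )
    n = len(pops)
    ind = (periods == levels[1]).astype(float)
    x_full = np.column_stack([np.ones(n), lat, ind, lat * ind])
    x_red = np.column_stack([np.ones(n), lat])

    def _ssr(x: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(x, sci, rcond=None)
        resid = sci - x @ beta
        return float(resid @ resid)

    ssr_full = _ssr(x_full)
    ssr_red = _ssr(x_red)
    df_num, df_den = 2, n - 4
    if df_den <= 0:
        raise InsufficientDataError("separate_slopes_test: too few populations")
    f = ((ssr_red - ssr_full) / df_num) / (ssr_full / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return SeparateSlopesResult(float(f), df_num, df_den, p)


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation (average ranks on ties)."""
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    _check_corr_inputs(xa, ya)
    rho, p = stats.spearmanr(xa, ya)
    return CorrelationResult(float(rho), float(p), int(xa.size))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with t-based two-sided p."""
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    _check_corr_inputs(xa, ya)
    r, p = stats.pearsonr(xa, ya)
    return CorrelationResult(float(r), float(p), int(xa.size))


def _check_corr_inputs(x: np.ndarray, y: np.ndarray) -> None:
    if x.size != y.size:
        raise InsufficientDataError("correlation: unequal lengths")
    if x.size < 5:
        raise InsufficientDataError("correlation: need n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation: constant vector")
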