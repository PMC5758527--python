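"""Temperature calibration regressions, cross-validation and spatial checks.

Two ordinary-least-squares calibrations sit at the core of the analysis:

* mean SCI on 20-year mean summer temperature (the temperature calibration),
* population maximum age on mean SCI (the longevity calibration).

Validation follows the original protocol: seeded 5-fold cross-validation
scored by MAPE, the log-accuracy-ratio (Tofallis) measure and min-max
accuracy; a Moran's I check (inverse great-circle-distance weights, variance
under the normality assumption) for spatial autocorrelation of the modelled
values; and outlier handling by explicit identifier list and/or externally
studentized residuals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    MeasureUndefinedError,
    ModelFitError,
)

logger = logging.getLogger("pearlclim.calibration")

EARTH_RADIUS_KM = 6371.0
#: duplicate-coordinate guard for inverse-distance weights
MIN_DISTANCE_KM = 1.0
OUTLIER_THRESHOLD = 2.5


@dataclass(frozen=True)
class LinearCalibration:
    """A fitted simple linear regression y = intercept + slope * x."""

    intercept: float
    slope: float
    pearson_r: float
    f_stat: float
    df_num: int
    df_den: int
    p: float
    n: int
    residual_sd: float

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, float)


@dataclass
class CvReport:
    """k-fold cross-validation accuracy report."""

    k: int
    seed: int | None
    fold_metrics: pd.DataFrame  # per fold: mape, tofallis, minmax, slope, intercept, n
    pooled_mape: float
    pooled_tofallis: float
    pooled_minmax: float


@dataclass(frozen=True)
class MoranResult:
    observed_i: float
    expected_i: float
    variance: float
    z_score: float
    p: float
    n: int


@dataclass
class OutlierReport:
    flagged_ids: list
    excluded_ids: list
    retained_ids: list
    studentized: pd.Series


def fit_calibration(x: Sequence[float], y: Sequence[float]) -> LinearCalibration:
    """Ordinary least squares of y on x with r, F(1, n-2) and two-sided p."""
    xa = np.asarray(x, float)
    ya = np.asarray(y, float)
    if xa.size != ya.size:
        raise InsufficientDataError("fit_calibration: unequal lengths")
    if xa.size < 5:
        raise InsufficientDataError("fit_calibration: need n >= 5")
    if np.ptp(xa) == 0:
        raise ModelFitError("fit_calibration: constant predictor")
    res = stats.linregress(xa, ya)
    n = xa.size
    resid = ya - (res.intercept + res.slope * xa)
    residual_sd = float(np.sqrt(resid @ resid / (n - 2)))
    t = res.slope / res.stderr if res.stderr > 0 else np.inf
    return LinearCalibration(
        intercept=float(res.intercept),
        slope=float(res.slope),
        pearson_r=float(res.rvalue),
        f_stat=float(t * t),
        df_num=1,
        df_den=n - 2,
        p=float(res.pvalue),
        n=n,
        residual_sd=residual_sd,
    )


def predict(cal: LinearCalibration, x):
    """Evaluate the fitted line at x (scalar or array)."""
    out = cal.predict(x)
    return float(out) if np.isscalar(x) else out


# ---------------------------------------------------------------------------
# Predictor selection
# ---------------------------------------------------------------------------

def compare_predictors(
    candidates: pd.DataFrame, sci_means: Sequence[float]
) -> pd.DataFrame:
    """Rank candidate climatic predictors by |Pearson r| against mean SCI.

    ``candidates`` holds one column per variable (rows aligned with
    ``sci_means``); all-missing or constant columns are excluded with a
    warning. Ties in |r| are broken alphabetically by variable name.
    """
    y = np.asarray(sci_means, float)
    numeric = candidates.select_dtypes(include=[np.number])
    if numeric.shape[1] < 2:
        raise InsufficientDataError("compare_predictors: need >= 2 candidates")
    rows = []
    for name in numeric.columns:
        col = numeric[name].to_numpy(float)
        ok = np.isfinite(col) & np.isfinite(y)
        if ok.sum() < 5 or np.ptp(col[ok]) == 0:
            logger.warning("compare_predictors: excluding %r (missing or constant)", name)
            continue
        r, p = stats.pearsonr(col[ok], y[ok])
        rows.append({"variable": name, "r": float(r), "p": float(p), "n": int(ok.sum())})
    table = pd.DataFrame(rows)
    table["abs_r"] = table["r"].abs()
    table = table.sort_values(
        ["abs_r", "variable"], ascending=[False, True], kind="mergesort"
    ).drop(columns="abs_r").reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def mape(obs: np.ndarray, pred: np.ndarray) -> float:
    """Mean absolute percentage error, in percent."""
    return float(np.mean(np.abs(pred - obs) / obs) * 100.0)


def tofallis_accuracy(obs: np.ndarray, pred: np.ndarray) -> float:
    """Mean absolute natural-log accuracy ratio, mean(|ln(pred/obs)|)."""
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise MeasureUndefinedError("log accuracy ratio needs positive obs and pred")
    return float(np.mean(np.abs(np.log(pred / obs))))


def minmax_accuracy(obs: np.ndarray, pred: np.ndarray) -> float:
    """Mean of min(obs, pred) / max(obs, pred)."""
    return float(np.mean(np.minimum(obs, pred) / np.maximum(obs, pred)))


def kfold_cv(
    x: Sequence[float],
    y: Sequence[float],
    k: int = 5,
    seed: int | None = None,
) -> CvReport:
    """Seeded k-fold cross-validation of the simple linear calibration.

    Observations are partitioned uniformly at random into k folds of
    near-equal size (any remainder spread one per fold); each fold is
    predicted from the line fitted on the remaining k-1 folds. Accuracy
    measures are reported per fold and pooled over all held-out points.
    With k = n (leave-one-out) the result is partition-independent.
    """
    xa = np.asarray(x, float)
    ya = np.asarray(y, float)
    n = xa.size
    if not (2 <= k <= n):
        raise InsufficientDataError(f"kfold_cv: need n >= k >= 2, got n={n}, k={k}")
    if np.any(ya <= 0):
        raise MeasureUndefinedError("kfold_cv: percentage measures need y > 0")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    pooled_obs, pooled_pred = [], []
    rows = []
    for f, test_idx in enumerate(folds):
        train = np.setdiff1d(order, test_idx)
        cal = fit_calibration(xa[train], ya[train])
        pred = cal.predict(xa[test_idx])
        obs = ya[test_idx]
        if np.any(pred <= 0):
            raise MeasureUndefinedError("kfold_cv: non-positive prediction")
        rows.append(
            {
                "fold": f,
                "n": len(test_idx),
                "slope": cal.slope,
                "intercept": cal.intercept,
                "mape": mape(obs, pred),
                "tofallis": tofallis_accuracy(obs, pred),
                "minmax": minmax_accuracy(obs, pred),
            }
        )
        pooled_obs.append(obs)
        pooled_pred.append(pred)
    obs = np.concatenate(pooled_obs)
    pred = np.concatenate(pooled_pred)
    return CvReport(
        k=k,
        seed=seed,
        fold_metrics=pd.DataFrame(rows),
        pooled_mape=mape(obs, pred),
        pooled_tofallis=tofallis_accuracy(obs, pred),
        pooled_minmax=minmax_accuracy(obs, pred),
    )


# ---------------------------------------------------------------------------
# Spatial autocorrelation
# ---------------------------------------------------------------------------

def great_circle_km(
    lat1: np.ndarray, lon1: np.ndarray, lat2: np.ndarray, lon2: np.ndarray
) -> np.ndarray:
    """Haversine great-circle distance in km (broadcasting)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def morans_i(
    values: Sequence[float],
    lat: Sequence[float],
    lon: Sequence[float],
    min_distance_km: float = MIN_DISTANCE_KM,
) -> MoranResult:
    """Moran's I with inverse great-circle-distance weights.

    Weights w_ij = 1 / d_ij (km) are left unstandardized. Duplicate or
    near-duplicate coordinates have their pair distance floored at
    ``min_distance_km`` (warning emitted). The expectation is -1/(n-1) and
    the variance follows the normality assumption; p is two-sided normal.
    """
    v = np.asarray(values, float)
    la = np.asarray(lat, float)
    lo = np.asarray(lon, float)
    n = v.size
    if n < 5:
        raise InsufficientDataError("morans_i: need n >= 5")
    coords = set(zip(la.tolist(), lo.tolist()))
    if len(coords) < 2:
        raise InsufficientDataError("morans_i: need >= 2 distinct locations")
    d = great_circle_km(la[:, None], lo[:, None], la[None, :], lo[None, :])
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] < min_distance_km):
        logger.warning(
            "morans_i: %d site pairs closer than %.1f km; distance floored",
            int(np.sum(d[off] < min_distance_km) // 2), min_distance_km,
        )
        d = np.maximum(d, min_distance_km)
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off]

    z = v - v.mean()
    s0 = w.sum()
    i_obs = (n / s0) * (z @ w @ z) / (z @ z)
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * np.sum((w + w.T) ** 2)
    s2 = np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2)
    var = (n * n * s1 - n * s2 + 3 * s0 * s0) / ((n * n - 1) * s0 * s0) - e_i**2
    zscore = (i_obs - e_i) / math.sqrt(var)
    p = 2 * stats.norm.sf(abs(zscore))
    return MoranResult(float(i_obs), e_i, float(var), float(zscore), float(p), n)


# ---------------------------------------------------------------------------
# Outliers
# ---------------------------------------------------------------------------

def flag_outliers(
    model_data: pd.DataFrame,
    exclude_ids: Sequence | None = None,
    auto_exclude: bool = False,
    threshold: float = OUTLIER_THRESHOLD,
    id_col: str = "population_id",
    x_col: str = "x",
    y_col: str = "y",
) -> OutlierReport:
    """Flag calibration outliers and assemble the retained sample set.

    Two mechanisms: (a) an explicit identifier exclusion list, always removed;
    (b) automatic flagging at |externally studentized residual| > ``threshold``
    on the simple regression of ``y_col`` on ``x_col``, removed only when
    ``auto_exclude`` is set (otherwise merely flagged).
    """
    import statsmodels.api as sm
    from statsmodels.stats.outliers_influence import OLSInfluence

    exclude = list(exclude_ids or [])
    ids = model_data[id_col]
    fit = sm.OLS(
        model_data[y_col].to_numpy(float),
        sm.add_constant(model_data[x_col].to_numpy(float)),
    ).fit()
    student = pd.Series(
        np.asarray(OLSInfluence(fit).resid_studentized_external), index=ids
    )
    flagged = student.index[student.abs() > threshold].tolist()
    removed = set(exclude) | (set(flagged) if auto_exclude else set())
    retained = [i for i in ids if i not in removed]
    if flagged:
        logger.info("flag_outliers: flagged %s (|t| > %.1f)", flagged, threshold)
    return OutlierReport(
        flagged_ids=flagged,
        excluded_ids=sorted(removed, key=str),
        retained_ids=retained,
        studentized=student,
    )
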