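"""Regression machinery for the seasonal isotope calibrations.

Three bundled calibrations ship with the package (see :data:`BUILTIN_CALIBRATIONS`):

``eq5_milk_d18O``
    Quartic of 10³δ¹⁸O_M (‰) on day number, fitted on 84 indoor shed-months
    (outdoor-grazing sheds excluded); s(yx) = 0.92‰.
``eq6a_alpha_all``
    Quartic of the oxygen fractionation factor α on day number, all sheds
    (n = 108); s(yx) = 0.50‰, prediction uncertainty ≈ 0.51‰.
``eq6b_alpha_indoor``
    Same with outdoor-grazing sheds excluded (n = 84); s(yx) = 0.41‰,
    prediction uncertainty ≈ 0.42‰.  This is the default for the second step
    of the provenance check, which targets animals kept indoors.

Units convention: a calibration's ``s_yx`` and ``u_pred`` are always in ‰
of the target quantity — for the α calibrations that means 10³·α units, so
the numbers compare directly with the ‰-scale α differences used in
reporting.  ``predict`` always returns the target in its natural units
(‰ for milk δ, dimensionless for α).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml
from scipy import stats as _stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .core import FractionationFactor, SampleRecord, deuterium_excess
from .errors import (
    IncompleteDesignError,
    InsufficientDataError,
    SingularFitError,
    WindowTooSmallError,
)

__all__ = [
    "WaterLineFit",
    "QuarticCalibration",
    "AnovaTable",
    "TemperatureRegression",
    "PeriodComparison",
    "MilkDeltaPrediction",
    "BUILTIN_CALIBRATIONS",
    "COLD_MONTHS",
    "WARM_MONTHS",
    "fit_water_line",
    "fit_quartic",
    "fit_seasonal_calibrations",
    "loess_smooth",
    "predict_milk_delta",
    "predict_alpha",
    "alpha_prediction_uncertainty",
    "fit_alpha_vs_temperature",
    "two_way_anova",
    "dex_temperature_correlation",
    "periodic_regressions",
    "load_calibration",
    "save_calibration",
]

#: Months defining the cold (stabled, low-evaporation) period.
COLD_MONTHS = (11, 12, 1, 2, 3, 4)
#: Months defining the warm period (outdoor grazing possible).
WARM_MONTHS = (5, 6, 7, 8, 9, 10)

BUILTIN_CALIBRATIONS = ("eq5_milk_d18O", "eq6a_alpha_all", "eq6b_alpha_indoor")

_TARGETS = ("milk_d18O", "alpha")


@dataclass(frozen=True)
class WaterLineFit:
    """OLS line of δ²H on δ¹⁸O (a local meteoric-water-line style fit)."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r2: float
    s_yx: float
    n: int

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass
class QuarticCalibration:
    """A quartic (4th-order polynomial) seasonal calibration in day number.

    ``coefficients`` are (A, B, C, D, E) in descending powers of t, in the
    natural units of the target.  ``s_yx`` and ``u_pred`` are in ‰ of the
    target (10³·α units for an α calibration).  ``u_pred`` may be pinned to
    a published constant; when ``None`` it is derived from ``s_yx`` and ``n``
    by :func:`alpha_prediction_uncertainty`.
    """

    name: str
    target: str
    coefficients: tuple
    n: int
    s_yx: float
    r2: Optional[float] = None
    u_pred: Optional[float] = None
    excluded_sheds: tuple = ()
    version: int = 1

    def __post_init__(self) -> None:
        if self.target not in _TARGETS:
            raise ValueError(f"unknown calibration target {self.target!r}")
        if len(self.coefficients) != 5:
            raise ValueError("a quartic calibration needs exactly 5 coefficients")
        self.coefficients = tuple(float(c) for c in self.coefficients)
        self.excluded_sheds = tuple(self.excluded_sheds)

    @property
    def scale(self) -> float:
        """‰ per natural unit of the target (1000 for α, 1 for milk δ)."""
        return 1000.0 if self.target == "alpha" else 1.0

    def predict(self, t):
        """Evaluate the quartic at day number(s) t, in natural target units."""
        return np.polyval(self.coefficients, np.asarray(t, dtype=float))


@dataclass(frozen=True)
class MilkDeltaPrediction:
    """Seasonal milk-δ prediction with its one-s(yx) and 90% bands (‰)."""

    t: int
    value: float
    s_yx: float
    coverage: float
    band_1s: tuple
    band_coverage: tuple


@dataclass(frozen=True)
class AnovaTable:
    """Two-way ANOVA (no replication) of α by sampling time × shed.

    ``ms_*`` are the mean squares, interpreted as variance components:
    the row (time) component dominating the column (shed) component is the
    signature of a seasonally driven fractionation factor.
    """

    ss_rows: float
    ss_cols: float
    ss_error: float
    df_rows: int
    df_cols: int
    df_error: int

    @property
    def ss_total(self) -> float:
        return self.ss_rows + self.ss_cols + self.ss_error

    @property
    def ms_rows(self) -> float:
        return self.ss_rows / self.df_rows

    @property
    def ms_cols(self) -> float:
        return self.ss_cols / self.df_cols

    @property
    def ms_error(self) -> float:
        return self.ss_error / self.df_error


@dataclass(frozen=True)
class TemperatureRegression:
    """Per-shed line α = B·T̄ + A against 2-week mean temperature."""

    shed_id: str
    slope: float
    slope_se: float
    intercept: float
    r: float
    n: int
    n_skipped: int = 0


@dataclass(frozen=True)
class PeriodComparison:
    """Cold- vs warm-period regressions of milk δ¹⁸O on farm-water δ¹⁸O."""

    cold: WaterLineFit
    warm: WaterLineFit
    p_same_slope: float

    @property
    def intercept_difference(self) -> float:
        return self.warm.intercept - self.cold.intercept


# ---------------------------------------------------------------------------
# line fits


def _ols_line(x: np.ndarray, y: np.ndarray) -> WaterLineFit:
    n = x.size
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0 or not math.isfinite(sxx):
        raise SingularFitError("predictor has zero variance")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    s_yx = math.sqrt(sse / (n - 2)) if n > 2 else 0.0
    slope_se = s_yx / math.sqrt(sxx)
    intercept_se = s_yx * math.sqrt(1.0 / n + x.mean() ** 2 / sxx)
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return WaterLineFit(
        slope=slope,
        slope_se=slope_se,
        intercept=intercept,
        intercept_se=intercept_se,
        r2=max(0.0, min(1.0, r2)),
        s_yx=s_yx,
        n=n,
    )


def fit_water_line(pairs: Iterable[tuple]) -> WaterLineFit:
    """OLS of δ²H on δ¹⁸O for (δ¹⁸O, δ²H) pairs, in ‰.

    Standard errors come from the classical closed-form OLS expressions and
    s(yx) = √(SSE/(n−2)).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise InsufficientDataError("need at least 3 (d18O, d2H) pairs")
    return _ols_line(arr[:, 0], arr[:, 1])


# ---------------------------------------------------------------------------
# quartic seasonal calibrations


def fit_quartic(
    ts: Sequence[float],
    ys: Sequence[float],
    shed_ids: Optional[Sequence[str]] = None,
    exclude: Sequence[str] = (),
    target: str = "milk_d18O",
    name: str = "fitted_quartic",
) -> QuarticCalibration:
    """Least-squares quartic of the target on day number.

    Points whose shed label is in ``exclude`` are dropped before fitting
    (the bundled calibrations exclude the outdoor-grazing sheds this way).
    s(yx) = √(SSE/(n−5)) with 5 fitted parameters; R² is against the mean
    model.  The returned ``s_yx`` is in ‰ of the target.
    """
    ts = np.asarray(ts, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if shed_ids is not None and len(exclude) > 0:
        labels = np.asarray(shed_ids)
        keep = ~np.isin(labels, list(exclude))
        ts, ys = ts[keep], ys[keep]
    n = ts.size
    if n < 6:
        raise InsufficientDataError(f"need ≥6 points for a quartic fit, got {n}")
    if np.unique(ts).size < 5:
        raise SingularFitError("fewer than 5 distinct day numbers: quartic is rank deficient")
    # Fit on t/365 for conditioning, then rescale to raw-power coefficients.
    t_scale = 365.0
    coeffs_scaled = np.polynomial.polynomial.polyfit(ts / t_scale, ys, 4)  # ascending
    coeffs = coeffs_scaled / t_scale ** np.arange(5)
    fitted = np.polynomial.polynomial.polyval(ts, coeffs)
    sse = float(np.sum((ys - fitted) ** 2))
    sst = float(np.sum((ys - ys.mean()) ** 2))
    scale = 1000.0 if target == "alpha" else 1.0
    s_yx = math.sqrt(max(sse, 0.0) / (n - 5)) * scale
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return QuarticCalibration(
        name=name,
        target=target,
        coefficients=tuple(coeffs[::-1]),  # descending powers
        n=int(n),
        s_yx=s_yx,
        r2=max(0.0, min(1.0, r2)),
        u_pred=None,
        excluded_sheds=tuple(exclude),
    )


def fit_seasonal_calibrations(
    records: Sequence[SampleRecord], exclude: Sequence[str] = ()
) -> tuple:
    """Fit the (milk-δ¹⁸O, α) quartic pair from a set of sample records.

    Convenience wrapper used when re-deriving the two calibrations of the
    provenance check from new herd data; returns
    ``(milk_d18O_calibration, alpha_calibration)``.
    """
    from .core import compute_alpha

    rows = [
        r
        for r in records
        if r.t is not None and r.d18O_M is not None and r.d18O_W is not None
    ]
    if len(rows) < 6:
        raise InsufficientDataError("need ≥6 complete records")
    ts = [r.t for r in rows]
    sheds = [r.shed_id for r in rows]
    calib_delta = fit_quartic(
        ts,
        [r.d18O_M for r in rows],
        shed_ids=sheds,
        exclude=exclude,
        target="milk_d18O",
        name="refit_milk_d18O",
    )
    calib_alpha = fit_quartic(
        ts,
        [compute_alpha(r.d18O_M, r.d18O_W).alpha for r in rows],
        shed_ids=sheds,
        exclude=exclude,
        target="alpha",
        name="refit_alpha",
    )
    return calib_delta, calib_alpha


def loess_smooth(
    ts: Sequence[float],
    ys: Sequence[float],
    span: float = 0.2,
    grid: Optional[Sequence[float]] = None,
):
    """LOESS smoother (degree 1, tricube weights, no robustness iterations).

    ``span`` is the fraction of points in each local window; the seasonal
    plots use 0.2.  Returns ``(grid, smoothed)``.
    """
    ts = np.asarray(ts, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if ts.size < 10:
        raise InsufficientDataError("need ≥10 points for LOESS smoothing")
    if span * ts.size < 3:
        raise WindowTooSmallError(
            f"span={span} leaves {span * ts.size:.1f} points per window (<3)"
        )
    if grid is None:
        grid = np.linspace(ts.min(), ts.max(), 101)
    grid = np.asarray(grid, dtype=float)
    smoothed = _sm_lowess(ys, ts, frac=span, it=0, xvals=grid)
    return grid, smoothed


def predict_milk_delta(
    t: int, calib: QuarticCalibration, coverage: float = 1.645
) -> MilkDeltaPrediction:
    """Seasonal milk-water δ¹⁸O prediction (‰) with its scatter bands.

    The ±s(yx) band mirrors the calibration's one-sigma residual scatter;
    the ±coverage·s(yx) band (default coverage 1.645, significance 0.10)
    is the acceptance band of step one of the provenance check.
    """
    if not 1 <= int(t) <= 365:
        raise ValueError(f"day number {t} outside 1..365")
    value = float(calib.predict(int(t)))
    half = coverage * calib.s_yx
    return MilkDeltaPrediction(
        t=int(t),
        value=value,
        s_yx=calib.s_yx,
        coverage=coverage,
        band_1s=(value - calib.s_yx, value + calib.s_yx),
        band_coverage=(value - half, value + half),
    )


def predict_alpha(t: int, calib: QuarticCalibration) -> FractionationFactor:
    """Calibration-predicted fractionation factor α̂ at day number t."""
    if calib.target != "alpha":
        raise ValueError(f"calibration {calib.name!r} does not target alpha")
    if not 1 <= int(t) <= 365:
        raise ValueError(f"day number {t} outside 1..365")
    return FractionationFactor(alpha=float(calib.predict(int(t))), t=int(t))


def alpha_prediction_uncertainty(calib: QuarticCalibration) -> float:
    """Approximate standard prediction uncertainty of α̂, in ‰.

    u = √(s(yx)² + s(yx)²/n).  The exact prediction variance of a quartic
    depends on the design leverage at each t; this leverage-free
    approximation (which understates the true value) is what the bundled
    thresholds are built on.  A calibration may pin ``u_pred`` to a published
    rounded constant, which then takes precedence.
    """
    if calib.u_pred is not None:
        return float(calib.u_pred)
    return math.sqrt(calib.s_yx**2 + calib.s_yx**2 / calib.n)


# ---------------------------------------------------------------------------
# temperature and period structure


def fit_alpha_vs_temperature(records: Sequence[SampleRecord]) -> TemperatureRegression:
    """OLS of the oxygen fractionation factor on 2-week mean temperature.

    Records without a temperature (or without both δ¹⁸O values) are skipped
    and counted in ``n_skipped``.  All records are assumed to come from one
    shed; the label of the first record is reported.
    """
    from .core import compute_alpha

    usable, skipped = [], 0
    for r in records:
        if r.temp_2wk is None or r.d18O_M is None or r.d18O_W is None:
            skipped += 1
            continue
        usable.append((r.temp_2wk, compute_alpha(r.d18O_M, r.d18O_W).alpha))
    if len(usable) < 3:
        raise InsufficientDataError(
            f"need ≥3 records with temperature, got {len(usable)} ({skipped} skipped)"
        )
    arr = np.asarray(usable, dtype=float)
    line = _ols_line(arr[:, 0], arr[:, 1])
    r = float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])
    shed = records[0].shed_id if records else ""
    return TemperatureRegression(
        shed_id=shed,
        slope=line.slope,
        slope_se=line.slope_se,
        intercept=line.intercept,
        r=r,
        n=line.n,
        n_skipped=skipped,
    )


def two_way_anova(matrix) -> AnovaTable:
    """Two-way ANOVA without replication: rows = sampling times, cols = sheds.

    Classical sum-of-squares decomposition with one observation per cell;
    the residual is the row×column interaction plus measurement error.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise IncompleteDesignError("need a 2-D layout with ≥2 rows and ≥2 columns")
    if not np.all(np.isfinite(m)):
        raise IncompleteDesignError("missing cells in the two-way layout")
    r, c = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = c * float(np.sum((row_means - grand) ** 2))
    ss_cols = r * float(np.sum((col_means - grand) ** 2))
    resid = m - row_means[:, None] - col_means[None, :] + grand
    ss_error = float(np.sum(resid**2))
    return AnovaTable(
        ss_rows=ss_rows,
        ss_cols=ss_cols,
        ss_error=ss_error,
        df_rows=r - 1,
        df_cols=c - 1,
        df_error=(r - 1) * (c - 1),
    )


def dex_temperature_correlation(records: Sequence[SampleRecord]) -> float:
    """Pearson R between (d_ex,W − d_ex,M) and the 2-week mean temperature.

    Needs both isotopes for both materials plus a temperature.  Returns NaN
    when the correlation is undefined (zero variance in either variable).
    """
    pairs = []
    for r in records:
        if None in (r.d18O_W, r.d2H_W, r.d18O_M, r.d2H_M, r.temp_2wk):
            continue
        gap = deuterium_excess(r.d2H_W, r.d18O_W) - deuterium_excess(r.d2H_M, r.d18O_M)
        pairs.append((r.temp_2wk, gap))
    if len(pairs) < 3:
        raise InsufficientDataError(f"need ≥3 complete records, got {len(pairs)}")
    arr = np.asarray(pairs, dtype=float)
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        return float("nan")
    return float(_stats.pearsonr(arr[:, 0], arr[:, 1])[0])


def periodic_regressions(
    records: Sequence[SampleRecord], exclude: Sequence[str] = ()
) -> PeriodComparison:
    """Cold- vs warm-period lines of shed-mean milk δ¹⁸O on farm-water δ¹⁸O.

    Cold period = Nov–Apr, warm period = May–Oct.  Records are averaged per
    shed within each period before fitting, so each shed contributes one
    point per period.  The equal-slope test is the standard t-test on the
    slope difference with the two fits' standard errors pooled.
    """
    groups: dict[tuple[str, str], list] = {}
    for r in records:
        if r.shed_id in exclude or r.d18O_M is None or r.d18O_W is None:
            continue
        month = r.month
        if month is None:
            continue
        period = "cold" if month in COLD_MONTHS else "warm"
        groups.setdefault((period, r.shed_id), []).append((r.d18O_W, r.d18O_M))

    fits = {}
    for period in ("cold", "warm"):
        pts = [
            tuple(np.mean(v, axis=0))
            for (p, _), v in sorted(groups.items())
            if p == period
        ]
        if len(pts) < 3:
            raise InsufficientDataError(f"{period} period has {len(pts)} sheds (<3)")
        fits[period] = fit_water_line(pts)

    b1, b2 = fits["cold"].slope, fits["warm"].slope
    se = math.sqrt(fits["cold"].slope_se**2 + fits["warm"].slope_se**2)
    df = fits["cold"].n + fits["warm"].n - 4
    if se == 0:
        p = 1.0
    else:
        tstat = (b1 - b2) / se
        p = float(2 * _stats.t.sf(abs(tstat), df))
    return PeriodComparison(cold=fits["cold"], warm=fits["warm"], p_same_slope=p)


# ---------------------------------------------------------------------------
# calibration files


def load_calibration(name_or_path: str) -> QuarticCalibration:
    """Load a calibration by bundled name or from a YAML file path."""
    if name_or_path in BUILTIN_CALIBRATIONS:
        text = (
            resources.files("isomilk").joinpath(f"data/{name_or_path}.yaml").read_text()
        )
    else:
        with open(name_or_path, "r", encoding="utf-8") as fh:
            text = fh.read()
    payload = yaml.safe_load(text)
    return QuarticCalibration(
        name=payload["name"],
        target=payload["target"],
        coefficients=tuple(payload["coefficients"]),
        n=int(payload["n"]),
        s_yx=float(payload["s_yx_permil"]),
        r2=payload.get("r2"),
        u_pred=payload.get("u_pred_permil"),
        excluded_sheds=tuple(payload.get("excluded_sheds", ())),
        version=int(payload.get("version", 1)),
    )


def save_calibration(calib: QuarticCalibration, path: str) -> None:
    """Write a calibration as versioned key-value YAML."""
    payload = {
        "name": calib.name,
        "version": calib.version,
        "target": calib.target,
        "coefficients": [float(c) for c in calib.coefficients],
        "n": calib.n,
        "s_yx_permil": calib.s_yx,
        "r2": calib.r2,
        "u_pred_permil": calib.u_pred,
        "excluded_sheds": list(calib.excluded_sheds),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
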