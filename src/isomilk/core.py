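"""Fundamental isotope quantities.

All delta values are exchanged in per-mil (‰) on the VSMOW/SLAP scale;
conversion to absolute isotope ratios happens only inside
:func:`compute_alpha` and :func:`milk_delta_from_alpha`.  The fractionation
factor α is kept dimensionless; differences between α values are reported in
‰, i.e. ``10³·(α₁ − α₂)``.

The day number ``t`` is the ordinal day of a non-leap year (1 January → 1,
31 December → 365); 29 February has no day number and is rejected.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Optional, Union

from .errors import InvalidDateError, InvalidMeasurementError, InvalidRecordError

__all__ = [
    "DeltaValue",
    "FractionationFactor",
    "SampleRecord",
    "DEFAULT_UNCERTAINTY",
    "default_uncertainty",
    "compute_alpha",
    "milk_delta_from_alpha",
    "deuterium_excess",
    "day_number",
    "date_of_day_number",
]

#: Standard prediction uncertainties of a single measurement, in ‰,
#: keyed by (isotope, material).
DEFAULT_UNCERTAINTY: dict[tuple[str, str], float] = {
    ("O18_O16", "farm_water"): 0.08,
    ("H2_H1", "farm_water"): 1.0,
    ("O18_O16", "milk_water"): 0.15,
    ("H2_H1", "milk_water"): 1.5,
}

_ISOTOPES = ("O18_O16", "H2_H1")
_MATERIALS = ("farm_water", "milk_water")

# Cumulative days before each month in a non-leap year (February = 28 days).
_MONTH_OFFSETS = (0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334)
_MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


def default_uncertainty(isotope: str, material: str) -> float:
    """Standard prediction uncertainty (‰) of a single delta measurement."""
    try:
        return DEFAULT_UNCERTAINTY[(isotope, material)]
    except KeyError:
        raise InvalidMeasurementError(
            f"no default uncertainty for isotope={isotope!r}, material={material!r}"
        ) from None


def _check_delta(value: float, name: str = "delta") -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidMeasurementError(f"{name} must be finite, got {value!r}")
    if value <= -1000.0:
        raise InvalidMeasurementError(
            f"{name} = {value}‰ implies a non-positive isotope ratio"
        )
    return value


@dataclass(frozen=True)
class DeltaValue:
    """A per-mil deviation from VSMOW with its measurement uncertainty.

    Parameters
    ----------
    value
        δ in ‰ vs VSMOW; must exceed −1000‰ (the isotope ratio stays positive).
    isotope
        ``"O18_O16"`` or ``"H2_H1"``.
    material
        ``"farm_water"`` or ``"milk_water"``.
    uncertainty
        Standard prediction uncertainty in ‰.  Defaults to the stated
        single-measurement values: 0.08‰ / 1‰ for farm water (O / H) and
        0.15‰ / 1.5‰ for milk water.
    """

    value: float
    isotope: str = "O18_O16"
    material: str = "farm_water"
    uncertainty: Optional[float] = None

    def __post_init__(self) -> None:
        _check_delta(self.value, "delta value")
        if self.isotope not in _ISOTOPES:
            raise InvalidMeasurementError(f"unknown isotope {self.isotope!r}")
        if self.material not in _MATERIALS:
            raise InvalidMeasurementError(f"unknown material {self.material!r}")
        if self.uncertainty is None:
            object.__setattr__(
                self, "uncertainty", default_uncertainty(self.isotope, self.material)
            )
        elif self.uncertainty < 0:
            raise InvalidMeasurementError("uncertainty must be non-negative")

    @property
    def ratio_factor(self) -> float:
        """``δ/10³ + 1``, the sample/standard isotope-ratio quotient."""
        return self.value / 1000.0 + 1.0


@dataclass(frozen=True)
class FractionationFactor:
    """Milk-water / farm-water isotope fractionation factor.

    ``alpha`` is the dimensionless ratio of ratio-quotients; values near 1.
    Differences between fractionation factors are conventionally reported in
    ‰ via :meth:`permil_difference`.
    """

    alpha: float
    isotope: str = "O18_O16"
    t: Optional[int] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha) or self.alpha <= 0:
            raise InvalidMeasurementError(f"alpha must be positive, got {self.alpha!r}")

    def permil_difference(self, other: "FractionationFactor | float") -> float:
        """``10³·(self − other)``, the ‰-scale difference used in reporting."""
        other_alpha = other.alpha if isinstance(other, FractionationFactor) else float(other)
        return 1000.0 * (self.alpha - other_alpha)


def day_number(date: Union[_dt.date, str, tuple]) -> int:
    """Ordinal day of year on the non-leap calendar (1 January → 1).

    Accepts a :class:`datetime.date`, a ``"DD/MM/YYYY"`` string, or a
    ``(day, month)`` tuple.  29 February is rejected regardless of the year:
    the seasonal calibrations are defined on a 365-day calendar.
    """
    if isinstance(date, str):
        parts = date.strip().split("/")
        if len(parts) == 2:
            day, month = int(parts[0]), int(parts[1])
        elif len(parts) == 3:
            day, month = int(parts[0]), int(parts[1])
        else:
            raise InvalidDateError(f"cannot parse date {date!r} (expected DD/MM/YYYY)")
    elif isinstance(date, tuple):
        day, month = int(date[0]), int(date[1])
    elif isinstance(date, _dt.datetime):
        day, month = date.day, date.month
    elif isinstance(date, _dt.date):
        day, month = date.day, date.month
    else:
        raise InvalidDateError(f"unsupported date type {type(date).__name__}")

    if not 1 <= month <= 12:
        raise InvalidDateError(f"month {month} out of range")
    if not 1 <= day <= _MONTH_LENGTHS[month - 1]:
        raise InvalidDateError(
            f"day {day:02d}/{month:02d} does not exist on the non-leap calendar"
        )
    return _MONTH_OFFSETS[month - 1] + day


def date_of_day_number(t: int, year: int = 2019) -> _dt.date:
    """Inverse of :func:`day_number` on the non-leap calendar."""
    t = int(t)
    if not 1 <= t <= 365:
        raise InvalidDateError(f"day number {t} out of 1..365")
    for month in range(12, 0, -1):
        if t > _MONTH_OFFSETS[month - 1]:
            return _dt.date(year, month, t - _MONTH_OFFSETS[month - 1])
    raise InvalidDateError(f"day number {t} out of 1..365")  # pragma: no cover


@dataclass
class SampleRecord:
    """One shed-month observation: paired farm-water and milk-water deltas.

    Delta fields are plain floats in ‰ vs VSMOW (``None`` when not measured).
    ``t`` is the non-leap day number; when absent it is filled from ``date``.
    An explicitly supplied ``t`` is authoritative even if it disagrees with
    the date (sampling campaigns sometimes report a nominal day number).
    ``temp_2wk`` is the mean air temperature (°C) over the 14 days preceding
    sampling — the equilibration window of a cow's body water.
    """

    shed_id: str
    date: Optional[_dt.date] = None
    t: Optional[int] = None
    d18O_W: Optional[float] = None
    d2H_W: Optional[float] = None
    d18O_M: Optional[float] = None
    d2H_M: Optional[float] = None
    temp_2wk: Optional[float] = None
    outdoor_summer: bool = False

    def __post_init__(self) -> None:
        if self.t is None and self.date is not None:
            self.t = day_number(self.date)
        if self.t is not None:
            self.t = int(self.t)
            if not 1 <= self.t <= 365:
                raise InvalidRecordError(f"day number t={self.t} outside 1..365")
        for name in ("d18O_W", "d2H_W", "d18O_M", "d2H_M"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, _check_delta(v, name))

    @property
    def month(self) -> Optional[int]:
        if self.date is not None:
            return self.date.month
        if self.t is not None:
            return date_of_day_number(self.t).month
        return None


def compute_alpha(
    delta_M: float, delta_W: float, isotope: str = "O18_O16", t: Optional[int] = None
) -> FractionationFactor:
    """Milk/farm-water fractionation factor from a pair of δ values (‰).

    α = (δ_M/10³ + 1) / (δ_W/10³ + 1).  α > 1 exactly when the milk water is
    enriched in the heavy isotope relative to the farm water (δ_M > δ_W).
    """
    m = _check_delta(delta_M, "delta_M")
    w = _check_delta(delta_W, "delta_W")
    alpha = (m / 1000.0 + 1.0) / (w / 1000.0 + 1.0)
    return FractionationFactor(alpha=alpha, isotope=isotope, t=t)


def milk_delta_from_alpha(alpha: Union[FractionationFactor, float], delta_W: float) -> float:
    """δ_M (‰) implied by a fractionation factor and a farm-water δ_W (‰).

    Algebraic inverse of :func:`compute_alpha`:
    ``compute_alpha(milk_delta_from_alpha(a, w), w).alpha == a`` to machine
    precision.  Used by the synthetic-herd generator.
    """
    a = alpha.alpha if isinstance(alpha, FractionationFactor) else float(alpha)
    if not math.isfinite(a) or a <= 0:
        raise InvalidMeasurementError(f"alpha must be positive, got {a!r}")
    w = _check_delta(delta_W, "delta_W")
    return (a * (w / 1000.0 + 1.0) - 1.0) * 1000.0


def deuterium_excess(delta2H: float, delta18O: float) -> float:
    """Deuterium excess d_ex = δ²H − 8·δ¹⁸O, in ‰.

    Decreases under evaporation-like fractionation, so the gap between
    farm-water and milk-water excess tracks the animals' evaporative
    response to temperature.
    """
    h = _check_delta(delta2H, "delta2H")
    o = _check_delta(delta18O, "delta18O")
    return h - 8.0 * o
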