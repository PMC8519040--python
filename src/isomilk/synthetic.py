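"""Synthetic dairy herd-year generator.

Emulates the statistical structure of a regional milk/farm-water isotope
survey: per-shed farm waters that are nearly constant through the year
(scatter at the measurement level), a seasonal temperature cycle, a
milk/water fractionation factor that responds linearly to the two-week mean
temperature with per-shed slopes, outdoor-grazing sheds whose warm-period
response is inflated, and measurement noise at the stated single-sample
uncertainties (0.15‰ for milk δ¹⁸O, 1.5‰ for milk δ²H).

The generator exists so that calibration fitting, the variance partition,
the deuterium-excess/temperature correlation, and the two-step provenance
check can all be exercised and power-tested without survey data.  It is a
phenomenological emulator, not a cow-physiology model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import truncnorm as _truncnorm

from .calibration import QuarticCalibration, WARM_MONTHS
from .core import SampleRecord, date_of_day_number, day_number, milk_delta_from_alpha
from .errors import InvalidConfigError

__all__ = ["SyntheticHerdConfig", "FraudDataset", "simulate_herd_year", "simulate_fraud_scenarios"]

FRAUD_SCENARIOS = ("authentic", "foreign_water", "foreign_milk", "season_mislabel")


@dataclass
class SyntheticHerdConfig:
    """Generative parameters of a synthetic herd-year.

    Defaults reproduce the study conditions of the regional survey the
    analysis assumes: nine sheds sampled monthly for a year, farm-water
    δ¹⁸O means spanning −11.4…−7.8‰ on a slope-8.33/intercept-16.3 water
    line, monthly water scatter at measurement level, a Po-plain style
    temperature cycle, and α-temperature slopes in the 5.7–13.3 ×10⁻⁵ /°C
    range (the top of the range reserved for outdoor-grazing sheds).
    """

    n_sheds: int = 9
    shed_ids: Optional[Sequence[str]] = None
    #: Per-shed farm-water δ¹⁸O means (‰); when None they are drawn from a
    #: normal distribution truncated to the regional range (regional
    #: groundwater means cluster around the centre of their range).
    water_d18O_means: Optional[Sequence[float]] = None
    water_d18O_range: tuple = (-11.4, -7.8)
    water_d18O_mean: float = -9.6
    water_d18O_sd: float = 0.9
    water_line_slope: float = 8.33
    water_line_intercept: float = 16.3
    water_line_scatter: float = 1.6
    #: Month-to-month scatter of a shed's water (measurement level, ‰).
    water_monthly_sd_O: float = 0.08
    water_monthly_sd_H: float = 1.0

    #: Annual temperature sinusoid (°C): coldest around mid January.
    temp_mean: float = 13.5
    temp_amplitude: float = 10.5
    temp_phase_day: int = 15
    temp_daily_sd: float = 2.0

    #: α(T̄) model: α = A_i + B_i·T̄ with B_i per shed in this range (/°C).
    alpha_temp_slope_range: tuple = (5.7e-5, 9.0e-5)
    #: Regional mean fractionation factor at the mean temperature.
    alpha_at_mean_temp: float = 1.0016
    #: Per-shed offset scatter of A_i, in ‰ (10³·α units).
    shed_alpha_offset_sd_permil: float = 0.15
    #: Residual α scatter beyond the temperature response, in ‰.
    alpha_process_sd_permil: float = 0.20
    #: Sheds whose animals graze outdoors in the warm period.
    outdoor_sheds: tuple = ()
    outdoor_slope_range: tuple = (1.18e-4, 1.33e-4)

    #: Alternative α(t) source: a stored quartic instead of the A+B·T̄ model.
    alpha_calibration: Optional[QuarticCalibration] = None
    #: Optional seasonal milk-δ target; with ``alpha_calibration`` it pins
    #: the farm water so records are exactly self-consistent (used for
    #: validation runs with all noise set to zero).
    milk_delta_calibration: Optional[QuarticCalibration] = None

    #: Measurement noise on milk deltas (‰).
    milk_noise_O: float = 0.15
    milk_noise_H: float = 1.5
    #: Milk line δ²H = slope·δ¹⁸O + intercept plus deviations.
    milk_line_slope: float = 6.30
    milk_line_intercept: float = -5.6
    #: Temperature-correlated part of the milk-line deviation (‰/°C): the
    #: evaporation-like ²H response beyond what the δ¹⁸O value carries.
    dex_temp_slope: float = -0.35
    #: Independent part of the milk-line deviation (‰).
    milk_line_scatter: float = 1.0

    sample_months: tuple = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12)
    sample_day_of_month: int = 15
    seed: int = 0
    #: When set, month-level noise (water scatter, α process noise, milk
    #: measurement noise) comes from this separate stream while the herd
    #: itself (shed water means, α slopes, the year's weather) stays pinned
    #: by ``seed`` — this generates held-out samples from the same herds.
    noise_seed: Optional[int] = None

    def shed_labels(self) -> list:
        if self.shed_ids is not None:
            if len(self.shed_ids) != self.n_sheds:
                raise InvalidConfigError("shed_ids length must equal n_sheds")
            return list(self.shed_ids)
        return [f"shed{i + 1:02d}" for i in range(self.n_sheds)]


@dataclass(frozen=True)
class FraudDataset:
    """Labelled records for false-accept / false-reject estimation."""

    scenario: str
    records: list
    is_authentic: list


def _daily_temperature(config: SyntheticHerdConfig, rng: np.random.Generator) -> np.ndarray:
    """Daily temperatures for days −13..365 (periodic sinusoid + noise)."""
    days = np.arange(-13, 366, dtype=float)
    base = config.temp_mean - config.temp_amplitude * np.cos(
        2.0 * np.pi * (days - config.temp_phase_day) / 365.0
    )
    return base + rng.normal(0.0, config.temp_daily_sd, size=days.size)


def _temp_2wk(daily: np.ndarray, t: int) -> float:
    """Mean temperature of the 14 days preceding sampling day t."""
    idx = t + 13  # daily[0] is day −13
    return float(daily[idx - 14 : idx].mean())


def simulate_herd_year(
    config: SyntheticHerdConfig,
    _alpha_offset: float = 0.0,
    _t_shift: int = 0,
    _water_report_shift: float = 0.0,
) -> list:
    """Generate one record per shed per sampled month.

    Milk δ¹⁸O is built by inverting the fractionation relation around the
    sampled farm water: δ_M = inverse_alpha(α(t) + process noise, δ_W) plus
    measurement noise.  Identical config + seed gives identical output.

    The leading-underscore parameters are scenario hooks used by
    :func:`simulate_fraud_scenarios` (an α offset for foreign milk, a
    seasonal shift for mislabelled milking dates, a reported-water shift for
    foreign water) and default to the authentic case.
    """
    sheds = config.shed_labels()
    if not sheds:
        raise InvalidConfigError("empty shed list")
    if not config.sample_months:
        raise InvalidConfigError("no months to sample")
    rng = np.random.default_rng(config.seed)
    noise_rng = (
        np.random.default_rng(config.noise_seed)
        if config.noise_seed is not None
        else rng
    )
    daily = _daily_temperature(config, rng)

    if config.water_d18O_means is not None:
        if len(config.water_d18O_means) != len(sheds):
            raise InvalidConfigError("water_d18O_means length must equal n_sheds")
        means_O = np.asarray(config.water_d18O_means, dtype=float)
    else:
        lo, hi = config.water_d18O_range
        a = (lo - config.water_d18O_mean) / config.water_d18O_sd
        b = (hi - config.water_d18O_mean) / config.water_d18O_sd
        means_O = _truncnorm.rvs(
            a, b,
            loc=config.water_d18O_mean,
            scale=config.water_d18O_sd,
            size=len(sheds),
            random_state=rng,
        )
    means_H = (
        config.water_line_slope * means_O
        + config.water_line_intercept
        + rng.normal(0.0, config.water_line_scatter, size=len(sheds))
    )

    slopes = rng.uniform(*config.alpha_temp_slope_range, size=len(sheds))
    slopes_out = rng.uniform(*config.outdoor_slope_range, size=len(sheds))
    intercepts = (
        config.alpha_at_mean_temp
        - slopes * config.temp_mean
        + rng.normal(0.0, config.shed_alpha_offset_sd_permil / 1000.0, size=len(sheds))
    )

    records: list[SampleRecord] = []
    for i, shed in enumerate(sheds):
        outdoor = shed in config.outdoor_sheds
        for month in config.sample_months:
            t = day_number((config.sample_day_of_month, month))
            t_prod = (t - 1 + _t_shift) % 365 + 1  # day the milk was actually produced
            tbar_declared = _temp_2wk(daily, t)
            tbar_prod = _temp_2wk(daily, t_prod)

            # farm water actually feeding the milk
            if (
                config.milk_delta_calibration is not None
                and config.alpha_calibration is not None
            ):
                # water pinned so that milk lands on the milk-δ calibration
                alpha_model = float(config.alpha_calibration.predict(t_prod))
                target_milk = float(config.milk_delta_calibration.predict(t_prod))
                w_O = ((target_milk / 1000.0 + 1.0) / alpha_model - 1.0) * 1000.0
                w_H = config.water_line_slope * w_O + config.water_line_intercept
            else:
                w_O = means_O[i] + noise_rng.normal(0.0, config.water_monthly_sd_O)
                w_H = means_H[i] + noise_rng.normal(0.0, config.water_monthly_sd_H)
                if config.alpha_calibration is not None:
                    alpha_model = float(config.alpha_calibration.predict(t_prod))
                else:
                    b = slopes_out[i] if (outdoor and date_of_day_number(t_prod).month in WARM_MONTHS) else slopes[i]
                    alpha_model = intercepts[i] + b * tbar_prod

            alpha_true = (
                alpha_model
                + _alpha_offset / 1000.0
                + noise_rng.normal(0.0, config.alpha_process_sd_permil / 1000.0)
            )
            m_O = milk_delta_from_alpha(alpha_true, w_O) + noise_rng.normal(
                0.0, config.milk_noise_O
            )
            m_H = (
                config.milk_line_slope * m_O
                + config.milk_line_intercept
                + config.dex_temp_slope * (tbar_prod - config.temp_mean)
                + noise_rng.normal(0.0, config.milk_line_scatter)
                + noise_rng.normal(0.0, config.milk_noise_H)
            )

            records.append(
                SampleRecord(
                    shed_id=shed,
                    date=date_of_day_number(t),
                    t=t,
                    d18O_W=w_O + _water_report_shift,
                    d2H_W=w_H + config.water_line_slope * _water_report_shift,
                    d18O_M=m_O,
                    d2H_M=m_H,
                    temp_2wk=tbar_declared,
                    outdoor_summer=outdoor,
                )
            )
    return records


def simulate_fraud_scenarios(
    config: SyntheticHerdConfig,
    scenario: str,
    water_shift: float = 3.0,
    alpha_offset_permil: float = 1.5,
    season_shift_days: int = 180,
) -> FraudDataset:
    """Generate labelled records for one provenance scenario.

    ``authentic``
        Records straight from the generator (label True).
    ``foreign_water``
        Milk unchanged, but the declared farm water is shifted by
        ``water_shift`` ‰ in δ¹⁸O (off-region source); the measured α no
        longer matches the seasonal calibration.
    ``foreign_milk``
        Milk produced under a fractionation regime ``alpha_offset_permil`` ‰
        above the regional seasonal model.
    ``season_mislabel``
        Milk produced ``season_shift_days`` later than the declared
        sampling date.
    """
    if scenario not in FRAUD_SCENARIOS:
        raise InvalidConfigError(
            f"unknown scenario {scenario!r}; expected one of {FRAUD_SCENARIOS}"
        )
    kwargs = {}
    if scenario == "foreign_water":
        kwargs["_water_report_shift"] = float(water_shift)
    elif scenario == "foreign_milk":
        kwargs["_alpha_offset"] = float(alpha_offset_permil)
    elif scenario == "season_mislabel":
        kwargs["_t_shift"] = int(season_shift_days)
    records = simulate_herd_year(config, **kwargs)
    authentic = scenario == "authentic"
    return FraudDataset(
        scenario=scenario,
        records=records,
        is_authentic=[authentic] * len(records),
    )
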