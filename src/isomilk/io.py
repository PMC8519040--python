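"""Delimited-text readers and writers.

Sample files are comma-separated UTF-8 with a header row.  Dates are
``DD/MM/YYYY``; the decimal separator is the point; missing values are empty
fields; a Unicode minus (U+2212) in any numeric field is normalised to the
ASCII hyphen-minus on read.
"""

from __future__ import annotations

import csv
import datetime as _dt
import logging
from dataclasses import dataclass, fields as _dc_fields
from typing import Optional, Sequence

import yaml

from .core import SampleRecord
from .errors import InvalidConfigError, SchemaError
from .verification import VerificationResult

__all__ = [
    "SAMPLE_COLUMNS",
    "REPORT_COLUMNS",
    "RowError",
    "ReadResult",
    "RunConfig",
    "read_samples",
    "write_samples",
    "write_report",
    "read_report",
]

log = logging.getLogger("isomilk")

SAMPLE_COLUMNS = (
    "shed_id",
    "date",
    "t",
    "d18O_W",
    "d2H_W",
    "d18O_M",
    "d2H_M",
    "temp_2wk",
    "outdoor_summer",
)

REPORT_COLUMNS = (
    "shed_id",
    "date",
    "t",
    "d18O_W",
    "d18O_M",
    "d18O_M_calc",
    "step1_diff_permil",
    "step1_threshold",
    "step1_pass",
    "alpha_m",
    "alpha_hat",
    "step2_diff_permil",
    "step2_threshold",
    "step2_pass",
    "overall",
    "calib_delta",
    "calib_alpha",
)


@dataclass(frozen=True)
class RowError:
    line: int
    message: str


@dataclass(frozen=True)
class ReadResult:
    """Parsed records plus per-row errors (malformed rows are dropped)."""

    records: list
    errors: list

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _clean(value: Optional[str]) -> Optional[str]:
    if value is None:
        return None
    value = value.replace("−", "-").strip()
    return value or None


def _parse_date(text: str) -> _dt.date:
    day, month, year = (int(p) for p in text.split("/"))
    return _dt.date(year, month, day)


def read_samples(path: str) -> ReadResult:
    """Read sample records from a CSV file.

    The header must contain ``shed_id``, ``d18O_M`` and at least one of
    ``date``/``t`` (missing mandatory columns raise :class:`SchemaError`).
    Malformed rows are reported with their line number in ``errors`` and the
    remaining rows are kept.  Day numbers are filled from dates where absent;
    an explicit ``t`` wins over the date.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        header = [h.strip() for h in reader.fieldnames]
        missing = {"shed_id", "d18O_M"} - set(header)
        if missing or not ({"date", "t"} & set(header)):
            raise SchemaError(
                f"{path}: missing mandatory columns "
                f"{sorted(missing) + ([] if {'date', 't'} & set(header) else ['date|t'])}"
            )
        records: list[SampleRecord] = []
        errors: list[RowError] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row))
            except Exception as exc:  # row-level: keep going
                errors.append(RowError(line=lineno, message=str(exc)))
    for err in errors:
        log.warning("%s line %d: %s", path, err.line, err.message)
    return ReadResult(records=records, errors=errors)


def _parse_row(row: dict) -> SampleRecord:
    get = lambda key: _clean(row.get(key))
    shed = get("shed_id")
    if not shed:
        raise ValueError("missing shed_id")
    date_text = get("date")
    date = _parse_date(date_text) if date_text else None
    t_text = get("t")
    t = int(t_text) if t_text else None
    flag_text = get("outdoor_summer")
    outdoor = (flag_text or "").lower() in ("1", "true", "yes")

    def num(key):
        v = get(key)
        return float(v) if v is not None else None

    return SampleRecord(
        shed_id=shed,
        date=date,
        t=t,
        d18O_W=num("d18O_W"),
        d2H_W=num("d2H_W"),
        d18O_M=num("d18O_M"),
        d2H_M=num("d2H_M"),
        temp_2wk=num("temp_2wk"),
        outdoor_summer=outdoor,
    )


def _fmt_date(date: Optional[_dt.date]) -> str:
    return date.strftime("%d/%m/%Y") if date else ""


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_samples(records: Sequence[SampleRecord], path: str) -> None:
    """Write sample records as CSV (full float precision; round-trips)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SAMPLE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.shed_id,
                    _fmt_date(r.date),
                    _fmt(r.t),
                    _fmt(r.d18O_W),
                    _fmt(r.d2H_W),
                    _fmt(r.d18O_M),
                    _fmt(r.d2H_M),
                    _fmt(r.temp_2wk),
                    _fmt(r.outdoor_summer),
                ]
            )


def write_report(results: Sequence[VerificationResult], path: str) -> None:
    """Write a verification report: per-sample deltas, thresholds, verdicts.

    Columns mirror the published validation-table layout (measured water and
    milk δ¹⁸O, calculated milk δ¹⁸O, the ‰-scale step-1 and step-2
    differences) plus pass flags and the calibration identifiers.  Numbers
    are written at full precision so the file round-trips losslessly.
    """
    results = list(results)
    if not results:
        raise ValueError("no verification results to report")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REPORT_COLUMNS)
        for res in results:
            r = res.record
            overall = res.overall
            writer.writerow(
                [
                    r.shed_id,
                    _fmt_date(r.date),
                    _fmt(r.t),
                    _fmt(r.d18O_W),
                    _fmt(r.d18O_M),
                    _fmt(res.step1.delta_calculated),
                    _fmt(res.step1.delta_abs_diff),
                    _fmt(res.step1.threshold),
                    _fmt(res.step1.passed),
                    _fmt(res.step2.alpha_measured),
                    _fmt(res.step2.alpha_predicted),
                    _fmt(res.step2.diff_permil),
                    _fmt(res.step2.threshold),
                    _fmt(res.step2.passed) if not res.step2.skipped else "skipped",
                    _fmt(overall) if overall is not None else "undetermined",
                    res.calib_delta,
                    res.calib_alpha,
                ]
            )


def read_report(path: str) -> list:
    """Read a verification report back as a list of dicts (numbers parsed)."""
    rows = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            parsed = {}
            for key, val in row.items():
                val = _clean(val)
                if val is None:
                    parsed[key] = None
                elif val in ("true", "false"):
                    parsed[key] = val == "true"
                else:
                    try:
                        parsed[key] = float(val) if "." in val or "e" in val.lower() else val
                    except ValueError:
                        parsed[key] = val
            rows.append(parsed)
    return rows


@dataclass
class RunConfig:
    """Run configuration for the command-line pipeline (YAML-backed)."""

    input: Optional[str] = None
    output: Optional[str] = None
    calib_delta: str = "eq5_milk_d18O"
    calib_alpha: str = "eq6b_alpha_indoor"
    coverage: float = 1.645
    step2_threshold: Optional[float] = None
    groundwater_d18O: Optional[float] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise InvalidConfigError("coverage factor must be > 0")
        if self.step2_threshold is not None and self.step2_threshold <= 0:
            raise InvalidConfigError("step-2 threshold must be > 0")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in _dc_fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)
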