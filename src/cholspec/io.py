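"""Readers and writers for the project's plain-text formats.

CSV is the interchange format (explicit headers, UTF-8, decimal text);
fitted curves and study reports are JSON.  Writers format floats with
``repr`` (shortest exact decimal), so a write -> read round trip preserves
every value bit-for-bit.  Readers validate and reject rather than coerce,
naming the offending line.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

from .calibration import CalibrationCurve, CalibrationPoint
from .errors import ParseError, ValidationError
from .pipeline import GROUPS, SubjectRecord
from .spectral import ExtinctionProfile, Spectrum

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_extinction_csv",
    "write_extinction_csv",
    "read_calibration_csv",
    "write_calibration_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_curve_json",
    "write_curve_json",
]

SPECTRUM_HEADER = ["wavelength_nm", "intensity"]
EXTINCTION_HEADER = ["wavelength_nm", "alpha_per_mm"]
CALIBRATION_HEADER = ["concentration_ug_ml", "signal"]
COHORT_HEADER = ["subject_id", "group", "device_value", "reference_value"]


def _fmt(x: float) -> str:
    return repr(float(x))


def _parse_float(text: str, path, line_no: int, column: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"{path}: line {line_no}: cannot parse {column}={text!r} as a number"
        ) from None


def _read_two_column(path, expected_header: list[str]):
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: file is empty") from None
        if [h.strip() for h in header] != expected_header:
            raise ParseError(
                f"{path}: line 1: expected header {','.join(expected_header)!r}, "
                f"got {','.join(header)!r}"
            )
        xs, ys = [], []
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise ParseError(f"{path}: line {line_no}: expected 2 fields, got {len(row)}")
            xs.append(_parse_float(row[0], path, line_no, expected_header[0]))
            ys.append(_parse_float(row[1], path, line_no, expected_header[1]))
    if not xs:
        raise ParseError(f"{path}: no data rows (header only)")
    return xs, ys


def _validate_columns(path, xs, ys, y_name: str) -> None:
    for i in range(1, len(xs)):
        if xs[i] <= xs[i - 1]:
            raise ValidationError(
                f"{path}: line {i + 2}: wavelengths not strictly increasing "
                f"({xs[i]!r} after {xs[i - 1]!r})"
            )
    for i, y in enumerate(ys):
        if y < 0:
            raise ValidationError(f"{path}: line {i + 2}: negative {y_name} ({y!r})")


def read_spectrum_csv(path) -> Spectrum:
    xs, ys = _read_two_column(path, SPECTRUM_HEADER)
    _validate_columns(path, xs, ys, "intensity")
    return Spectrum(xs, ys)


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    _write_two_column(path, SPECTRUM_HEADER, spectrum.wavelengths, spectrum.intensities)


def read_extinction_csv(path) -> ExtinctionProfile:
    xs, ys = _read_two_column(path, EXTINCTION_HEADER)
    _validate_columns(path, xs, ys, "alpha")
    return ExtinctionProfile(xs, ys)


def write_extinction_csv(profile: ExtinctionProfile, path) -> None:
    _write_two_column(path, EXTINCTION_HEADER, profile.wavelengths, profile.alpha)


def _write_two_column(path, header, xs, ys) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for x, y in zip(xs, ys):
            writer.writerow([_fmt(x), _fmt(y)])


def read_calibration_csv(path) -> list[CalibrationPoint]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise ParseError(f"{path}: file is empty") from None
        if header[:2] != CALIBRATION_HEADER or len(header) > 3 or (
            len(header) == 3 and header[2] != "replicate_sd"
        ):
            raise ParseError(
                f"{path}: line 1: expected header "
                f"'concentration_ug_ml,signal[,replicate_sd]', got {','.join(header)!r}"
            )
        has_sd = len(header) == 3
        points = []
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            expected = 3 if has_sd else 2
            if len(row) != expected:
                raise ParseError(
                    f"{path}: line {line_no}: expected {expected} fields, got {len(row)}"
                )
            conc = _parse_float(row[0], path, line_no, "concentration_ug_ml")
            sig = _parse_float(row[1], path, line_no, "signal")
            sd = None
            if has_sd and row[2].strip() != "":
                sd = _parse_float(row[2], path, line_no, "replicate_sd")
            try:
                points.append(CalibrationPoint(conc, sig, sd))
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {line_no}: {exc}") from None
    if not points:
        raise ParseError(f"{path}: no data rows (header only)")
    return points


def write_calibration_csv(points: Sequence[CalibrationPoint], path) -> None:
    path = Path(path)
    has_sd = any(p.replicate_sd is not None for p in points)
    header = CALIBRATION_HEADER + (["replicate_sd"] if has_sd else [])
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for p in points:
            row = [_fmt(p.concentration), _fmt(p.signal)]
            if has_sd:
                row.append("" if p.replicate_sd is None else _fmt(p.replicate_sd))
            writer.writerow(row)


def read_cohort_csv(path) -> list[SubjectRecord]:
    """Read subject records; the reference_value column is optional and may
    be empty per-row (record loads with reference absent)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise ParseError(f"{path}: file is empty") from None
        if header not in (COHORT_HEADER, COHORT_HEADER[:3]):
            raise ParseError(
                f"{path}: line 1: expected header "
                f"'subject_id,group,device_value[,reference_value]', got {','.join(header)!r}"
            )
        has_ref = len(header) == 4
        records = []
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}: line {line_no}: expected {len(header)} fields, got {len(row)}"
                )
            group = row[1].strip()
            if group not in GROUPS:
                raise ValidationError(
                    f"{path}: line {line_no}: unknown group {group!r}; expected one of {GROUPS}"
                )
            device = _parse_float(row[2], path, line_no, "device_value")
            ref = None
            if has_ref and row[3].strip() != "":
                ref = _parse_float(row[3], path, line_no, "reference_value")
            records.append(
                SubjectRecord(
                    subject_id=row[0].strip(),
                    group=group,
                    device_value=device,
                    reference_value=ref,
                )
            )
    if not records:
        raise ParseError(f"{path}: no data rows (header only)")
    return records


def write_cohort_csv(records: Sequence[SubjectRecord], path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(COHORT_HEADER)
        for r in records:
            writer.writerow(
                [
                    r.subject_id,
                    r.group,
                    _fmt(r.device_value),
                    "" if r.reference_value is None else _fmt(r.reference_value),
                ]
            )


def write_curve_json(curve: CalibrationCurve, path) -> None:
    Path(path).write_text(json.dumps(curve.to_dict(), sort_keys=True, indent=2) + "\n")


def read_curve_json(path) -> CalibrationCurve:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from None
    return CalibrationCurve.from_dict(data)
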