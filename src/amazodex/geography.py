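"""Geographic validation (filter 2): coordinate parsing and precision rules.

Records are excluded when coordinates are absent, out of range, described
only at an administrative level (municipality / state / country), or
carry an uncertainty radius strictly greater than 20 km.  Coordinates
written in degrees-minutes-seconds are converted to decimal degrees
(datum assumed WGS84 throughout; no datum shift is performed).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Iterable, Optional

from .core import ADMIN_PRECISIONS, FilterReport, Flag, OccurrenceRecord

__all__ = [
    "CoordinateOutcome",
    "CoordinateCheck",
    "dms_to_decimal",
    "decimal_to_dms",
    "check_coordinates",
    "apply_geographic_filter",
]


class CoordinateOutcome(str, enum.Enum):
    OK = "ok"
    MISSING = "missing"
    OUT_OF_RANGE = "out_of_range"
    ZERO_ZERO = "zero_zero"
    TOO_IMPRECISE = "too_imprecise"
    ADMIN_LEVEL = "admin_level"


@dataclass
class CoordinateCheck:
    outcome: CoordinateOutcome
    latitude: Optional[float] = None
    longitude: Optional[float] = None


_DMS_RE = re.compile(
    r"""^\s*(?P<sign>[-+])?\s*
        (?P<deg>\d+(?:\.\d+)?)\s*(?:[°ºd]\s*)?
        (?:(?P<min>\d+(?:\.\d+)?)\s*(?:['’m]\s*)?)?
        (?:(?P<sec>\d+(?:\.\d+)?)\s*(?:["”s]\s*)?)?
        (?P<hemi>[NSEWnsew])?\s*$""",
    re.VERBOSE,
)


def dms_to_decimal(text: str) -> float:
    """Convert a coordinate string to decimal degrees.

    Accepts plain decimals (pass-through), and D°M'S" with an optional
    hemisphere letter (S/W negative) or leading minus.  Raises
    ``ValueError`` for minutes/seconds >= 60 or when a hemisphere letter
    contradicts an explicit minus sign.
    """
    if text is None:
        raise ValueError("empty coordinate string")
    text = str(text).strip()
    if not text:
        raise ValueError("empty coordinate string")
    try:
        return float(text)
    except ValueError:
        pass
    m = _DMS_RE.match(text)
    if m is None:
        raise ValueError(f"unparseable coordinate {text!r}")
    deg = float(m.group("deg"))
    minutes = float(m.group("min") or 0.0)
    seconds = float(m.group("sec") or 0.0)
    if minutes >= 60.0 or seconds >= 60.0:
        raise ValueError(f"minutes/seconds out of range in {text!r}")
    value = deg + minutes / 60.0 + seconds / 3600.0
    hemi = (m.group("hemi") or "").upper()
    negative_letter = hemi in ("S", "W")
    explicit_minus = m.group("sign") == "-"
    if explicit_minus and hemi and not negative_letter:
        raise ValueError(f"sign conflict in {text!r}: minus with hemisphere {hemi}")
    if explicit_minus or negative_letter:
        value = -value
    return value


def decimal_to_dms(value: float, axis: str = "lat") -> str:
    """Format decimal degrees as a D°M'S" string (inverse of :func:`dms_to_decimal`)."""
    if axis == "lat":
        hemi = "S" if value < 0 else "N"
    else:
        hemi = "W" if value < 0 else "E"
    v = abs(value)
    deg = int(v)
    rem = (v - deg) * 60.0
    minutes = int(rem)
    seconds = round((rem - minutes) * 60.0, 9)
    if seconds >= 60.0:  # carry from float rounding at the format precision
        seconds = 0.0
        minutes += 1
    if minutes >= 60:
        minutes = 0
        deg += 1
    return f"{deg}°{minutes}'{seconds:.9f}\"{hemi}"


def check_coordinates(record: OccurrenceRecord, max_radius_km: float = 20.0) -> CoordinateCheck:
    """Classify a record's coordinates with exactly one outcome.

    Precedence: missing, out_of_range, zero_zero, admin_level,
    too_imprecise (uncertainty strictly greater than ``max_radius_km``),
    then ok.  Records with coordinates but no stated uncertainty pass
    when their described precision is point / locality / unknown.
    """
    if not record.has_coordinates:
        return CoordinateCheck(CoordinateOutcome.MISSING)
    lat, lon = record.latitude, record.longitude
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        return CoordinateCheck(CoordinateOutcome.OUT_OF_RANGE)
    if lat == 0.0 and lon == 0.0:
        return CoordinateCheck(CoordinateOutcome.ZERO_ZERO, lat, lon)
    if record.locality_precision in ADMIN_PRECISIONS:
        return CoordinateCheck(CoordinateOutcome.ADMIN_LEVEL, lat, lon)
    if (
        record.coordinate_uncertainty_m is not None
        and record.coordinate_uncertainty_m > max_radius_km * 1000.0
    ):
        return CoordinateCheck(CoordinateOutcome.TOO_IMPRECISE, lat, lon)
    return CoordinateCheck(CoordinateOutcome.OK, lat, lon)


_OUTCOME_FLAGS = {
    CoordinateOutcome.MISSING: Flag.MISSING_COORD,
    CoordinateOutcome.OUT_OF_RANGE: Flag.OUT_OF_RANGE,
    CoordinateOutcome.ZERO_ZERO: Flag.ZERO_ZERO,
    CoordinateOutcome.TOO_IMPRECISE: Flag.TOO_IMPRECISE,
    CoordinateOutcome.ADMIN_LEVEL: Flag.ADMIN_LEVEL,
}


def apply_geographic_filter(
    records: Iterable[OccurrenceRecord],
    max_radius_km: float = 20.0,
    drop_zero_zero: bool = True,
) -> tuple[list[OccurrenceRecord], list[tuple[OccurrenceRecord, str]], FilterReport]:
    """Filter 2: keep records with usable point coordinates.

    Returns (retained, excluded-with-reason, report slice).  (0, 0)
    coordinates are dropped by default as a data-entry artifact; set
    ``drop_zero_zero=False`` to keep them.
    """
    records = list(records)
    retained: list[OccurrenceRecord] = []
    excluded: list[tuple[OccurrenceRecord, str]] = []
    for rec in records:
        check = check_coordinates(rec, max_radius_km=max_radius_km)
        keep = check.outcome == CoordinateOutcome.OK or (
            check.outcome == CoordinateOutcome.ZERO_ZERO and not drop_zero_zero
        )
        if check.outcome != CoordinateOutcome.OK:
            rec.flags.add(_OUTCOME_FLAGS[check.outcome])
        if keep:
            retained.append(rec)
        else:
            excluded.append((rec, check.outcome.value))
    report = FilterReport(len(records))
    n_species = len({r.accepted_name or r.raw_name for r in retained})
    report.record_stage("geographic", len(excluded), n_species)
    return retained, excluded, report
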