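"""Canonical trial-record model, sentinel handling, and CSV/SQLite I/O.

CTRI stores several "date" fields as fixed sentinel strings rather than
leaving them blank: ``"Date Missing"``, ``"Not Applicable"`` and
``"Applicable only for Completed/Terminated trials"``.  The audit logic
depends on keeping those sentinels distinct from genuinely empty cells,
so every raw field value maps to exactly one of: a parsed value, a named
sentinel, or EMPTY.

Dates are read in the registry's dd/mm/yyyy dialect (ISO yyyy-mm-dd is
also accepted on input); all serialized output is ISO.
"""

from __future__ import annotations

import csv
import enum
import re
import sqlite3
from dataclasses import dataclass, field, fields as dc_fields
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Union


class Sentinel(enum.Enum):
    """Fixed registry strings standing in for a value; EMPTY marks a blank cell."""

    DATE_MISSING = "Date Missing"
    NOT_APPLICABLE = "Not Applicable"
    COMPLETED_SENTINEL = "Applicable only for Completed/Terminated trials"
    EMPTY = ""

    def __str__(self) -> str:  # serialize back to the registry string
        return self.value


_SENTINEL_LOOKUP = {s.value.casefold(): s for s in Sentinel}
# common registry spelling variants
_SENTINEL_LOOKUP["not applicable"] = Sentinel.NOT_APPLICABLE
_SENTINEL_LOOKUP["date missing"] = Sentinel.DATE_MISSING
_SENTINEL_LOOKUP["applicable only for completed/terminated trials"] = (
    Sentinel.COMPLETED_SENTINEL
)

DateOrSentinel = Union[date, Sentinel]

_DDMMYYYY = re.compile(r"^(\d{1,2})/(\d{1,2})/(\d{4})$")
_ISO = re.compile(r"^(\d{4})-(\d{2})-(\d{2})$")


def parse_date(raw: str) -> DateOrSentinel:
    """Parse a registry date cell into a date or a sentinel.

    Accepts dd/mm/yyyy (registry dialect) and yyyy-mm-dd (ISO).  Raises
    ``ValueError`` for non-empty strings that are neither a known
    sentinel nor a parseable date.
    """
    text = raw.strip()
    tag = _SENTINEL_LOOKUP.get(text.casefold())
    if tag is not None:
        return tag
    m = _DDMMYYYY.match(text)
    if m:
        d, mo, y = (int(g) for g in m.groups())
        return date(y, mo, d)
    m = _ISO.match(text)
    if m:
        return date.fromisoformat(text)
    raise ValueError(f"unparseable date: {raw!r}")


def format_date(value: DateOrSentinel) -> str:
    """Serialize a date field: ISO for real dates, the verbatim string for sentinels."""
    if isinstance(value, Sentinel):
        return value.value
    return value.isoformat()


def parse_int(raw: str) -> Optional[int]:
    """Lenient non-negative integer parse (strips commas/whitespace); '' -> None."""
    text = raw.strip().replace(",", "")
    if not text or _SENTINEL_LOOKUP.get(text.casefold()) is not None:
        return None
    value = int(float(text))
    if value < 0:
        raise ValueError(f"negative count: {raw!r}")
    return value


@dataclass(frozen=True)
class FieldValue:
    """A raw registry cell together with its parsed value or sentinel tag."""

    raw: str
    parsed: Union[date, int, str, Sentinel]

    @classmethod
    def of_date(cls, raw: str) -> "FieldValue":
        return cls(raw=raw, parsed=parse_date(raw))


class Duration(NamedTuple):
    """Estimated trial duration as registered: whole years, months and days."""

    years: int = 0
    months: int = 0
    days: int = 0


@dataclass
class TrialRecord:
    """One CTRI registry entry, restricted to the fields the audit reads."""

    ctri_number: str
    registration_date: Optional[date] = None
    trial_type: str = ""
    phase: str = ""
    recruitment_status_india: str = ""
    recruitment_status_global: str = ""
    first_enrollment_india: DateOrSentinel = Sentinel.EMPTY
    first_enrollment_global: DateOrSentinel = Sentinel.EMPTY
    total_sample_size: Optional[int] = None
    sample_size_india: Optional[int] = None
    final_enrollment_total: Optional[int] = None
    final_enrollment_india: Optional[int] = None
    completion_date_india: DateOrSentinel = Sentinel.EMPTY
    completion_date_global: DateOrSentinel = Sentinel.EMPTY
    estimated_duration: Duration = field(default_factory=Duration)
    primary_sponsor: str = ""
    sponsor_country: str = ""


#: canonical column order for CSV / SQLite serialization
COLUMNS = [
    "ctri_number",
    "registration_date",
    "trial_type",
    "phase",
    "recruitment_status_india",
    "recruitment_status_global",
    "first_enrollment_india",
    "first_enrollment_global",
    "total_sample_size",
    "sample_size_india",
    "final_enrollment_total",
    "final_enrollment_india",
    "completion_date_india",
    "completion_date_global",
    "duration_years",
    "duration_months",
    "duration_days",
    "primary_sponsor",
    "sponsor_country",
]

_DATE_COLUMNS = {"first_enrollment_india", "first_enrollment_global",
                 "completion_date_india", "completion_date_global"}
_INT_COLUMNS = {"total_sample_size", "sample_size_india",
                "final_enrollment_total", "final_enrollment_india",
                "duration_years", "duration_months", "duration_days"}


@dataclass
class RejectedRow:
    """A malformed input row, kept with the reason it could not be parsed."""

    row_number: int
    ctri_number: str
    reason: str


@dataclass
class ReadResult:
    records: list  # list[TrialRecord]
    rejects: list  # list[RejectedRow]


class SchemaError(Exception):
    """A required column is absent from the input."""


def _record_from_raw(raw: Mapping[str, str]) -> TrialRecord:
    reg = raw.get("registration_date", "").strip()
    reg_date: Optional[date] = None
    if reg:
        parsed = parse_date(reg)
        if isinstance(parsed, date):
            reg_date = parsed
    dur = Duration(
        years=parse_int(raw.get("duration_years", "")) or 0,
        months=parse_int(raw.get("duration_months", "")) or 0,
        days=parse_int(raw.get("duration_days", "")) or 0,
    )
    return TrialRecord(
        ctri_number=raw["ctri_number"].strip(),
        registration_date=reg_date,
        trial_type=raw.get("trial_type", "").strip(),
        phase=raw.get("phase", "").strip(),
        recruitment_status_india=raw.get("recruitment_status_india", "").strip(),
        recruitment_status_global=raw.get("recruitment_status_global", "").strip(),
        first_enrollment_india=parse_date(raw.get("first_enrollment_india", "")),
        first_enrollment_global=parse_date(raw.get("first_enrollment_global", "")),
        total_sample_size=parse_int(raw.get("total_sample_size", "")),
        sample_size_india=parse_int(raw.get("sample_size_india", "")),
        final_enrollment_total=parse_int(raw.get("final_enrollment_total", "")),
        final_enrollment_india=parse_int(raw.get("final_enrollment_india", "")),
        completion_date_india=parse_date(raw.get("completion_date_india", "")),
        completion_date_global=parse_date(raw.get("completion_date_global", "")),
        estimated_duration=dur,
        primary_sponsor=raw.get("primary_sponsor", "").strip(),
        sponsor_country=raw.get("sponsor_country", "").strip(),
    )


def record_to_row(record: TrialRecord) -> dict:
    """Serialize a TrialRecord to a flat string-valued row in canonical columns."""
    return {
        "ctri_number": record.ctri_number,
        "registration_date": (
            record.registration_date.isoformat() if record.registration_date else ""
        ),
        "trial_type": record.trial_type,
        "phase": record.phase,
        "recruitment_status_india": record.recruitment_status_india,
        "recruitment_status_global": record.recruitment_status_global,
        "first_enrollment_india": format_date(record.first_enrollment_india),
        "first_enrollment_global": format_date(record.first_enrollment_global),
        "total_sample_size": _int_str(record.total_sample_size),
        "sample_size_india": _int_str(record.sample_size_india),
        "final_enrollment_total": _int_str(record.final_enrollment_total),
        "final_enrollment_india": _int_str(record.final_enrollment_india),
        "completion_date_india": format_date(record.completion_date_india),
        "completion_date_global": format_date(record.completion_date_global),
        "duration_years": str(record.estimated_duration.years),
        "duration_months": str(record.estimated_duration.months),
        "duration_days": str(record.estimated_duration.days),
        "primary_sponsor": record.primary_sponsor,
        "sponsor_country": record.sponsor_country,
    }


def _int_str(v: Optional[int]) -> str:
    return "" if v is None else str(v)


def _rows_to_records(
    rows: Iterable[Mapping[str, str]],
    column_map: Optional[Mapping[str, str]],
) -> ReadResult:
    records: list = []
    rejects: list = []
    seen: set = set()
    for i, raw in enumerate(rows, start=1):
        if column_map:
            raw = {canon: raw.get(src, "") for canon, src in column_map.items()}
        ctri = (raw.get("ctri_number") or "").strip()
        try:
            if not ctri:
                raise ValueError("empty ctri_number")
            if ctri in seen:
                raise ValueError(f"duplicate ctri_number {ctri}")
            records.append(_record_from_raw(raw))
            seen.add(ctri)
        except (ValueError, KeyError) as exc:
            rejects.append(RejectedRow(row_number=i, ctri_number=ctri, reason=str(exc)))
    return ReadResult(records=records, rejects=rejects)


def _check_schema(columns: Iterable[str], column_map: Optional[Mapping[str, str]]) -> None:
    have = set(columns)
    if column_map:
        missing = [src for src in column_map.values() if src not in have]
    else:
        missing = [c for c in COLUMNS if c not in have]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(sorted(missing))}")


def read_records(
    source: Union[str, Path],
    table_name: str = "trials",
    column_map: Optional[Mapping[str, str]] = None,
) -> ReadResult:
    """Read a registry snapshot from a CSV file or SQLite database.

    Parameters
    ----------
    source
        Path to a ``.csv`` file or an SQLite database.
    table_name
        Table to read when ``source`` is SQLite.
    column_map
        Optional mapping from canonical snake_case names to the column
        labels actually present in the source (the escape hatch for
        scrape dialects with verbose headers).

    Returns
    -------
    ReadResult
        Parsed records plus a list of rejected rows with reasons;
        malformed rows are never silently dropped.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:  # empty file
                return ReadResult(records=[], rejects=[])
            _check_schema(reader.fieldnames, column_map)
            return _rows_to_records(reader, column_map)
    with sqlite3.connect(path) as conn:
        conn.row_factory = sqlite3.Row
        cur = conn.execute(f'SELECT * FROM "{table_name}"')
        cols = [d[0] for d in cur.description]
        _check_schema(cols, column_map)
        rows = [{k: ("" if r[k] is None else str(r[k])) for k in cols} for r in cur]
    return _rows_to_records(rows, column_map)


def write_records(
    records: Iterable[TrialRecord],
    dest: Union[str, Path],
    format: str = "csv",
    table_name: str = "trials",
) -> None:
    """Write records to CSV or SQLite; read_records(write_records(x)) == x."""
    dest = Path(dest)
    rows = [record_to_row(r) for r in records]
    if format == "csv":
        with open(dest, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=COLUMNS)
            writer.writeheader()
            writer.writerows(rows)
    elif format == "sqlite":
        with sqlite3.connect(dest) as conn:
            col_defs = ", ".join(f'"{c}" TEXT' for c in COLUMNS)
            conn.execute(f'DROP TABLE IF EXISTS "{table_name}"')
            conn.execute(f'CREATE TABLE "{table_name}" ({col_defs})')
            placeholders = ", ".join("?" for _ in COLUMNS)
            conn.executemany(
                f'INSERT INTO "{table_name}" VALUES ({placeholders})',
                [[row[c] for c in COLUMNS] for row in rows],
            )
            conn.commit()
    else:
        raise ValueError(f"unknown format: {format!r}")
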