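"""Estimated completion dates and overdue-record detection.

For each record in the Not Completed Set the expected registry-filing
date is reconstructed in five steps:

1. the overall date of first enrollment is the later of the India and
   Global first-enrollment dates;
2. the registered estimated duration (years, months, days) is
   normalized to whole months — years contribute 12 months each and any
   non-zero day component counts as one extra month;
3. a delay margin scales the months by duration class: durations up to
   two years are doubled, durations of two to five years are multiplied
   by 1.5 (rounded up), and longer durations get no margin;
4. the margin-adjusted months are added to the overall first-enrollment
   date (calendar-month addition, clamping to month end) to give the
   estimated completion date;
5. a further six-month grace for updating the registry record gives the
   filing-due date.

A record is overdue at a reference date when its filing-due date is on
or before that date (inclusive).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from datetime import date
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from dateutil.relativedelta import relativedelta

from ctri_audit.records import TrialRecord

#: months of grace for updating the record after estimated completion
DEFAULT_GRACE_MONTHS = 6
#: reference date: the day before the snapshot download of 2022-01-28
DEFAULT_AS_OF = date(2022, 1, 27)


class MarginClass(enum.Enum):
    """Delay-margin class by estimated duration."""

    SHORT_2X = "SHORT_2X"  # up to 24 months: doubled
    INTERMEDIATE_1_5X = "INTERMEDIATE_1_5X"  # 25-60 months: x1.5, rounded up
    LONG_1X = "LONG_1X"  # over 60 months: no margin


class DegenerateDurationError(ValueError):
    """Raised when the registered duration is zero in all components."""


def normalize_duration(years: int, months: int, days: int) -> int:
    """Collapse a (years, months, days) duration to whole months.

    Any non-zero day count is substituted by one month; years are
    converted at 12 months each.  An all-zero duration is degenerate
    (the margin algorithm is undefined on it) and raises.
    """
    if min(years, months, days) < 0:
        raise ValueError("duration components must be non-negative")
    if years == months == days == 0:
        raise DegenerateDurationError("all-zero estimated duration")
    return years * 12 + months + (1 if days > 0 else 0)


def apply_margin(duration_months: int) -> Tuple[MarginClass, int]:
    """Margin-adjusted months for a normalized duration.

    Exactly 24 months sits on the boundary between the doubled and the
    1.5x class and is assigned the more generous doubling; exactly 60
    months likewise stays in the 1.5x class.  Fractional months from the
    1.5x factor are rounded up.
    """
    if duration_months < 1:
        raise ValueError("duration must be at least one month")
    if duration_months <= 24:
        return MarginClass.SHORT_2X, 2 * duration_months
    if duration_months <= 60:
        return MarginClass.INTERMEDIATE_1_5X, math.ceil(1.5 * duration_months)
    return MarginClass.LONG_1X, duration_months


def add_months(start: date, months: int) -> date:
    """Calendar-month addition with end-of-month clamping (Jan 31 + 1 -> Feb 28/29)."""
    return start + relativedelta(months=months)


@dataclass(frozen=True)
class CompletionEstimate:
    """Reconstructed completion and filing dates for one record."""

    ctri_number: str
    overall_first_enrollment: date
    duration_months: int
    margin_class: MarginClass
    adjusted_months: int
    estimated_completion: date
    filing_due: date
    overdue_at: Dict[date, bool]

    def is_overdue(self, as_of: date) -> bool:
        return self.filing_due <= as_of


@dataclass
class OverdueResult:
    """Overdue count with the per-record estimates and exclusions."""

    count: int
    as_of: date
    estimates: List[CompletionEstimate]
    excluded: List[Tuple[TrialRecord, str]]

    @property
    def denominator(self) -> int:
        return len(self.estimates)


def estimate_filing_due(
    record: TrialRecord,
    as_of: date = DEFAULT_AS_OF,
    grace_months: int = DEFAULT_GRACE_MONTHS,
) -> CompletionEstimate:
    """Run the five estimation steps on one not-completed record.

    Raises ``ValueError`` when a first-enrollment date is missing and
    ``DegenerateDurationError`` for an all-zero duration; callers
    aggregating over a set catch these and report the record excluded.
    """
    di = record.first_enrollment_india
    dg = record.first_enrollment_global
    if not isinstance(di, date) or not isinstance(dg, date):
        raise ValueError("both first-enrollment dates are required")
    start = max(di, dg)
    months = normalize_duration(*record.estimated_duration)
    margin_class, adjusted = apply_margin(months)
    completion = add_months(start, adjusted)
    filing_due = add_months(completion, grace_months)
    return CompletionEstimate(
        ctri_number=record.ctri_number,
        overall_first_enrollment=start,
        duration_months=months,
        margin_class=margin_class,
        adjusted_months=adjusted,
        estimated_completion=completion,
        filing_due=filing_due,
        overdue_at={as_of: filing_due <= as_of},
    )


def count_overdue(
    not_completed_records: Iterable[TrialRecord],
    as_of: date = DEFAULT_AS_OF,
    grace_months: int = DEFAULT_GRACE_MONTHS,
) -> OverdueResult:
    """Count not-completed records whose filing-due date has passed.

    Records with missing enrollment dates or degenerate durations are
    excluded from the denominator and listed with their reasons.
    """
    estimates: List[CompletionEstimate] = []
    excluded: List[Tuple[TrialRecord, str]] = []
    for r in not_completed_records:
        try:
            estimates.append(estimate_filing_due(r, as_of, grace_months))
        except DegenerateDurationError:
            excluded.append((r, "degenerate_duration"))
        except ValueError as exc:
            excluded.append((r, str(exc)))
    count = sum(e.filing_due <= as_of for e in estimates)
    return OverdueResult(count=count, as_of=as_of, estimates=estimates, excluded=excluded)
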