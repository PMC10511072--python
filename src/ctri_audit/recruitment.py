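"""Recruitment-fraction audit: planned and actual India fractions,
high-recruitment flags with a cutoff sensitivity sweep, and the
actual-to-planned ratio categories.

The planned fraction is 'Sample Size from India' / 'Total Sample Size';
the actual fraction the analogous ratio of final enrollment numbers.
Invalid data (India exceeding the total, a zero total, missing values)
is tagged and propagated, never clipped or dropped: in a registry audit
these cases are findings in their own right.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple, Union

from ctri_audit.records import TrialRecord

#: "high recruitment": fraction from India at or above this, inclusive
DEFAULT_CUTOFF = 0.60
#: cutoffs of the sensitivity sweep (base +/- 5 and +/- 10 points)
DEFAULT_CUTOFFS: Tuple[float, ...] = (0.50, 0.55, 0.60, 0.65, 0.70)


class InvalidFraction(enum.Enum):
    """Why a recruitment fraction could not be computed."""

    MISSING = "MISSING"
    TOTAL_ZERO = "TOTAL_ZERO"
    INDIA_EXCEEDS_TOTAL = "INDIA_EXCEEDS_TOTAL"


Fraction = Union[float, InvalidFraction]


class RatioCategory(enum.Enum):
    """Bins for the ratio of actual to planned percent recruitment from India."""

    AT_OR_BELOW_1 = "AT_OR_BELOW_1"
    R_101_115 = "1.01-1.15"
    R_116_160 = "1.16-1.60"
    R_161_PLUS = "1.61+"
    INCORRECT_DATA = "INCORRECT_DATA"


def _fraction(total: Optional[int], india: Optional[int]) -> Fraction:
    if total is None or india is None:
        return InvalidFraction.MISSING
    if total == 0:
        return InvalidFraction.TOTAL_ZERO
    if india > total:
        return InvalidFraction.INDIA_EXCEEDS_TOTAL
    return india / total


def planned_fraction(record: TrialRecord) -> Fraction:
    """Planned fraction of recruitment from India, or an invalid-data tag."""
    return _fraction(record.total_sample_size, record.sample_size_india)


def actual_fraction(record: TrialRecord) -> Fraction:
    """Actual fraction of recruitment from India (final enrollments), or a tag."""
    return _fraction(record.final_enrollment_total, record.final_enrollment_india)


def is_valid(fraction: Fraction) -> bool:
    return not isinstance(fraction, InvalidFraction)


def flag_high(fraction: Fraction, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """True iff the fraction is at or above the cutoff (inclusive boundary)."""
    if isinstance(fraction, InvalidFraction):
        raise ValueError(f"fraction is invalid: {fraction}")
    return fraction >= cutoff


def sweep_cutoffs(
    base_cutoff: float = DEFAULT_CUTOFF, deltas: Sequence[float] = (0.05, 0.10)
) -> Tuple[float, ...]:
    cuts = {round(base_cutoff, 4)}
    for d in deltas:
        cuts.add(round(base_cutoff - abs(d), 4))
        cuts.add(round(base_cutoff + abs(d), 4))
    return tuple(sorted(cuts))


def sensitivity_sweep(
    records: Iterable[TrialRecord],
    base_cutoff: float = DEFAULT_CUTOFF,
    deltas: Sequence[float] = (0.05, 0.10),
) -> Dict[str, Dict[float, int]]:
    """Count high-recruitment trials at each sweep cutoff.

    Returns ``{"planned": {cutoff: count}, "actual": {cutoff: count}}``.
    Records with invalid fractions are excluded from that side's counts;
    counts are non-increasing in the cutoff by construction.
    """
    cutoffs = sweep_cutoffs(base_cutoff, deltas)
    out: Dict[str, Dict[float, int]] = {
        "planned": {c: 0 for c in cutoffs},
        "actual": {c: 0 for c in cutoffs},
    }
    for r in records:
        for kind, frac in (("planned", planned_fraction(r)), ("actual", actual_fraction(r))):
            if is_valid(frac):
                for c in cutoffs:
                    if frac >= c:
                        out[kind][c] += 1
    return out


def _round2(x: float) -> float:
    """Round half up to 2 decimal places (the granularity of the bin edges)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def ratio_category(
    planned: Fraction, actual: Fraction
) -> Tuple[Optional[float], RatioCategory]:
    """Ratio of actual to planned percent recruitment and its bin.

    The ratio is formed on the raw fractions (the percent scaling
    cancels), rounded half-up to two decimals, and binned into
    <= 1.00 / 1.01-1.15 / 1.16-1.60 / >= 1.61.  Any invalid input
    fraction makes the case INCORRECT_DATA with no ratio.
    """
    if not (is_valid(planned) and is_valid(actual)):
        return None, RatioCategory.INCORRECT_DATA
    if planned == 0:
        return None, RatioCategory.INCORRECT_DATA
    ratio = _round2(actual / planned)
    if ratio <= 1.00:
        return ratio, RatioCategory.AT_OR_BELOW_1
    if ratio <= 1.15:
        return ratio, RatioCategory.R_101_115
    if ratio <= 1.60:
        return ratio, RatioCategory.R_116_160
    return ratio, RatioCategory.R_161_PLUS


@dataclass(frozen=True)
class RecruitmentAudit:
    """Per-trial recruitment audit result."""

    ctri_number: str
    planned: Fraction
    actual: Fraction
    high_planned: Mapping[float, Optional[bool]]
    high_actual: Mapping[float, Optional[bool]]
    ratio: Optional[float]
    ratio_cat: RatioCategory

    @property
    def planned_valid(self) -> bool:
        return is_valid(self.planned)

    @property
    def actual_valid(self) -> bool:
        return is_valid(self.actual)


def audit_record(
    record: TrialRecord, cutoffs: Sequence[float] = DEFAULT_CUTOFFS
) -> RecruitmentAudit:
    """Full recruitment audit of one record at the given cutoffs.

    High-recruitment flags are ``None`` (undefined, excluded from
    counts) where the underlying fraction is invalid.
    """
    p = planned_fraction(record)
    a = actual_fraction(record)
    high_p = {c: (p >= c if is_valid(p) else None) for c in cutoffs}
    high_a = {c: (a >= c if is_valid(a) else None) for c in cutoffs}
    ratio, cat = ratio_category(p, a)
    return RecruitmentAudit(
        ctri_number=record.ctri_number,
        planned=p,
        actual=a,
        high_planned=high_p,
        high_actual=high_a,
        ratio=ratio,
        ratio_cat=cat,
    )
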