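"""Scope classification: Indian vs multinational vs everything else.

A record is accepted as Indian or multinational only when three
independent pairs of registry fields all agree on that scope:

1. recruitment statuses (India / Global),
2. dates of first enrollment (India / Global),
3. sample sizes (total / from India).

For a multinational trial both statuses must be applicable, both first
enrollment dates must be real dates, and the total sample size must
exceed the India sample size.  For an Indian trial the global-side
fields must be absent or marked not applicable and the two sample sizes
must be equal.  Terminated or suspended statuses, and trials with no
Indian arm at all, are set aside into their own categories.  Everything
else — the records whose fields contradict each other — lands in an
ambiguous or discrepancy bucket, with the fired rule recorded for audit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date
from typing import Iterable, List

from ctri_audit.records import Sentinel, TrialRecord


class PairVerdict(enum.Enum):
    """Sub-verdict of one field pair."""

    INDIAN = "indian-consistent"
    MULTINATIONAL = "multinational-consistent"
    TERMINATED = "terminated"
    SUSPENDED = "suspended"
    FOREIGN = "foreign-only"
    INCONSISTENT = "inconsistent"


class ScopeCategory(enum.Enum):
    INDIAN = "INDIAN"
    MULTINATIONAL = "MULTINATIONAL"
    FOREIGN_ONLY = "FOREIGN_ONLY"
    TERMINATED = "TERMINATED"
    SUSPENDED = "SUSPENDED"
    AMBIGUOUS_INDIAN_LIKE = "AMBIGUOUS_INDIAN_LIKE"
    AMBIGUOUS_MULTINATIONAL_LIKE = "AMBIGUOUS_MULTINATIONAL_LIKE"
    OTHER_DISCREPANCY = "OTHER_DISCREPANCY"


@dataclass(frozen=True)
class ScopeVerdict:
    """Classification of one record with the per-pair signals that produced it."""

    ctri_number: str
    category: ScopeCategory
    status_verdict: PairVerdict
    dates_verdict: PairVerdict
    sizes_verdict: PairVerdict
    rule_fired: str


def _norm_status(s: str) -> str:
    return s.strip().casefold()


def _is_na(s: str) -> bool:
    return _norm_status(s) in {"not applicable", "n/a", "na"}


def _is_real_date(v) -> bool:
    return isinstance(v, date)


def _date_absent(v) -> bool:
    return v in (Sentinel.DATE_MISSING, Sentinel.EMPTY)


def pair_verdict_status(record: TrialRecord) -> PairVerdict:
    """Judge the recruitment-status pair (India / Global).

    Terminated or Suspended in either field dominates.  Multinational
    needs both statuses present and neither "Not Applicable"; Indian
    needs an applicable India status with the global one absent or not
    applicable.  Both-not-applicable with an Indian sample registered is
    a contradiction, not a scope.
    """
    si = _norm_status(record.recruitment_status_india)
    sg = _norm_status(record.recruitment_status_global)
    if "terminated" in (si, sg):
        return PairVerdict.TERMINATED
    if "suspended" in (si, sg):
        return PairVerdict.SUSPENDED
    india_na = _is_na(record.recruitment_status_india)
    global_na = _is_na(record.recruitment_status_global)
    if india_na and sg and not global_na:
        return PairVerdict.FOREIGN
    if si and not india_na and sg and not global_na:
        return PairVerdict.MULTINATIONAL
    if si and not india_na and (not sg or global_na):
        return PairVerdict.INDIAN
    return PairVerdict.INCONSISTENT


def pair_verdict_enrollment_dates(record: TrialRecord) -> PairVerdict:
    """Judge the first-enrollment date pair (India / Global).

    Multinational requires real dates on both sides; Indian requires a
    real India date with the global one blank or "Date Missing"; a
    global date without an India date signals a trial with no Indian
    recruitment.
    """
    di = record.first_enrollment_india
    dg = record.first_enrollment_global
    if _is_real_date(di) and _is_real_date(dg):
        return PairVerdict.MULTINATIONAL
    if _is_real_date(di) and _date_absent(dg):
        return PairVerdict.INDIAN
    if _is_real_date(dg) and _date_absent(di):
        return PairVerdict.FOREIGN
    return PairVerdict.INCONSISTENT


def pair_verdict_sample_sizes(record: TrialRecord) -> PairVerdict:
    """Judge the sample-size pair (total / from India).

    Multinational requires total > India > 0; Indian requires
    total == India > 0; an India size of zero signals no Indian arm;
    a missing size, a zero total, or India exceeding the total is a
    contradiction.
    """
    total = record.total_sample_size
    india = record.sample_size_india
    if total is None or india is None:
        return PairVerdict.INCONSISTENT
    if india > total:
        return PairVerdict.INCONSISTENT
    if india == 0 and total > 0:
        return PairVerdict.FOREIGN
    if total == 0:
        return PairVerdict.INCONSISTENT
    if total == india:
        return PairVerdict.INDIAN
    return PairVerdict.MULTINATIONAL


def classify_scope(record: TrialRecord) -> ScopeVerdict:
    """Assign exactly one scope category from the three pair sub-verdicts.

    Precedence: terminated/suspended > foreign-only > unanimous scope >
    ambiguous-leaning > other-discrepancy.  A record is foreign-only when
    its registered India sample size is zero, or when the India status is
    not applicable while the global side is fully populated.  The
    ambiguous leaning follows the sample-size pair (equal sizes suggest
    an Indian trial, total exceeding India a multinational one), falling
    back to the majority of the three pair sub-verdicts when the size
    pair is itself contradictory.
    """
    sv = pair_verdict_status(record)
    dv = pair_verdict_enrollment_dates(record)
    zv = pair_verdict_sample_sizes(record)
    verdicts = (sv, dv, zv)

    def make(category: ScopeCategory, rule: str) -> ScopeVerdict:
        return ScopeVerdict(
            ctri_number=record.ctri_number,
            category=category,
            status_verdict=sv,
            dates_verdict=dv,
            sizes_verdict=zv,
            rule_fired=rule,
        )

    if sv is PairVerdict.TERMINATED:
        return make(ScopeCategory.TERMINATED, "status-terminated")
    if sv is PairVerdict.SUSPENDED:
        return make(ScopeCategory.SUSPENDED, "status-suspended")
    if zv is PairVerdict.FOREIGN:
        return make(ScopeCategory.FOREIGN_ONLY, "india-sample-size-zero")
    if sv is PairVerdict.FOREIGN and _is_real_date(record.first_enrollment_global):
        return make(ScopeCategory.FOREIGN_ONLY, "india-status-na-global-populated")
    if all(v is PairVerdict.INDIAN for v in verdicts):
        return make(ScopeCategory.INDIAN, "all-pairs-indian")
    if all(v is PairVerdict.MULTINATIONAL for v in verdicts):
        return make(ScopeCategory.MULTINATIONAL, "all-pairs-multinational")
    if zv is PairVerdict.INDIAN:
        return make(
            ScopeCategory.AMBIGUOUS_INDIAN_LIKE, "sizes-equal-but-pairs-disagree"
        )
    if zv is PairVerdict.MULTINATIONAL:
        return make(
            ScopeCategory.AMBIGUOUS_MULTINATIONAL_LIKE,
            "total-exceeds-india-but-pairs-disagree",
        )
    n_indian = sum(v is PairVerdict.INDIAN for v in verdicts)
    n_multi = sum(v is PairVerdict.MULTINATIONAL for v in verdicts)
    if n_indian >= 2:
        return make(ScopeCategory.AMBIGUOUS_INDIAN_LIKE, "pair-majority-indian")
    if n_multi >= 2:
        return make(
            ScopeCategory.AMBIGUOUS_MULTINATIONAL_LIKE, "pair-majority-multinational"
        )
    return make(ScopeCategory.OTHER_DISCREPANCY, "no-coherent-scope-signal")


def classify_all(records: Iterable[TrialRecord]) -> List[ScopeVerdict]:
    """Classify every record; each receives exactly one category."""
    return [classify_scope(r) for r in records]
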