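"""Cohort filters upstream of scope classification.

The audit cohort is built in three steps: registration inside the study
window (inclusive on both ends), trial type "Interventional", and a
phase label denoting phase 2, phase 3 or a combined 2/3 label.  Every
dropped record is tallied with a reason code so the processing cascade
is fully reconstructible from the filter outputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, List, Sequence, Tuple

from ctri_audit.records import TrialRecord


@dataclass
class FilterResult:
    """Kept records plus (record, reason) pairs for everything dropped."""

    kept: List[TrialRecord]
    dropped: List[Tuple[TrialRecord, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.kept)

    def __len__(self) -> int:
        return len(self.kept)


@dataclass
class CascadeCounts:
    """Counts at each stage of the processing cascade."""

    total_downloaded: int = 0
    in_window: int = 0
    interventional: int = 0
    phase2or3: int = 0
    indian: int = 0
    multinational: int = 0
    other: int = 0

    def check(self) -> None:
        assert self.total_downloaded >= self.in_window >= self.interventional >= self.phase2or3
        assert self.indian + self.multinational + self.other == self.phase2or3


def filter_window(
    records: Iterable[TrialRecord], start: date, end: date
) -> FilterResult:
    """Keep records registered in [start, end], both bounds inclusive.

    Records whose registration date failed to parse are dropped with a
    reason rather than silently excluded.
    """
    if start > end:
        raise ValueError(f"start {start} after end {end}")
    kept, dropped = [], []
    for r in records:
        if r.registration_date is None:
            dropped.append((r, "registration_date_unparseable"))
        elif start <= r.registration_date <= end:
            kept.append(r)
        else:
            dropped.append((r, "outside_window"))
    return FilterResult(kept=kept, dropped=dropped)


def filter_interventional(records: Iterable[TrialRecord]) -> FilterResult:
    """Keep records whose trial type is Interventional (case/space-insensitive)."""
    kept, dropped = [], []
    for r in records:
        ttype = r.trial_type.strip().casefold()
        if ttype == "interventional":
            kept.append(r)
        elif not ttype:
            dropped.append((r, "trial_type_missing"))
        else:
            dropped.append((r, "not_interventional"))
    return FilterResult(kept=kept, dropped=dropped)


#: phase tokens accepted as phase 2 or phase 3 (after stripping a
#: leading "phase" and lowercasing); editable for other registries'
#: label dialects.
DEFAULT_PHASE_TOKENS: Sequence[str] = ("2", "3", "ii", "iii", "2/3", "ii/iii")

_PHASE_SPLIT = re.compile(r"[/,;]| and ")


def _phase_tokens(phase: str) -> List[str]:
    text = phase.strip().casefold()
    parts = [p.strip() for p in _PHASE_SPLIT.split(text) if p.strip()]
    tokens = []
    for p in parts:
        p = re.sub(r"^phase\s*", "", p)
        tokens.append(p)
    return tokens


def filter_phase(
    records: Iterable[TrialRecord],
    allowed_tokens: Sequence[str] = DEFAULT_PHASE_TOKENS,
) -> FilterResult:
    """Keep records whose phase label denotes phase 2 and/or phase 3.

    Matching is token-based: the label is split on separators
    ("Phase 2/Phase 3" -> ["2", "3"]) and kept if any token is in the
    allow-list.  "Phase 1" is dropped; "Phase 1/Phase 2" is kept because
    part of the trial is in an audited phase.
    """
    allowed = {t.casefold() for t in allowed_tokens}
    kept, dropped = [], []
    for r in records:
        tokens = _phase_tokens(r.phase)
        if any(t in allowed for t in tokens):
            kept.append(r)
        elif not tokens:
            dropped.append((r, "phase_missing"))
        else:
            dropped.append((r, "phase_not_2_or_3"))
    return FilterResult(kept=kept, dropped=dropped)
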