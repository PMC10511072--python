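"""Assembled audit report: the full cascade run end to end.

``run_audit`` takes a list of records and a configuration and produces
an :class:`AuditReport` holding the cascade counts, the scope
breakdown, the completion partition sizes, high-recruitment counts per
cutoff for both sets, the actual-to-planned ratio table, the invalid
enrollment-data cases, and the overdue count — together with the
per-trial tables backing every count.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import date
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from ctri_audit.cohort import (
    CascadeCounts,
    DEFAULT_PHASE_TOKENS,
    filter_interventional,
    filter_phase,
    filter_window,
)
from ctri_audit.completion import partition_by_completion
from ctri_audit.overdue import DEFAULT_AS_OF, DEFAULT_GRACE_MONTHS, count_overdue
from ctri_audit.records import TrialRecord
from ctri_audit.recruitment import (
    DEFAULT_CUTOFF,
    RatioCategory,
    audit_record,
    is_valid,
    sweep_cutoffs,
)
from ctri_audit.scope import ScopeCategory, classify_scope

REPORT_SCHEMA_VERSION = 1


@dataclass
class AuditConfig:
    """Tunable parameters of an audit run."""

    window_start: date = date(2013, 1, 1)
    window_end: date = date(2020, 12, 31)
    cutoff: float = DEFAULT_CUTOFF
    sweep_deltas: Tuple[float, ...] = (0.05, 0.10)
    as_of: date = DEFAULT_AS_OF
    grace_months: int = DEFAULT_GRACE_MONTHS
    phase_tokens: Tuple[str, ...] = tuple(DEFAULT_PHASE_TOKENS)

    def digest(self) -> str:
        payload = json.dumps(
            {
                "window": [self.window_start.isoformat(), self.window_end.isoformat()],
                "cutoff": self.cutoff,
                "sweep_deltas": list(self.sweep_deltas),
                "as_of": self.as_of.isoformat(),
                "grace_months": self.grace_months,
                "phase_tokens": list(self.phase_tokens),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class AuditReport:
    """All counts and per-trial tables of one audit run."""

    cascade: CascadeCounts
    scope_breakdown: Dict[str, int]
    completion_sizes: Dict[str, int]
    planned_high_completed: Dict[float, int]
    actual_high_completed: Dict[float, int]
    planned_high_not_completed: Dict[float, int]
    ratio_table: Dict[str, int]
    invalid_data: List[Tuple[str, str]]
    overdue_count: int
    overdue_denominator: int
    overdue_excluded: int
    as_of: date
    config_digest: str
    verdicts: pd.DataFrame = field(repr=False, default=None)
    recruitment: pd.DataFrame = field(repr=False, default=None)
    estimates: pd.DataFrame = field(repr=False, default=None)

    def check_consistency(self) -> None:
        """Internal count consistency; raises AssertionError on violation."""
        self.cascade.check()
        assert sum(self.scope_breakdown.values()) == self.cascade.phase2or3
        assert sum(self.completion_sizes.values()) == self.cascade.multinational
        for counts in (
            self.planned_high_completed,
            self.actual_high_completed,
            self.planned_high_not_completed,
        ):
            cuts = sorted(counts)
            assert all(counts[a] >= counts[b] for a, b in zip(cuts, cuts[1:]))
        assert self.overdue_count <= self.overdue_denominator
        assert (
            self.overdue_denominator + self.overdue_excluded
            == self.completion_sizes["not_completed"]
        )

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "config_digest": self.config_digest,
            "cascade": vars(self.cascade),
            "scope_breakdown": self.scope_breakdown,
            "completion_sizes": self.completion_sizes,
            "planned_high_completed": {str(k): v for k, v in self.planned_high_completed.items()},
            "actual_high_completed": {str(k): v for k, v in self.actual_high_completed.items()},
            "planned_high_not_completed": {
                str(k): v for k, v in self.planned_high_not_completed.items()
            },
            "ratio_table": self.ratio_table,
            "invalid_data": [list(t) for t in self.invalid_data],
            "overdue": {
                "count": self.overdue_count,
                "denominator": self.overdue_denominator,
                "excluded": self.overdue_excluded,
                "as_of": self.as_of.isoformat(),
            },
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def render_text(self) -> str:
        """Human-readable summary; percentages to the nearest integer."""
        c = self.cascade
        lines = [
            "CTRI registry audit",
            "===================",
            f"records read:            {c.total_downloaded}",
            f"in window:               {c.in_window}",
            f"interventional:          {c.interventional}",
            f"phase 2/3:               {c.phase2or3}",
            f"  Indian:                {c.indian}",
            f"  multinational:         {c.multinational}",
            f"  other:                 {c.other}",
            "",
            f"completed set:           {self.completion_sizes['completed']}",
            f"not completed set:       {self.completion_sizes['not_completed']}",
            f"mixed completion:        {self.completion_sizes['mixed']}",
            "",
        ]
        nc = self.completion_sizes["completed"] or 1
        nn = self.completion_sizes["not_completed"] or 1
        hp = self.planned_high_completed.get(DEFAULT_CUTOFF, 0)
        ha = self.actual_high_completed.get(DEFAULT_CUTOFF, 0)
        hn = self.planned_high_not_completed.get(DEFAULT_CUTOFF, 0)
        lines += [
            f"completed, planned >=60%:     {hp} ({round(100 * hp / nc)}%)",
            f"completed, actual >=60%:      {ha} ({round(100 * ha / nc)}%)",
            f"not completed, planned >=60%: {hn} ({round(100 * hn / nn)}%)",
            f"invalid enrollment data:      {len(self.invalid_data)}",
            "",
            "actual:planned ratio table (completed set):",
        ]
        for cat in RatioCategory:
            lines.append(f"  {cat.value:15s} {self.ratio_table.get(cat.value, 0)}")
        pct = round(100 * self.overdue_count / (self.overdue_denominator or 1))
        lines += [
            "",
            f"overdue at {self.as_of.isoformat()}: {self.overdue_count} of "
            f"{self.overdue_denominator} ({pct}%)"
            + (f"; {self.overdue_excluded} excluded" if self.overdue_excluded else ""),
        ]
        return "\n".join(lines)


def run_audit(
    records: Iterable[TrialRecord], config: Optional[AuditConfig] = None
) -> AuditReport:
    """Run the full audit cascade over a record set."""
    config = config or AuditConfig()
    records = list(records)
    cutoffs = sweep_cutoffs(config.cutoff, config.sweep_deltas)

    in_window = filter_window(records, config.window_start, config.window_end)
    interventional = filter_interventional(in_window.kept)
    phase23 = filter_phase(interventional.kept, config.phase_tokens)

    verdicts = [classify_scope(r) for r in phase23.kept]
    by_cat: Dict[ScopeCategory, List[TrialRecord]] = {c: [] for c in ScopeCategory}
    for r, v in zip(phase23.kept, verdicts):
        by_cat[v.category].append(r)

    scope_breakdown = {c.value: len(by_cat[c]) for c in ScopeCategory}
    multinational = by_cat[ScopeCategory.MULTINATIONAL]
    cascade = CascadeCounts(
        total_downloaded=len(records),
        in_window=len(in_window.kept),
        interventional=len(interventional.kept),
        phase2or3=len(phase23.kept),
        indian=scope_breakdown["INDIAN"],
        multinational=scope_breakdown["MULTINATIONAL"],
        other=len(phase23.kept)
        - scope_breakdown["INDIAN"]
        - scope_breakdown["MULTINATIONAL"],
    )

    partition = partition_by_completion(multinational)
    completion_sizes = {
        "completed": len(partition.completed),
        "not_completed": len(partition.not_completed),
        "mixed": len(partition.mixed),
    }

    audits_completed = [audit_record(r, cutoffs) for r in partition.completed]
    audits_not_completed = [audit_record(r, cutoffs) for r in partition.not_completed]

    planned_high_completed = {
        c: sum(bool(a.high_planned[c]) for a in audits_completed) for c in cutoffs
    }
    actual_high_completed = {
        c: sum(bool(a.high_actual[c]) for a in audits_completed) for c in cutoffs
    }
    planned_high_not_completed = {
        c: sum(bool(a.high_planned[c]) for a in audits_not_completed) for c in cutoffs
    }

    ratio_table = {cat.value: 0 for cat in RatioCategory}
    invalid_data: List[Tuple[str, str]] = []
    for a in audits_completed:
        ratio_table[a.ratio_cat.value] += 1
        for frac, side in ((a.planned, "planned"), (a.actual, "actual")):
            if not is_valid(frac):
                invalid_data.append((a.ctri_number, f"{side}:{frac.value}"))

    overdue = count_overdue(partition.not_completed, config.as_of, config.grace_months)

    completion_of = {r.ctri_number: "completed" for r in partition.completed}
    completion_of.update({r.ctri_number: "not_completed" for r in partition.not_completed})
    completion_of.update({r.ctri_number: "mixed" for r in partition.mixed})
    verdict_df = pd.DataFrame(
        [
            {
                "ctri_number": v.ctri_number,
                "category": v.category.value,
                "rule_fired": v.rule_fired,
                "status_verdict": v.status_verdict.value,
                "dates_verdict": v.dates_verdict.value,
                "sizes_verdict": v.sizes_verdict.value,
                "completion": completion_of.get(v.ctri_number, ""),
            }
            for v in verdicts
        ]
    )
    recruit_df = pd.DataFrame(
        [
            {
                "ctri_number": a.ctri_number,
                "set": s,
                "planned_fraction": a.planned if is_valid(a.planned) else None,
                "planned_tag": None if is_valid(a.planned) else a.planned.value,
                "actual_fraction": a.actual if is_valid(a.actual) else None,
                "actual_tag": None if is_valid(a.actual) else a.actual.value,
                **{f"planned_high_{c}": a.high_planned[c] for c in cutoffs},
                **{f"actual_high_{c}": a.high_actual[c] for c in cutoffs},
                "ratio": a.ratio,
                "ratio_category": a.ratio_cat.value,
            }
            for s, audits in (("completed", audits_completed), ("not_completed", audits_not_completed))
            for a in audits
        ]
    )
    est_df = pd.DataFrame(
        [
            {
                "ctri_number": e.ctri_number,
                "overall_first_enrollment": e.overall_first_enrollment.isoformat(),
                "duration_months": e.duration_months,
                "margin_class": e.margin_class.value,
                "adjusted_months": e.adjusted_months,
                "estimated_completion": e.estimated_completion.isoformat(),
                "filing_due": e.filing_due.isoformat(),
                "overdue": e.filing_due <= config.as_of,
            }
            for e in overdue.estimates
        ]
    )

    report = AuditReport(
        cascade=cascade,
        scope_breakdown=scope_breakdown,
        completion_sizes=completion_sizes,
        planned_high_completed=planned_high_completed,
        actual_high_completed=actual_high_completed,
        planned_high_not_completed=planned_high_not_completed,
        ratio_table=ratio_table,
        invalid_data=invalid_data,
        overdue_count=overdue.count,
        overdue_denominator=overdue.denominator,
        overdue_excluded=len(overdue.excluded),
        as_of=config.as_of,
        config_digest=config.digest(),
        verdicts=verdict_df,
        recruitment=recruit_df,
        estimates=est_df,
    )
    report.check_consistency()
    return report
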