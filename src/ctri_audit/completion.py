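"""Partition multinational records by the two study-completion date fields.

A multinational record belongs to the Completed Set when both the India
and Global completion-date fields carry real dates, and to the Not
Completed Set when both carry the registry sentinel "Applicable only for
Completed/Terminated trials".  Records matching neither definition (one
date and one sentinel, blanks, "Date Missing") go into an explicit mixed
bucket rather than being dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, List

from ctri_audit.records import Sentinel, TrialRecord


@dataclass
class CompletionPartition:
    """Completed / Not Completed / mixed split of a multinational set."""

    completed: List[TrialRecord] = field(default_factory=list)
    not_completed: List[TrialRecord] = field(default_factory=list)
    mixed: List[TrialRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.completed) + len(self.not_completed) + len(self.mixed)


def partition_by_completion(
    multinational_records: Iterable[TrialRecord],
) -> CompletionPartition:
    """Split records already classified multinational by completion status."""
    part = CompletionPartition()
    for r in multinational_records:
        ci, cg = r.completion_date_india, r.completion_date_global
        if isinstance(ci, date) and isinstance(cg, date):
            part.completed.append(r)
        elif ci is Sentinel.COMPLETED_SENTINEL and cg is Sentinel.COMPLETED_SENTINEL:
            part.not_completed.append(r)
        else:
            part.mixed.append(r)
    return part
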