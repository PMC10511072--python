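"""Scope classifier: pair sub-verdicts, the unanimity rule, worked examples."""

import dataclasses
from datetime import date

import pytest

from ctri_audit.records import Sentinel, TrialRecord
from ctri_audit.scope import (
    PairVerdict,
    ScopeCategory,
    classify_scope,
    pair_verdict_enrollment_dates,
    pair_verdict_sample_sizes,
    pair_verdict_status,
)

SCOPE_OF_TRUTH = {
    "indian": ScopeCategory.INDIAN,
    "multinational": ScopeCategory.MULTINATIONAL,
    "foreign_only": ScopeCategory.FOREIGN_ONLY,
    "terminated": ScopeCategory.TERMINATED,
    "suspended": ScopeCategory.SUSPENDED,
    "ambiguous_indian": ScopeCategory.AMBIGUOUS_INDIAN_LIKE,
    "ambiguous_multinational": ScopeCategory.AMBIGUOUS_MULTINATIONAL_LIKE,
    "other_discrepancy": ScopeCategory.OTHER_DISCREPANCY,
}


def _rec(**kw):
    return TrialRecord(ctri_number="CTRI/2015/01/000001", **kw)


class TestStatusPair:
    def test_both_not_applicable_with_india_sample_is_inconsistent(self):
        rec = _rec(
            recruitment_status_india="Not Applicable",
            recruitment_status_global="Not Applicable",
            sample_size_india=700,
        )
        assert pair_verdict_status(rec) is PairVerdict.INCONSISTENT

    def test_both_applicable_is_multinational(self):
        rec = _rec(recruitment_status_india="Completed", recruitment_status_global="Completed")
        assert pair_verdict_status(rec) is PairVerdict.MULTINATIONAL

    def test_india_only_is_indian(self):
        rec = _rec(recruitment_status_india="Open to Recruitment",
                   recruitment_status_global="Not Applicable")
        assert pair_verdict_status(rec) is PairVerdict.INDIAN

    @pytest.mark.parametrize("field_side", ["recruitment_status_india", "recruitment_status_global"])
    def test_terminated_dominates(self, field_side):
        rec = _rec(**{field_side: "Terminated"},
                   **{("recruitment_status_global" if "india" in field_side else
                       "recruitment_status_india"): "Completed"})
        assert pair_verdict_status(rec) is PairVerdict.TERMINATED

    def test_suspended_in_india(self):
        rec = _rec(recruitment_status_india="Suspended", recruitment_status_global="Open")
        assert pair_verdict_status(rec) is PairVerdict.SUSPENDED

    def test_india_na_with_global_populated_signals_foreign(self):
        rec = _rec(recruitment_status_india="Not Applicable",
                   recruitment_status_global="Completed")
        assert pair_verdict_status(rec) is PairVerdict.FOREIGN


class TestEnrollmentDatePair:
    def test_both_dates_is_multinational(self):
        rec = _rec(first_enrollment_india=date(2016, 1, 1),
                   first_enrollment_global=date(2016, 2, 1))
        assert pair_verdict_enrollment_dates(rec) is PairVerdict.MULTINATIONAL

    def test_global_date_with_india_missing_is_not_indian_or_multinational(self):
        rec = _rec(first_enrollment_india=Sentinel.DATE_MISSING,
                   first_enrollment_global=date(2016, 2, 15))
        assert pair_verdict_enrollment_dates(rec) is PairVerdict.FOREIGN

    def test_india_date_with_global_missing_is_indian(self):
        rec = _rec(first_enrollment_india=date(2015, 8, 7),
                   first_enrollment_global=Sentinel.DATE_MISSING)
        assert pair_verdict_enrollment_dates(rec) is PairVerdict.INDIAN

    def test_both_missing_is_inconsistent(self):
        rec = _rec()
        assert pair_verdict_enrollment_dates(rec) is PairVerdict.INCONSISTENT


class TestSampleSizePair:
    @pytest.mark.parametrize(
        "total, india, expected",
        [
            (700, 700, PairVerdict.INDIAN),
            (40, 20, PairVerdict.MULTINATIONAL),
            (100, 120, PairVerdict.INCONSISTENT),  # India exceeds total
            (100, 0, PairVerdict.FOREIGN),
            (0, 0, PairVerdict.INCONSISTENT),
            (None, 50, PairVerdict.INCONSISTENT),
            (50, None, PairVerdict.INCONSISTENT),
        ],
    )
    def test_size_relations(self, total, india, expected):
        rec = _rec(total_sample_size=total, sample_size_india=india)
        assert pair_verdict_sample_sizes(rec) is expected


class TestClassify:
    def test_worked_examples_not_indian_or_multinational(self, worked_fixture):
        for rec in worked_fixture[:3]:
            cat = classify_scope(rec).category
            assert cat not in (ScopeCategory.INDIAN, ScopeCategory.MULTINATIONAL)

    def test_worked_example_categories(self, worked_fixture):
        cats = [classify_scope(r).category for r in worked_fixture]
        assert cats == [
            ScopeCategory.AMBIGUOUS_INDIAN_LIKE,        # equal sizes, NA statuses, global date
            ScopeCategory.AMBIGUOUS_INDIAN_LIKE,        # equal sizes, global side populated
            ScopeCategory.AMBIGUOUS_MULTINATIONAL_LIKE, # total > India, global side absent
            ScopeCategory.INDIAN,
            ScopeCategory.MULTINATIONAL,
        ]

    def test_consistent_multinational(self, consistent_multinational):
        v = classify_scope(consistent_multinational)
        assert v.category is ScopeCategory.MULTINATIONAL
        assert v.rule_fired == "all-pairs-multinational"

    def test_na_status_with_india_sample_never_scoped(self):
        rec = _rec(
            total_sample_size=100, sample_size_india=50,
            recruitment_status_india="Not Applicable",
            recruitment_status_global="Not Applicable",
            first_enrollment_india=date(2016, 1, 1),
            first_enrollment_global=date(2016, 1, 1),
        )
        assert classify_scope(rec).category not in (
            ScopeCategory.INDIAN, ScopeCategory.MULTINATIONAL
        )

    def test_every_record_gets_exactly_one_category(self, default_dataset):
        records, _ = default_dataset
        for rec in records:
            assert isinstance(classify_scope(rec).category, ScopeCategory)

    MUTATIONS = [
        {"recruitment_status_global": "Not Applicable"},
        {"recruitment_status_india": "Not Applicable"},
        {"recruitment_status_india": ""},
        {"first_enrollment_global": Sentinel.DATE_MISSING},
        {"first_enrollment_india": Sentinel.DATE_MISSING},
        {"sample_size_india": 200},   # equal to total
        {"sample_size_india": 250},   # exceeds total
        {"total_sample_size": None},
    ]

    @pytest.mark.parametrize("mutation", MUTATIONS, ids=lambda m: repr(m))
    def test_unanimity_any_conflicting_field_demotes(self, consistent_multinational, mutation):
        mutated = dataclasses.replace(consistent_multinational, **mutation)
        assert classify_scope(mutated).category is not ScopeCategory.MULTINATIONAL

    def test_ground_truth_recovery_zero_error(self, zero_error_dataset):
        records, truth = zero_error_dataset
        by_id = {r.ctri_number: r for r in records}
        cohort = truth[truth.scope != ""]
        assert len(cohort) > 100
        for _, row in cohort.iterrows():
            got = classify_scope(by_id[row.ctri_number]).category
            assert got is SCOPE_OF_TRUTH[row.scope], row.ctri_number
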