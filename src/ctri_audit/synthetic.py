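"""Seeded synthetic registry-snapshot generator with ground-truth labels.

The generator emulates the CTRI field dialect the audit reads: the
dd/mm/yyyy dates, the sentinel strings ("Date Missing", "Not
Applicable", "Applicable only for Completed/Terminated trials"), the
scope structure of phase-2/3 interventional records (Indian,
multinational, entirely foreign, terminated, suspended, ambiguous,
discrepant), right-skewed planned-recruitment fractions with a small
high tail, duration mixes spanning the three margin classes, and the
documented data-error modes (India enrollment exceeding the total,
zero final totals, not-applicable statuses alongside an Indian sample,
missing global enrollment dates, misuse of the completion sentinel).

Ground truth is returned in a separate table, never embedded in the
records, so it cannot leak into the audit path.  The same seed and
configuration always reproduce the identical dataset.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from ctri_audit.records import Duration, Sentinel, TrialRecord

_SCOPES = (
    "indian",
    "multinational",
    "foreign_only",
    "terminated",
    "suspended",
    "ambiguous_indian",
    "ambiguous_multinational",
    "other_discrepancy",
)

_COMPLETIONS = ("completed", "not_completed", "mixed")

_ERROR_MODES = (
    "india_exceeds_total_final",
    "total_final_zero",
    "status_na_with_india_sample",
    "date_missing_global",
    "completed_sentinel_misuse",
)


def _default_scope_mix() -> Dict[str, float]:
    # proportions of the eight scope outcomes among phase-2/3
    # interventional registry records (dominated by purely Indian trials,
    # with multinational and ambiguous minorities)
    n = 6437.0
    return {
        "indian": 5580 / n,
        "multinational": 473 / n,
        "foreign_only": 22 / n,
        "terminated": 77 / n,
        "suspended": 1 / n,
        "ambiguous_indian": 256 / n,
        "ambiguous_multinational": 18 / n,
        "other_discrepancy": 10 / n,
    }


def _default_completion_mix() -> Dict[str, float]:
    # multinational records: a small completed minority, a dominant
    # not-updated majority, and a residue with half-filled fields
    n = 473.0
    return {"completed": 62 / n, "not_completed": 362 / n, "mixed": 49 / n}


def _default_error_rates() -> Dict[str, float]:
    return {
        "india_exceeds_total_final": 0.03,
        "total_final_zero": 0.03,
        "status_na_with_india_sample": 0.01,
        "date_missing_global": 0.01,
        "completed_sentinel_misuse": 0.01,
    }


def _default_actual_factor() -> Dict[str, float]:
    # distribution of the actual/planned multiplicative factor: most
    # trials recruit at or below plan; the >1 mass is split so every
    # over-recruitment ratio bin is populated, including >=1.61
    return {"at_or_below_1": 0.76, "r_101_115": 0.10, "r_116_160": 0.05, "r_161_plus": 0.09}


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic snapshot generator.

    Defaults mirror the stage proportions, fraction distributions and
    error modes of a real CTRI snapshot so that every pipeline code
    path is exercised at default settings.
    """

    n_records: int = 1000
    seed: int = 0
    window: Tuple[date, date] = (date(2013, 1, 1), date(2020, 12, 31))
    p_in_window: float = 26889 / 39821
    p_interventional: float = 19361 / 26889  # given in-window
    p_phase23: float = 6437 / 19361  # given interventional
    scope_mix: Dict[str, float] = field(default_factory=_default_scope_mix)
    completion_mix: Dict[str, float] = field(default_factory=_default_completion_mix)
    #: planned India fraction for multinational trials: Beta(2, 6) body
    #: with a uniform [0.6, 1) tail of this mass (the "high" planners)
    planned_high_mass: float = 0.08
    planned_beta: Tuple[float, float] = (2.0, 6.0)
    actual_factor_mix: Dict[str, float] = field(default_factory=_default_actual_factor)
    #: duration-class mix: short (<=24 mo), intermediate (25-60), long (>60)
    duration_mix: Tuple[float, float, float] = (0.55, 0.35, 0.10)
    error_rates: Dict[str, float] = field(default_factory=_default_error_rates)

    def validate(self) -> None:
        for name, mix in (("scope_mix", self.scope_mix), ("completion_mix", self.completion_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{name} has negative probability")
        if set(self.scope_mix) != set(_SCOPES):
            raise ValueError(f"scope_mix keys must be {_SCOPES}")
        if set(self.completion_mix) != set(_COMPLETIONS):
            raise ValueError(f"completion_mix keys must be {_COMPLETIONS}")
        if abs(sum(self.duration_mix) - 1.0) > 1e-9:
            raise ValueError("duration_mix must sum to 1")
        if abs(sum(self.actual_factor_mix.values()) - 1.0) > 1e-9:
            raise ValueError("actual_factor_mix must sum to 1")
        unknown = set(self.error_rates) - set(_ERROR_MODES)
        if unknown:
            raise ValueError(f"unknown error modes: {sorted(unknown)}")

    def zero_error(self) -> "GeneratorConfig":
        """Copy of this config with every error rate set to zero."""
        return replace(self, error_rates={m: 0.0 for m in _ERROR_MODES})


def _days_in_month(y: int, m: int) -> int:
    return calendar.monthrange(y, m)[1]


def _add_months_clamped(d: date, n: int) -> date:
    """Month addition with day clamping, independent of the audit path."""
    total = d.year * 12 + (d.month - 1) + n
    y, m0 = divmod(total, 12)
    m = m0 + 1
    return date(y, m, min(d.day, _days_in_month(y, m)))


def _rand_date(rng: np.random.Generator, start: date, end: date) -> date:
    span = (end - start).days
    return start + timedelta(days=int(rng.integers(0, span + 1)))


def _draw_duration(rng: np.random.Generator, mix: Tuple[float, float, float]) -> Tuple[Duration, int]:
    """Draw a (years, months, days) duration and its normalized months."""
    cls = rng.choice(3, p=list(mix))
    if cls == 0:
        target = int(rng.integers(3, 25))  # 3..24 months normalized
    elif cls == 1:
        target = int(rng.integers(25, 61))
    else:
        target = int(rng.integers(61, 121))
    has_days = bool(rng.random() < 0.3) and target > 1
    mo_total = target - (1 if has_days else 0)
    dur = Duration(
        years=mo_total // 12,
        months=mo_total % 12,
        days=int(rng.integers(1, 29)) if has_days else 0,
    )
    return dur, target


def _draw_planned_fraction(rng: np.random.Generator, cfg: GeneratorConfig) -> float:
    if rng.random() < cfg.planned_high_mass:
        return float(rng.uniform(0.60, 0.999))
    a, b = cfg.planned_beta
    return float(min(rng.beta(a, b), 0.999))


def _draw_actual_factor(rng: np.random.Generator, cfg: GeneratorConfig) -> float:
    keys = list(cfg.actual_factor_mix)
    probs = [cfg.actual_factor_mix[k] for k in keys]
    bin_ = keys[int(rng.choice(len(keys), p=probs))]
    if bin_ == "at_or_below_1":
        return float(rng.uniform(0.55, 1.0))
    if bin_ == "r_101_115":
        return float(rng.uniform(1.02, 1.15))
    if bin_ == "r_116_160":
        return float(rng.uniform(1.17, 1.60))
    return float(rng.uniform(1.62, 6.0))


_ACTIVE_STATUSES = ("Open to Recruitment", "Closed to Recruitment of Participants", "Completed")


def generate(config: GeneratorConfig) -> Tuple[List[TrialRecord], pd.DataFrame]:
    """Generate a synthetic registry snapshot and its ground-truth table.

    Returns the records plus a DataFrame with one row per record giving
    the stage it should survive to, its true scope and completion
    status, the true planned/actual fractions, the true filing-due date
    and overdue flag, and any injected error modes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    w_start, w_end = config.window
    records: List[TrialRecord] = []
    truth_rows: List[dict] = []

    scope_keys = list(_SCOPES)
    scope_p = [config.scope_mix[k] for k in scope_keys]
    comp_keys = list(_COMPLETIONS)
    comp_p = [config.completion_mix[k] for k in comp_keys]

    for i in range(config.n_records):
        in_window = bool(rng.random() < config.p_in_window)
        if in_window:
            reg = _rand_date(rng, w_start, w_end)
        elif rng.random() < 0.5:
            reg = _rand_date(rng, date(2008, 1, 1), w_start - timedelta(days=1))
        else:
            reg = _rand_date(rng, w_end + timedelta(days=1), date(2022, 1, 27))
        serial = 100000 + i
        ctri = f"CTRI/{reg.year}/{reg.month:02d}/{serial:06d}"

        interventional = bool(rng.random() < config.p_interventional)
        trial_type = "Interventional" if interventional else str(
            rng.choice(["Observational", "PMS", "BA/BE"])
        )
        phase23 = bool(rng.random() < config.p_phase23)
        if phase23:
            phase = str(rng.choice(["Phase 2", "Phase 3", "Phase 2/Phase 3"]))
        else:
            phase = str(rng.choice(["Phase 1", "Phase 4", "N/A"]))

        in_cohort = in_window and interventional and phase23
        scope = scope_keys[int(rng.choice(len(scope_keys), p=scope_p))] if in_cohort else "indian"

        dur, dur_months = _draw_duration(rng, config.duration_mix)
        enroll_start = reg + timedelta(days=int(rng.integers(15, 365)))

        truth: dict = {
            "ctri_number": ctri,
            "in_window": in_window,
            "interventional": interventional,
            "phase23": phase23,
            "scope": scope if in_cohort else "",
            "completion": "",
            "planned_fraction": np.nan,
            "actual_fraction": np.nan,
            "duration_months": dur_months,
            "filing_due": "",
            "overdue": False,
            "errors": "",
        }

        rec = _build_record(rng, config, ctri, reg, trial_type, phase, scope, dur, enroll_start, truth)
        if in_cohort:
            _maybe_inject_errors(rng, config, rec, scope, truth)
        records.append(rec)
        truth_rows.append(truth)

    return records, pd.DataFrame(truth_rows)


def _build_record(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    ctri: str,
    reg: date,
    trial_type: str,
    phase: str,
    scope: str,
    dur: Duration,
    enroll_start: date,
    truth: dict,
) -> TrialRecord:
    sponsor = str(rng.choice(["Aurora Pharma Ltd", "Global Biologics Inc", "NovaCure AG", "Meridian CRO"]))
    country = str(rng.choice(["India", "United States", "Sweden", "South Korea", "Switzerland"]))
    rec = TrialRecord(
        ctri_number=ctri,
        registration_date=reg,
        trial_type=trial_type,
        phase=phase,
        estimated_duration=dur,
        primary_sponsor=sponsor,
        sponsor_country=country,
    )

    if scope == "indian":
        total = int(rng.integers(20, 1000))
        rec.total_sample_size = total
        rec.sample_size_india = total
        rec.recruitment_status_india = str(rng.choice(_ACTIVE_STATUSES))
        rec.recruitment_status_global = "Not Applicable"
        rec.first_enrollment_india = enroll_start
        rec.first_enrollment_global = Sentinel.DATE_MISSING
        rec.completion_date_india = Sentinel.COMPLETED_SENTINEL
        rec.completion_date_global = Sentinel.COMPLETED_SENTINEL
        truth["planned_fraction"] = 1.0
        return rec

    if scope == "multinational":
        return _build_multinational(rng, cfg, rec, enroll_start, truth)

    if scope == "foreign_only":
        rec.total_sample_size = int(rng.integers(50, 2000))
        rec.sample_size_india = 0
        rec.recruitment_status_india = "Not Applicable"
        rec.recruitment_status_global = str(rng.choice(_ACTIVE_STATUSES))
        rec.first_enrollment_india = Sentinel.DATE_MISSING
        rec.first_enrollment_global = enroll_start
        rec.completion_date_india = Sentinel.COMPLETED_SENTINEL
        rec.completion_date_global = Sentinel.COMPLETED_SENTINEL
        return rec

    if scope in ("terminated", "suspended"):
        total = int(rng.integers(50, 2000))
        rec.total_sample_size = total
        rec.sample_size_india = int(rng.integers(1, total))
        bad = "Terminated" if scope == "terminated" else "Suspended"
        if scope == "terminated" and rng.random() < 0.5:
            rec.recruitment_status_india = str(rng.choice(_ACTIVE_STATUSES))
            rec.recruitment_status_global = bad
        else:
            rec.recruitment_status_india = bad
            rec.recruitment_status_global = str(rng.choice(_ACTIVE_STATUSES))
        rec.first_enrollment_india = enroll_start
        rec.first_enrollment_global = enroll_start + timedelta(days=int(rng.integers(0, 90)))
        rec.completion_date_india = Sentinel.COMPLETED_SENTINEL
        rec.completion_date_global = Sentinel.COMPLETED_SENTINEL
        return rec

    if scope == "ambiguous_indian":
        total = int(rng.integers(20, 1000))
        rec.total_sample_size = total
        rec.sample_size_india = total  # equal sizes: looks Indian
        if rng.random() < 0.5:
            # not-applicable statuses alongside a registered Indian sample,
            # with a global-only enrollment date
            rec.recruitment_status_india = "Not Applicable"
            rec.recruitment_status_global = "Not Applicable"
            rec.first_enrollment_india = Sentinel.DATE_MISSING
            rec.first_enrollment_global = enroll_start
        else:
            # global fields fully populated despite the equal sizes
            rec.recruitment_status_india = "Completed"
            rec.recruitment_status_global = "Completed"
            rec.first_enrollment_india = enroll_start
            rec.first_enrollment_global = enroll_start + timedelta(days=int(rng.integers(0, 90)))
        rec.completion_date_india = Sentinel.COMPLETED_SENTINEL
        rec.completion_date_global = Sentinel.COMPLETED_SENTINEL
        return rec

    if scope == "ambiguous_multinational":
        total = int(rng.integers(50, 2000))
        rec.total_sample_size = total
        rec.sample_size_india = int(rng.integers(1, total))  # total > India: looks multinational
        rec.recruitment_status_india = "Completed"
        rec.recruitment_status_global = "Not Applicable"
        rec.first_enrollment_india = enroll_start
        rec.first_enrollment_global = Sentinel.DATE_MISSING
        rec.completion_date_india = Sentinel.COMPLETED_SENTINEL
        rec.completion_date_global = Sentinel.COMPLETED_SENTINEL
        return rec

    # other_discrepancy: India sample exceeding the registered total with
    # no coherent status or date signal
    total = int(rng.integers(20, 500))
    rec.total_sample_size = total
    rec.sample_size_india = total + int(rng.integers(1, 100))
    rec.recruitment_status_india = ""
    rec.recruitment_status_global = ""
    rec.first_enrollment_india = Sentinel.DATE_MISSING
    rec.first_enrollment_global = Sentinel.DATE_MISSING
    rec.completion_date_india = Sentinel.EMPTY
    rec.completion_date_global = Sentinel.EMPTY
    return rec


def _build_multinational(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    rec: TrialRecord,
    enroll_start: date,
    truth: dict,
) -> TrialRecord:
    pf = _draw_planned_fraction(rng, cfg)
    total = int(rng.integers(50, 2000))
    india = int(np.clip(round(pf * total), 1, total - 1))
    rec.total_sample_size = total
    rec.sample_size_india = india
    truth["planned_fraction"] = india / total

    rec.recruitment_status_india = str(rng.choice(_ACTIVE_STATUSES))
    rec.recruitment_status_global = str(rng.choice(_ACTIVE_STATUSES))
    d_global = enroll_start
    d_india = enroll_start + timedelta(days=int(rng.integers(0, 120)))
    rec.first_enrollment_global = d_global
    rec.first_enrollment_india = d_india

    comp_keys = list(_COMPLETIONS)
    comp_p = [cfg.completion_mix[k] for k in comp_keys]
    completion = comp_keys[int(rng.choice(len(comp_keys), p=comp_p))]
    truth["completion"] = completion

    dur_months = int(truth["duration_months"])
    if completion == "completed":
        rec.recruitment_status_india = "Completed"
        rec.recruitment_status_global = "Completed"
        end = _add_months_clamped(max(d_india, d_global), dur_months)
        rec.completion_date_india = end
        rec.completion_date_global = end + timedelta(days=int(rng.integers(0, 60)))
        final_total = max(1, int(round(total * float(rng.uniform(0.8, 1.1)))))
        af = float(np.clip((india / total) * _draw_actual_factor(rng, cfg), 0.0, 1.0))
        final_india = int(np.clip(round(af * final_total), 0, final_total))
        rec.final_enrollment_total = final_total
        rec.final_enrollment_india = final_india
        truth["actual_fraction"] = final_india / final_total
    elif completion == "not_completed":
        rec.completion_date_india = Sentinel.COMPLETED_SENTINEL
        rec.completion_date_global = Sentinel.COMPLETED_SENTINEL
        # ground-truth filing-due date via the documented margin rule,
        # computed with the generator's own month arithmetic
        if dur_months <= 24:
            adjusted = 2 * dur_months
        elif dur_months <= 60:
            adjusted = -(-3 * dur_months // 2)  # ceil(1.5x)
        else:
            adjusted = dur_months
        filing = _add_months_clamped(_add_months_clamped(max(d_india, d_global), adjusted), 6)
        truth["filing_due"] = filing.isoformat()
        truth["overdue"] = filing <= date(2022, 1, 27)
    else:  # mixed: one real date, one sentinel
        end = _add_months_clamped(max(d_india, d_global), dur_months)
        if rng.random() < 0.5:
            rec.completion_date_india = end
            rec.completion_date_global = Sentinel.COMPLETED_SENTINEL
        else:
            rec.completion_date_india = Sentinel.COMPLETED_SENTINEL
            rec.completion_date_global = end
    return rec


def _maybe_inject_errors(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    rec: TrialRecord,
    scope: str,
    truth: dict,
) -> None:
    injected: List[str] = []
    rates = cfg.error_rates

    if rec.final_enrollment_total is not None:
        if rng.random() < rates.get("india_exceeds_total_final", 0.0):
            rec.final_enrollment_india = rec.final_enrollment_total + int(rng.integers(1, 100))
            truth["actual_fraction"] = np.nan
            injected.append("india_exceeds_total_final")
        elif rng.random() < rates.get("total_final_zero", 0.0):
            rec.final_enrollment_total = 0
            rec.final_enrollment_india = 0
            truth["actual_fraction"] = np.nan
            injected.append("total_final_zero")

    if scope in ("indian", "multinational"):
        if rng.random() < rates.get("status_na_with_india_sample", 0.0):
            # replicate the contradiction of a registered Indian sample with
            # not-applicable statuses and a global-only enrollment date
            rec.recruitment_status_india = "Not Applicable"
            rec.recruitment_status_global = "Not Applicable"
            rec.sample_size_india = rec.total_sample_size
            rec.first_enrollment_india = Sentinel.DATE_MISSING
            if not isinstance(rec.first_enrollment_global, date):
                rec.first_enrollment_global = rec.registration_date + timedelta(days=30)
            injected.append("status_na_with_india_sample")
        elif scope == "multinational" and rng.random() < rates.get("date_missing_global", 0.0):
            rec.first_enrollment_global = Sentinel.DATE_MISSING
            injected.append("date_missing_global")

    if truth.get("completion") == "completed" and rng.random() < rates.get(
        "completed_sentinel_misuse", 0.0
    ):
        rec.completion_date_india = Sentinel.COMPLETED_SENTINEL
        injected.append("completed_sentinel_misuse")

    truth["errors"] = ";".join(injected)


def generate_worked_fixture() -> List[TrialRecord]:
    """Five hand-built records for worked examples and tests.

    The first three reproduce, field for field, published examples of
    ambiguous registry entries (equal sample sizes alongside global-side
    data, or a larger total with the global fields not applicable); the
    last two are a minimal fully consistent Indian record and a minimal
    fully consistent multinational record for contrast.
    """
    amb1 = TrialRecord(
        ctri_number="CTRI/2013/02/003388",
        registration_date=date(2013, 2, 1),
        trial_type="Interventional",
        phase="Phase 3",
        total_sample_size=700,
        sample_size_india=700,
        recruitment_status_global="Not Applicable",
        recruitment_status_india="Not Applicable",
        first_enrollment_global=date(2016, 2, 15),
        first_enrollment_india=Sentinel.DATE_MISSING,
        completion_date_india=Sentinel.COMPLETED_SENTINEL,
        completion_date_global=Sentinel.COMPLETED_SENTINEL,
        estimated_duration=Duration(2, 0, 0),
    )
    amb2 = TrialRecord(
        ctri_number="CTRI/2019/06/019635",
        registration_date=date(2019, 6, 1),
        trial_type="Interventional",
        phase="Phase 2",
        total_sample_size=588,
        sample_size_india=588,
        recruitment_status_global="Completed",
        recruitment_status_india="Completed",
        first_enrollment_global=date(2019, 8, 1),
        first_enrollment_india=date(2019, 6, 20),
        completion_date_india=Sentinel.COMPLETED_SENTINEL,
        completion_date_global=Sentinel.COMPLETED_SENTINEL,
        estimated_duration=Duration(1, 6, 0),
    )
    amb3 = TrialRecord(
        ctri_number="CTRI/2020/06/026230",
        registration_date=date(2020, 6, 1),
        trial_type="Interventional",
        phase="Phase 2",
        total_sample_size=40,
        sample_size_india=20,
        recruitment_status_global="Not Applicable",
        recruitment_status_india="Completed",
        first_enrollment_global=Sentinel.DATE_MISSING,
        first_enrollment_india=date(2015, 8, 7),
        completion_date_india=Sentinel.COMPLETED_SENTINEL,
        completion_date_global=Sentinel.COMPLETED_SENTINEL,
        estimated_duration=Duration(1, 0, 0),
    )
    indian = TrialRecord(
        ctri_number="CTRI/2015/01/005001",
        registration_date=date(2015, 1, 10),
        trial_type="Interventional",
        phase="Phase 3",
        total_sample_size=100,
        sample_size_india=100,
        recruitment_status_global="Not Applicable",
        recruitment_status_india="Completed",
        first_enrollment_global=Sentinel.DATE_MISSING,
        first_enrollment_india=date(2015, 3, 1),
        completion_date_india=Sentinel.COMPLETED_SENTINEL,
        completion_date_global=Sentinel.COMPLETED_SENTINEL,
        estimated_duration=Duration(1, 0, 0),
        primary_sponsor="Aurora Pharma Ltd",
        sponsor_country="India",
    )
    multinational = TrialRecord(
        ctri_number="CTRI/2016/03/006002",
        registration_date=date(2016, 3, 5),
        trial_type="Interventional",
        phase="Phase 3",
        total_sample_size=200,
        sample_size_india=50,
        recruitment_status_global="Completed",
        recruitment_status_india="Completed",
        first_enrollment_global=date(2016, 5, 1),
        first_enrollment_india=date(2016, 7, 1),
        completion_date_india=date(2018, 7, 1),
        completion_date_global=date(2018, 8, 1),
        final_enrollment_total=200,
        final_enrollment_india=60,
        estimated_duration=Duration(2, 0, 0),
        primary_sponsor="Global Biologics Inc",
        sponsor_country="United States",
    )
    return [amb1, amb2, amb3, indian, multinational]
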