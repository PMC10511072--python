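# Methods

## The audit model

The package treats a registry snapshot as a table of independent trial
records and applies a deterministic, rule-based cascade.  Nothing is
estimated statistically; every output is a count or a date derived from
explicit rules, and every per-record decision carries the identifier of
the rule that fired, so any aggregate can be traced back to the rows
that produced it.

### Scope classification

The central design constraint is that CTRI records contain internal
contradictions: equal total and India sample sizes alongside a global
enrollment date, "Not Applicable" statuses on trials that registered an
Indian sample, completed global statuses on apparently domestic trials.
The classifier therefore demands *unanimity*: a record is accepted as
Indian or multinational only when the status pair, the enrollment-date
pair and the sample-size pair independently agree.  Multinational
requires both statuses applicable, both dates real, and
total > India > 0; Indian requires the global side absent or not
applicable and total = India > 0.

Precedence for everything else: terminated/suspended statuses first
(they describe the trial's fate, not its scope), then trials with no
Indian arm (India sample size 0, or India status not applicable with
the global side fully populated), then the unanimous scopes, then the
ambiguous buckets, then a residual discrepancy bucket.

The *leaning* of an ambiguous record (Indian-like vs
multinational-like) follows the sample-size pair: equal sizes say the
sponsor registered a domestic trial, a larger total says multinational,
whatever the other pairs claim.  When the size pair is itself invalid
(missing sizes, India exceeding the total) the leaning falls back to
the majority of the three pair sub-verdicts, and to the discrepancy
bucket if there is none.  We chose the size pair as the leaning anchor
because it is the only pair that directly encodes the arithmetic of
scope, and because equal-size contradictions are by far the dominant
ambiguity pattern in real snapshots; the fired rule in each verdict
records which path was taken.

### Completion partition

Multinational records split on the two completion-date fields: both
real dates → Completed Set; both the sentinel "Applicable only for
Completed/Terminated trials" → Not Completed Set.  Records matching
neither definition (one date and one sentinel, blanks) are kept in an
explicit `mixed` bucket rather than silently dropped — on real
snapshots this residue is not empty, and hiding it would make the
partition counts unauditable.

### Recruitment audit

Planned fraction = "Sample Size from India" / "Total Sample Size";
actual fraction = final India enrollment / final total enrollment.
"High recruitment" is fraction ≥ cutoff, inclusive; the default cutoff
is 0.60 (the point at which, for a trial with at least one non-Indian
site, the burden on Indian participants stops being defensible), swept
at ±0.05 and ±0.10.  Invalid data is a first-class outcome with three
tags — `INDIA_EXCEEDS_TOTAL`, `TOTAL_ZERO`, `MISSING` — that propagate
into the ratio ("invalidity is contagious"): fractions are never
clipped into range, because a fraction above 1 is a registry error to
report, not noise to smooth.

The actual:planned ratio is formed on the raw fractions (the ×100
percent scaling cancels), rounded half-up to two decimals — the
granularity of the published bin edges — and binned into ≤ 1.00,
1.01–1.15, 1.16–1.60, ≥ 1.61.  Ratios at or below 1 get their own
bucket so the bins partition the Completed Set exactly.

### Overdue detection

For each Not-Completed record, five steps:

1. overall first enrollment = the **later** of the India and Global
   first-enrollment dates (both exist for any multinational record);
2. registered duration (years, months, days) → whole months:
   `12·years + months + (1 if days > 0)`;
3. delay margin by duration class: ≤ 24 months → ×2; 25–60 months →
   ×1.5, fractional half-months rounded **up**; > 60 months → ×1;
4. estimated completion = first enrollment + adjusted months
   (calendar-month addition, clamping the day to the target month's
   length: Jan 31 + 1 month = Feb 28/29);
5. filing due = estimated completion + 6 calendar months of grace for
   updating the record.

A record is overdue when filing due ≤ reference date (default
2022-01-27, the day before a snapshot download date), inclusive.

Boundary choices, all resolved toward the more generous margin (fewer
false "overdue" labels): exactly 24 months doubles; exactly 60 months
stays in the 1.5× class; half-months round up.  Each is a single
constant in `apply_margin`, documented so another auditor can flip it.
The margin is deliberately discontinuous across class boundaries
(48 adjusted months at duration 24, 38 at 25; 90 at 60, 61 at 61) —
the classes come from the rule being audited, and smoothing them would
change its meaning.  All-zero durations are degenerate: those records
are excluded from the overdue denominator and reported with a reason.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| window | 2013-01-01 … 2020-12-31 | dates, inclusive | recent 8-year registration window; older records carry more errors |
| cutoff | 0.60 | fraction | "high recruitment" threshold, inclusive |
| sweep deltas | ±0.05, ±0.10 | fraction | sensitivity of the flag counts to the cutoff |
| as_of | 2022-01-27 | date | audit reference date (day before snapshot download) |
| grace | 6 | calendar months | time allowed to update the record after completion |
| margin classes | ≤24 → ×2, 25–60 → ×1.5 (ceil), >60 → ×1 | months | delay allowance shrinking with trial length |
| phase tokens | 2, 3, ii, iii (+combined) | — | editable allow-list; CTRI phase strings vary |

Combined phase labels ("Phase 2/Phase 3", and partially-in-scope labels
such as "Phase 1/Phase 2") are kept, since part of the trial runs in an
audited phase; the allow-list makes the policy explicit and editable.

## The synthetic generator

`GeneratorConfig` defaults encode the study conditions the pipeline is
meant to face: a snapshot in which roughly two-thirds of records fall
in the window, 72% of those are interventional, a third of those are
phase 2/3; the phase-2/3 cohort is ~87% Indian, ~7% multinational, with
small foreign-only (0.3%), terminated (1.2%), suspended (0.02%),
ambiguous (4.3%) and discrepant (0.2%) minorities; multinational
records are ~13% completed, ~77% not completed, ~10% mixed.  Planned
India fractions for multinational trials are right-skewed — a
Beta(2, 6) body with an 8% uniform tail on [0.6, 1) so a realistic
minority plans high recruitment — and actual enrollment is planned
enrollment times a factor whose distribution populates every ratio bin,
including the ≥1.61 "multinational became Indian" extreme (actual
fractions are capped at 1 through the final-enrollment integers).
Durations span the three margin classes (55/35/10%).  Error modes are
injected independently per record at small default rates (3% invalid
final enrollments among completed trials, 1% each for the status/date
contradictions and sentinel misuse), and each injection is recorded in
the ground-truth table, which is returned separately from the records
so truth can never leak into the audit path.

What the generator does **not** emulate: free-text fields (titles,
conditions, eligibility), sponsor-nationality structure beyond a label,
correlations between scope and calendar time, or the long tail of
formatting noise in scraped data.  Green tests on synthetic data
therefore demonstrate that the rules are implemented faithfully and
recover a known truth — not that the rules capture every pathology of
a real snapshot.  Against real data, the classifier's ambiguous-leaning
split and the phase allow-list are the places where counts may deviate,
and both are auditable through the per-record `rule_fired` column.

## Numerical and degenerate-input choices

- Dates parse from dd/mm/yyyy and ISO; all output is ISO.  Sentinel
  strings are matched case-insensitively and serialized verbatim; an
  empty cell is a distinct `EMPTY` state, never conflated with
  "Date Missing".
- Integer fields parse leniently (commas, whitespace); negative or
  non-numeric non-empty values reject the row with a reason.  Rejected
  rows are returned alongside the parsed records, never dropped.
- Ratio rounding is decimal half-up (not banker's rounding) at exactly
  two places, matching the bin-edge granularity.
- Month addition uses `dateutil.relativedelta`; the test suite checks
  it against an independent day-counting oracle on 1,000 random
  (date, months) pairs.
- Duplicate trial identifiers reject the later row; an empty input file
  yields an empty, valid result everywhere downstream (all-zero
  report, exit code 0).

## Problem sizes

The default test suite exercises the pipeline on synthetic snapshots of
1,000–4,000 records, enough to populate every scope category and both
completion sets many times over; the acceptance script generates a
39,821-record snapshot, the size of a full registry download, and runs
in seconds.

## Known limitations

- Scope labels are taken at face value: a trial mislabelled
  observational, or with a wrong phase string, is filtered out exactly
  as the registry describes it.
- The ambiguous-leaning rule and the residual-discrepancy boundary are
  design choices; other defensible operationalizations would shuffle
  records between the ambiguous and discrepancy buckets (not between
  the unanimous scopes, which are fully determined by the rules).
- Sponsor nationality is exposed as a string but never adjudicated;
  classing sponsors as domestic or foreign is manual downstream work.
- "Overdue" means the registry record was not updated by the estimated
  filing date — it is a statement about the record, not proof the trial
  actually finished; the margins trade false positives against false
  negatives and are configurable.
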