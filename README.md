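# ctri-audit

Audit pipeline for Clinical Trials Registry-India (CTRI) snapshots.

Multinational trials that run in India must register with CTRI, and the
registry record states both the planned recruitment ("Sample Size from
India" vs "Total Sample Size") and, once the trial ends, the achieved
recruitment ("Final Enrollment numbers achieved (India)" vs "(Total)").
Two meta-research questions hang on these fields: **was too large a
share of a multinational trial's participants recruited from India**
(an over-recruitment and burden-benefit concern for the Indian
population), and **are completion dates being updated in the registry at
all** (a reporting-compliance concern)?  This package implements the
full audit for anyone — registry meta-researchers, ethicists,
regulators — who has a tabular CTRI snapshot (SQLite or CSV) and wants
the analysis to be reproducible and rule-by-rule auditable.

## What it computes

Given one row per registered trial, the pipeline:

1. **filters** to trials registered in a window (default 2013-01-01 to
   2020-12-31, inclusive), of type Interventional, in phase 2 and/or 3;
2. **classifies scope**: a trial is *Indian* or *multinational* only if
   three independent field pairs — recruitment statuses (India/Global),
   first-enrollment dates (India/Global), and sample sizes
   (total/India) — all agree on that scope.  For a multinational
   verdict both statuses must be applicable, both dates real, and
   total > India.  Terminated/suspended trials, trials with no Indian
   arm, and records whose fields contradict each other get their own
   categories, each verdict carrying the rule that fired;
3. **partitions** multinational trials into a *Completed Set* (real
   dates in both completion-date fields), a *Not Completed Set* (both
   fields carry the sentinel "Applicable only for Completed/Terminated
   trials"), and a mixed residue;
4. **audits recruitment**: planned fraction p = India/total and actual
   fraction a over the final-enrollment fields; a trial is flagged
   *high recruitment* when the fraction is ≥ the cutoff (default 60%,
   inclusive), with a sensitivity sweep at ±5 and ±10 points; the ratio
   a/p (2-decimal, half-up) is binned into ≤1.00 / 1.01–1.15 /
   1.16–1.60 / ≥1.61, with invalid data (India exceeding the total,
   zero totals, missing fields) tagged and reported, never clipped;
5. **detects overdue records**: for each Not-Completed trial, the later
   first-enrollment date plus the registered duration (normalized to
   months; a non-zero day component counts as one month), scaled by a
   delay margin (×2 for durations ≤ 24 months, ×1.5 rounded up for
   25–60 months, ×1 beyond), plus a 6-month filing grace, gives a
   filing-due date; the record is overdue if that date is on or before
   the reference date (default 2022-01-27).

A seeded synthetic-snapshot generator (`ctri_audit.synthetic`) emulates
the registry's field dialect — dd/mm/yyyy dates, the sentinel strings,
the scope mix, right-skewed recruitment fractions, and the documented
data-error modes — with ground truth kept in a separate table, so the
whole pipeline is testable without any download.

## Worked example

```python
import ctri_audit as ca

records, truth = ca.generate(ca.GeneratorConfig(n_records=2000, seed=1))
report = ca.run_audit(records)
print(report.render_text())
```

prints

```
CTRI registry audit
===================
records read:            2000
in window:               1336
interventional:          968
phase 2/3:               490
  Indian:                445
  multinational:         23
  other:                 22

completed set:           2
not completed set:       19
mixed completion:        2

completed, planned >=60%:     0 (0%)
completed, actual >=60%:      0 (0%)
not completed, planned >=60%: 4 (21%)
invalid enrollment data:      0

actual:planned ratio table (completed set):
  AT_OR_BELOW_1   1
  1.01-1.15       1
  1.16-1.60       0
  1.61+           0
  INCORRECT_DATA  0

overdue at 2022-01-27: 10 of 19 (53%)
```

Of 2,000 synthetic registrations, 490 survive the window/type/phase
cascade; 23 are unambiguously multinational; of the 19 multinational
trials not yet marked completed, 4 planned to recruit 60% or more of
participants from India and 10 have sailed past their margin-adjusted
filing-due date without a registry update.  The same objects expose the
per-trial tables (`report.verdicts`, `report.recruitment`,
`report.estimates`) behind every count.

The same pipeline runs from the shell on a real snapshot:

```bash
ctri-audit simulate --n 2000 --seed 1 --out snapshot.csv
ctri-audit audit --db snapshot.csv --start 2013-01-01 --end 2020-12-31 \
    --cutoff 0.60 --as-of 2022-01-27 --out results/
```

`audit` accepts SQLite or CSV input, an optional `--column-map` JSON for
snapshots with verbose column labels, and writes `report.json`,
`report.txt` and the per-trial CSVs.

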