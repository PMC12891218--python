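# hypnovigil

Pharmacovigilance signal-detection pipeline for the **abuse, dependence and
withdrawal potential of insomnia medications**, built on spontaneous
adverse-event reports in the FAERS quarterly-extract dialect.

Physicians are often reluctant to prescribe hypnotics long-term because of
abuse concerns, and the DEA schedules benzodiazepines, Z-drugs and the newer
dual orexin receptor antagonists (DORAs) alike as Schedule IV. Spontaneous
reporting data let us ask how often abuse-related adverse events are actually
*reported* for each drug class relative to a reference drug. `hypnovigil`
implements that analysis end to end, for researchers working with FAERS-style
data or with the package's own synthetic corpora:

1. **Ingestion** of "$"-delimited DEMO/DRUG/REAC quarterly tables
   (`faers_io`), with case deduplication (one report per `caseid`: highest
   `caseversion`, then latest FDA receipt date, then largest `primaryid`) and
   scoping to US-occurrence cases in a date window.
2. **Drug-group resolution** (`lexicon`): verbatim drug strings (brand or
   generic, with dose/formulation suffixes) are matched exactly after
   normalization into seven study groups — benzodiazepines (any indication),
   benzodiazepines approved for insomnia, Z-drugs, DORAs, trazodone, doxepin,
   ramelteon.
3. **Case selection** (`case_selection`): a two-step *modified* Standardized
   MedDRA Query "Drug abuse, dependence and withdrawal" (v26.1) — include any
   case with an SMQ preferred term, then exclude cases whose only SMQ terms
   are overdose-type PTs co-reported with a suicidal-behavior PT (overdoses in
   a suicide attempt are not drug abuse).
4. **Disproportionality** (`disproportionality`): reporting odds ratio and
   proportional reporting ratio against a reference group, with 95% log-scale
   delta-method confidence intervals.
5. **Reporting** (`reporting`, `cli`): extraction funnel, signal tables (the
   data behind forest plots), run summary and a reproducibility manifest.

A first-class synthetic-data generator (`synthetic_data`) emits FAERS-dialect
corpora with a ground-truth ledger (planted duplicates, suicide-overdose
cases, brand-name mentions, partial dates), so every stage is testable
without downloading FAERS.

## The statistics

For an index drug group with `a` event cases out of `a + b` total, and a
reference group with `c` out of `c + d`:

```
ROR = (a/b) / (c/d)           95% CI: exp(ln ROR ± z·√(1/a + 1/b + 1/c + 1/d))
PRR = (a/(a+b)) / (c/(c+d))   95% CI: exp(ln PRR ± z·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))
```

with `z` the exact 0.975 normal quantile (Woolf interval for the ROR). A
ratio below 1 means the event is reported less often for the index drug than
for the reference; the difference is conventionally non-significant when 1
lies inside the CI. Zero cells get the Haldane–Anscombe +0.5 correction and
are flagged. Z-drugs serve as reference for the Schedule IV comparisons and
trazodone for the unscheduled ones.

## Worked example

The package bundles the overall 2×2 tables of a published 10-year US FAERS
benchmark (2014-01-01 to 2024-03-31) as an exact fixture:

```bash
hypnovigil analyze --fixture benchmark --out results/
```

prints

```
dora vs z_drug: ROR=0.150 [0.131, 0.171] (a=262, b=9701, c=2063, d=11432)
benzodiazepine_any vs z_drug: ROR=2.118 [2.015, 2.226] (a=18690, b=48894, c=2063, d=11432)
benzodiazepine_insomnia vs z_drug: ROR=1.653 [1.498, 1.825] (a=659, b=2209, c=2063, d=11432)
dora vs trazodone: ROR=0.092 [0.081, 0.105] (a=262, b=9701, c=2261, d=7704)
doxepin vs trazodone: ROR=0.976 [0.876, 1.087] (a=525, b=1833, c=2261, d=7704)
ramelteon vs trazodone: ROR=0.295 [0.195, 0.445] (a=25, b=289, c=2261, d=7704)
```

Reading the first line: of 9,963 DORA cases, 262 (2.6%) met the modified SMQ,
against 2,063 of 13,495 (15.3%) for Z-drugs — the odds of an abuse-related
report for DORAs are 0.150 times the Z-drug odds, significantly below parity.
The benzodiazepine classes sit significantly *above* their Z-drug reference,
and ramelteon and DORAs below trazodone. `results/` receives `funnel.csv/json`,
`signals.csv/json`, `summary.txt` and `manifest.json`.

The same pipeline runs on files — synthetic or real quarters:

```bash
hypnovigil simulate --seed 7 --out corpus/
hypnovigil analyze --demo corpus/demo.txt --drug corpus/drug.txt \
    --reac corpus/reac.txt --checkpoint cases.jsonl --out results/
```

Library use mirrors the CLI: `read_table` / `assemble_cases` / `deduplicate` /
`scope_filter` → `load_default_lexicon` → `select_modified_smq` →
`run_analysis`.

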