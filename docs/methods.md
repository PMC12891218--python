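# Methods

## Study design implemented

The pipeline operationalizes a reference-drug disproportionality study of
abuse-related adverse events for insomnia medications on spontaneous-report
data. Scope: cases whose event occurred in the US (occurrence country only,
not reporter country) between 2014-01-01 and 2024-03-31 inclusive. Scoping
uses the event date by default, falling back to the FDA receipt date when the
event date is missing (configurable the other way round); cases missing both
dates are excluded and counted. Partial FAERS dates (`YYYYMM`, `YYYY`)
resolve to the first day of the period.

**Deduplication.** FAERS distributes one row per *report*; follow-up versions
of a case share a `caseid`. One report per case is kept: highest
`caseversion`, ties broken by latest `fda_dt`, then by lexicographically
largest `primaryid`. The rule is deterministic and order-insensitive; the
version-first ordering follows FAERS practice of later versions superseding
earlier ones.

**Case definition.** The modified SMQ "Drug abuse, dependence and withdrawal"
(MedDRA v26.1) is applied in two steps:

1. include a case if any reaction PT is in the SMQ inclusion list (66 terms,
   packaged as plain text; PTs are compared as verbatim strings after
   whitespace collapsing and case folding, because the full MedDRA hierarchy
   is licensed);
2. exclude the case if *every* SMQ hit on it is overdose-type (Accidental
   overdose, Intentional overdose, Overdose, Prescribed overdose, Toxicity to
   various agents) **and** any suicidal-behavior PT (Completed suicide,
   Suicidal behavior, Suicide attempt, Suicide threat, Suspected suicide,
   Suspected suicide attempt) is co-reported.

The "every hit is overdose-type" reading is the only one consistent with the
rule's purpose — removing pure suicide-overdose cases — and gives the rescue
property that adding any non-overdose SMQ PT flips an excluded case to
selected. Suicidal-behavior PTs are not SMQ members and are matched against
all reactions of the case. Selection is computed per case, independent of
drug grouping; a case contributes the same outcome to every group it belongs
to (the counts are identical whichever order selection and grouping run in).

**Drug grouping.** Verbatim drug strings are normalized (uppercase, trimmed,
dose/formulation/salt tokens stripped: `"TEMAZEPAM 15 MG CAPSULE"` →
`"TEMAZEPAM"`) and matched exactly against each group's ingredients and
brand synonyms; both the `drugname` and `prod_ai` fields are tried. Matching
is never substring-based. A case counts toward a group if any mention in an
accepted role resolves into it; the default accepts all four FAERS roles
(primary/secondary suspect, concomitant, interacting) because the analysis
counts "cases linked to" a drug, with suspect-only available as a switch.
The benzodiazepine-any group extends the five insomnia-approved agents with
the common US benzodiazepines prescribed off-label (alprazolam, lorazepam,
clonazepam, diazepam, chlordiazepoxide, clorazepate, oxazepam, midazolam,
clobazam, remimazolam); the list is a package default and fully overridable,
since off-label hypnotic use of these agents is the stated reason the
any-indication class exists. Cases mentioning both the index and the
reference drug count in both margins by default (`co_mention="exclusive"`
drops them).

## Estimators

For a 2×2 table (a, b | c, d) of event vs non-event cases in the index and
reference groups:

- ROR = (a/b)/(c/d), CI `exp(ln ROR ± z·√(1/a+1/b+1/c+1/d))` (Woolf);
- PRR = (a/(a+b))/(c/(c+d)), CI with variance `1/a − 1/(a+b) + 1/c − 1/(c+d)`.

`z` is the exact normal 0.975 quantile by default; a fixed 1.96 is available
for bit-matching legacy outputs. If any cell is zero, 0.5 is added to all
four cells (Haldane–Anscombe) and the result is flagged
`continuity_corrected`; estimates are otherwise computed on the raw counts.
An empty index or reference margin is an error (`UndefinedTableError`), not a
silent NaN. PT-level analyses are restricted to modified-SMQ PTs with
frequency ≥ 1% of a group's *total* retrieved cases in at least one compared
group; the total-cases denominator matches the descriptive percentage
definition, and a modified-SMQ-cases denominator is available as a switch.
No multiplicity adjustment is applied, mirroring standard disproportionality
practice. Exported estimates and CI bounds are rounded half-up to 3 decimals,
percentages to 1 decimal.

## Synthetic-data generator

The generator emulates the structure the pipeline must survive, with a
ground-truth ledger for verification: versioned case ids (duplicate reports,
default rate 0.05), occurrence countries (default 94% US, the remainder
CA/GB/FR — non-US cases exercise the scope filter), event dates uniform in
the study window with FDA receipt lagging 0–60 days, partial (2%) and
missing (5%) event dates, brand-name mentions (30%), dose/formulation
suffixes (30%), random drug roles (70/15/15 PS/SS/C), and planted
suicide-related overdose cases (default 2%) constructed to match the step-2
exclusion predicate exactly. Abuse events are Bernoulli per group with
probability `odds/(1+odds)`; event cases carry 1–3 SMQ PTs (uniform over the
inclusion list by default, weights configurable), plus background noise PTs
drawn from a non-SMQ pool. Per-group case totals and event odds default to
the published benchmark conditions (e.g. DORAs: 9,963 cases, odds 262/9701),
so the configured true odds ratios match the benchmark estimates. The
generator does **not** model disease/comorbidity structure, co-reporting
correlations between PTs, notoriety-bias time dynamics, or reporter-quality
variation — passing tests demonstrate correctness of the pipeline's logic
and calibration of the estimators under clean sampling assumptions, not
robustness to those real-data biases.

`simulate_event_tables` runs the same Bernoulli event model in bulk without
report assembly; it is used to study estimator calibration (CI coverage,
log-ROR bias) at 500 replicates of 10,000 cases per group, while full
file-backed corpus round-trips are verified at a few hundred cases per group
— sizes chosen to keep the default suite fast while the identities checked
(exact ledger recovery) are size-independent.

## Numerical and design choices

- Dedup tie-break (version → receipt date → primaryid) makes output
  independent of input order; output is sorted by case id.
- PT and drug-name comparison keys are whitespace-collapsed and casefolded;
  the SMQ's canonical spelling is restored in outputs.
- The overdose-exclusion set is validated as a subset of the inclusion set,
  and the suicidal-behavior set as disjoint from it, at load time.
- Funnel invariant `selected ≤ SMQ hits ≤ total` is enforced by construction
  and revalidated on every exported row.
- Exports are deterministic (fixed column/row order, fixed precision, no
  timestamps); the manifest records seed, config hash and tool version, so a
  run is reproducible from its manifest.
- The bundled benchmark tables derive each group's 2×2 from its printed total
  and modified-SMQ count; per-PT cell counts are not published and PT-level
  benchmark reproduction is therefore out of scope.

## Limitations

Spontaneous-report analyses measure *reporting*, not incidence: no exposure
denominator exists, and signals are susceptible to notoriety bias and
confounding by indication. The lexicon is a fixed string table, not an
RxNorm/ATC integration, and applies no spelling correction; misspelled drug
names fail to resolve (silently, as in any string-matching pipeline). Only
DEMO/DRUG/REAC tables of the post-2012 FAERS dialect are handled.
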