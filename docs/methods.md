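# Methods

## Data model and cleaning

A spontaneous-reporting bundle is a set of "$"-delimited tables keyed by
`primaryid` (one report *version*): DEMO (demographics, receipt date
`fda_dt`, event date), DRUG (one row per drug with role code PS/SS/C/I and
route), REAC (one row per reaction PT), OUTC (outcome codes DE/LT/HO/DS/
CA/RI/OT), THER (therapy start dates) and INDI (indications), plus
plain-text lists of deleted CASEIDs. A safety report may appear in several
versions sharing a `caseid`.

Cleaning proceeds in a fixed order:

1. **Deduplication.** Rows are sorted by (caseid, fda_dt, primaryid)
   ascending and the last row per caseid kept: the most recent receipt
   date wins, ties broken by the highest primaryid. Identifiers are
   compared numerically when they parse as integers (FAERS stores numeric
   ids as strings; lexicographic order would rank "9" above "10").
2. **Deleted-report removal**, applied *after* deduplication. Any quarter's
   deleted list removes the case globally; caseids are treated as globally
   unique across quarters.
3. **Assembly.** Satellite rows are joined by primaryid; therapy start
   dates and indications are merged onto drug rows by (primaryid,
   drug_seq). Rows referencing a primaryid with no surviving DEMO row
   (stale versions, deleted cases) are dropped and counted, never silently.

Malformed lines (wrong field count) are counted per table and quarantined
to side files for audit. Missing report tables and unusable headers are
hard errors.

## Vocabulary

Drug classification uses a user-supplied tab-delimited dictionary mapping
verbatim drug names to (ingredient, ATC code); matching is exact after
case-folding and whitespace collapsing, with no fuzzy matching — unmapped
names return an explicit marker and are counted, so recall problems are
visible rather than silently absorbed. A product is *respiratory* when any
of its (possibly several, ";"-separated) ATC codes begins with "R".

Event classification uses a user-supplied MedDRA-style table with one row
per PT giving its primary PT → HLT → HLGT → SOC path. MedDRA itself is
licensed and is not bundled; the synthetic generator ships a mock hierarchy
in the same format. At load the table is checked for the single-parent
property at every level and for cross-level term reuse (which together
rule out cycles). The psychiatric SOC (code 10037175) and three focus
HLGTs — anxiety disorders and symptoms (10002861), depressed mood disorders
and disturbances (10012375), suicidal and self-injurious behaviours
(10042460) — are addressed by code.

## Cohort and derived fields

Inclusion requires all of: age in [0, 18) years after unit conversion
(YR ×1, MON ÷12, WK ÷52.18, DY ÷365.25, HR ÷8766, DEC ×10; negative values,
missing units and unknown codes become missing), at least one
primary-suspect drug with a respiratory ATC code, and at least one reaction
PT under the psychiatric SOC. The half-open [0, 18) boundary keeps
17-year-olds with fractional ages and excludes exact 18.0.

The analysis unit below the patient is the (PS respiratory drug,
psychiatric PT) *pair*: a patient with two qualifying drugs and three
psychiatric PTs contributes six pair rows, so pair counts can exceed
patient counts.

Derived fields: age group (0–4 / 5–11 / 12–17), seriousness (any outcome
code present ⇒ serious), time to onset (event date minus the first PS
respiratory drug's therapy start, computed only when both dates are
complete YYYYMMDD; negative differences become missing), onset bins (0–7,
8–60, 61–180, 181–360, >360 days, with missing reported separately rather
than forcing the bins to exhaust the cohort), and reporting-era bins
(2004–2008, 2009–2013, 2014–2018, 2019–2024).

## Descriptive arithmetic

Percentages are 100·count/denominator rounded **half-up** to two decimals
(the convention that reproduces printed pharmacovigilance tables; Python's
built-in banker's rounding does not). Single-choice tables are required to
sum to their denominator; the outcome table is multi-select (a report can
carry several outcome codes) and may exceed it. Medians and IQRs use
linear-interpolation quantiles; the convention is isolated in one helper
should another be needed. Per-drug PT composition tables use the drug's
pair count as denominator and by default omit drugs with ≤ 10 reports.

## Disproportionality statistics

All four algorithms run on a/b/c/d counts built from report-level sets:
the drug margin is "report carries the target drug as primary suspect",
the event margin is "report carries ≥ 1 PT in the target event set" (one
PT, one focus HLGT, or the whole psychiatric SOC depending on the rollup
level). The background is, by default, all deduplicated, deletion-filtered
*pediatric* reports in the bundle; an all-ages background is a switch.
Formulas are in the README. Numerical choices:

- **Zero cells** (ROR/PRR): the Haldane–Anscombe 0.5 is added to all four
  cells *only* when a zero cell occurs, and the row is marked `corrected`;
  nonzero tables are never perturbed.
- **χ²** uses the Yates continuity correction with each cell's term clamped
  to zero when |O−E| < 0.5 (matching scipy's corrected statistic);
  uncorrected Pearson is available by flag. Tables with a zero margin are
  `degenerate`: χ² is NaN and the MHRA flag false.
- **BCPNN**: the default IC/IC025 is the closed-form shrinkage
  approximation above; `variant="bate"` gives the original Bayesian
  posterior moments with Beta priors (α₁=β₁=γ₁₁=1, α=β=2) and a normal
  IC025. The two agree closely at large counts and diverge for sparse
  tables, where the posterior variant is slightly more conservative.
- **Minimum-report rule**: pairs with a < 3 are reported with *all* flags
  and the composite suppressed, regardless of the estimates.
- No multiple-comparison adjustment is applied; signal detection here is
  exploratory screening, not hypothesis confirmation.

Stratified analysis restricts the background — hence all four cells — to
reports in one stratum (an age group or a sex): the comparator for "girls
on drug D" is "girls on other drugs", which is what stratified
disproportionality operationally means. Age-stratum a-cells sum to the
pooled a-cell; sex strata sum to pooled minus unknown-sex reports.

## Synthetic bundle generator

The generator emulates the structure the pipeline must survive, with drug
and event independent in the background:

- a categorical drug distribution (default: six respiratory products
  including one combination, four non-respiratory comparators, remainder to
  a filler product) and a categorical PT distribution (default: eight
  focus-HLGT psychiatric PTs, one psychiatric non-focus PT, three
  non-psychiatric PTs, remainder to a filler PT), each summing to ≤ 1;
- **injected signals**: for each configured (drug, PT, λ) the joint
  probability of that cell is multiplied by λ ≥ 1 and the joint
  renormalized. With a single injected pair the generating reporting odds
  ratio is *exactly* λ (the renormalization cancels in the odds ratio);
  with several disjoint pairs each pair's closed-form ROR exceeds λ by a
  factor 1 + Σⱼ(λⱼ−1)·p_dⱼ·p_eⱼ/((1−p_D)(1−p_E)) ≈ 1.005–1.015 at the
  default probabilities. The manifest records the exact closed-form value
  per pair;
- demographics matching a pediatric reporting population: age bins at
  14.84% / 39.05% / 46.11% (0–4 / 5–11 / 12–17) emitted in mixed units
  (YR/MON/WK/DY, with occasional exact decades coded DEC), ~50% female with
  2% missing sex, country/reporter/route/indication mixes resembling a
  US-dominated spontaneous-reporting stream, reporting years weighted
  toward the recent era, serious-outcome rate 82.6%;
- **duplicate versions** for a configurable fraction of cases (default
  10%): same caseid, distinct primaryids, earlier receipt dates — except
  for a configurable tie fraction (default 25%) whose versions share the
  receipt date so the primaryid tie-break is exercised. The canonical
  (retained) version always carries the case's true drug/event, and stale
  versions' satellite rows become the orphans assembly must drop;
- **deleted lists** (default 2% of caseids), partial dates (default 10% of
  event/therapy dates truncated to YYYYMM or YYYY), and an optional
  multi-PT mode (off by default so the per-pair λ stays interpretable —
  one PS drug and one PT per case is the default report shape).

One integer seed fully determines the bundle byte for byte.

What the generator does **not** emulate — and hence what passing tests do
not establish about real FAERS data: verbatim drug-name noise (misspellings,
salts, brand names), reporting-rate secular trends and stimulated-reporting
waves, correlated drug–event–age structure beyond the injected pairs,
within-case drug co-prescription, and duplicate reports with *different*
caseids (true duplicates FAERS itself has not linked). Unmapped-name and
unmapped-PT accounting exists precisely because real bundles exercise it
harder than the simulator does.

## Validation experiment sizes

The standard validation conditions are 50,000-case bundles, injected
λ ∈ {2, 4, 8} with background pair probabilities ≥ 10⁻³, and 20 replicate
seeds per λ (one injected pair per bundle, so the λ being recovered is the
exact generating value). Null calibration uses 20 signal-free bundles of
the same size and pools all drug–PT pairs with a ≥ 3. On these conditions
the estimated ROR's 95% CI covers λ in ≳ 95% of replicates, every λ = 8
pair fires the composite rule, and the composite false-positive rate is
well under 1% — the conjunction rule is deliberately conservative.

## Known limitations

- Exact-match drug mapping trades recall for reproducibility; real FAERS
  verbatim names need curation before mapping.
- The background choice (pediatric-only vs all-ages) materially changes
  b/c/d; published analyses often leave theirs unstated, so cross-study
  ROR comparisons should be made cautiously.
- Time-to-onset uses only complete dates; in data with many partial dates
  the onset distribution describes a selected subset.
- The pipeline reads the modern (post-2012Q4) FAERS ASCII dialect only;
  legacy ISR-format and XML dialects are out of scope.
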