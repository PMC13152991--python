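"""Build the cohort and print its descriptive characteristic tables.

Selects pediatric cases with a primary-suspect respiratory drug and at
least one psychiatric reaction PT, then summarizes gender, age groups,
seriousness, outcomes and time to onset with exact count/percentage
arithmetic (half-up, two decimals).
"""

import tempfile
from pathlib import Path

from faerspv import (SyntheticConfig, VocabularyBundle, generate_bundle,
                     load_cases, select_cases, summarize_cohort,
                     drug_hlgt_composition, serious_outcome_rates)

config = SyntheticConfig(n_cases=20_000, seed=2)

with tempfile.TemporaryDirectory() as tmp:
    manifest = generate_bundle(config, Path(tmp) / "bundle")
    vocab = VocabularyBundle.read(manifest.paths["drug_dict"],
                                  manifest.paths["meddra"])
    cases, attrition = load_cases(manifest)
    cohort = select_cases(cases, vocab)

summary = summarize_cohort(cohort)
print(f"patients: {summary['n_patients']}, "
      f"drug-event pairs: {summary['n_pairs']}")

for key in ("gender", "age_group", "degree", "outcomes", "onset"):
    ft = summary[key]
    print(f"\n{ft.name} (of {ft.denominator} "
          f"{ft.denominator_kind}{', multi-select' if ft.multi_select else ''}):")
    print(ft.table.to_string(index=False))

med = summary["age_median_iqr"]
print(f"\nage median (IQR): {med['median']:.1f} "
      f"({med['q1']:.1f}-{med['q3']:.1f}) years")

# per-drug rollups: share of each focus HLGT and death / life-threatening rates
print("\nmontelukast focus-HLGT composition:")
print(drug_hlgt_composition(cohort.pair_table, "Montelukast")
      .table.to_string(index=False))
print("\nserious outcomes:", serious_outcome_rates(cohort.pair_table,
                                                   "Montelukast"))

# Counts are report counts; percents are of the stated denominator, so
# single-select tables sum to 100.00 while the multi-select outcome table
# can exceed it (one report may carry several outcome codes).
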