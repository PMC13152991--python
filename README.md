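# faerspv

Disproportionality signal detection for FAERS-style spontaneous
adverse-event reports, built for pediatric pharmacovigilance questions of
the form *"are psychiatric adverse events reported disproportionately often
for respiratory drugs in children?"* — with a synthetic-report simulator so
the entire pipeline can be validated against known ground truth without
downloading anything.

## Who this is for

Pharmacoepidemiologists and drug-safety analysts working with FDA Adverse
Event Reporting System (FAERS) quarterly ASCII bundles, or with any
spontaneous-reporting data in the same shape: per-report demographics
(DEMO), drugs with role codes (DRUG), reaction preferred terms (REAC),
outcome codes (OUTC), therapy dates (THER), indications (INDI), and
deleted-case-ID lists.

## What it computes

For a drug *D* and event *E* against a background of *N* reports, the 2×2
contingency table is

|              | event *E* | other events |
|--------------|-----------|--------------|
| drug *D*     | a         | b            |
| other drugs  | c         | d            |

and the four standard signal-detection statistics are

- **ROR** = ad/bc, with Wald 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`;
  flag when the CI lower bound exceeds 1;
- **PRR** = [a/(a+b)]/[c/(c+d)], with CI
  `exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))`; flag when the lower
  bound exceeds 1;
- **MHRA criterion**: PRR ≥ 2 together with a Yates-corrected χ² ≥ 4 and at
  least 3 reports;
- **BCPNN information component** IC = log₂((a+½)/(E+½)) with
  E = (a+b)(a+c)/N, and IC025 = IC − 3.3(a+½)^−½ − 2(a+½)^−3/2; flag when
  IC025 > 0 (the original Bayesian posterior variant is available as a
  switch).

A pair is a **composite signal** only when all four flags agree and the pair
has at least three reports — the conservative conjunction rule.

Around that core the package provides: FAERS bundle ingestion with
case-version deduplication (latest FDA_DT per CASEID, ties to the highest
PRIMARYID) and deleted-report removal; ATC drug-dictionary and MedDRA-style
hierarchy classification (PT → HLT → HLGT → SOC); pediatric cohort selection
(ages [0, 18) from mixed age units, primary-suspect respiratory drug,
psychiatric reaction); Table-1-style descriptive summaries with exact
half-up percentage arithmetic; PT- and HLGT-level rollups; age/sex
stratified analyses with forest-plot exports; and a synthetic bundle
generator with injected signals of known relative reporting rate λ.

## Worked example

```python
from faerspv import (SignalPair, SyntheticConfig, VocabularyBundle,
                     generate_bundle, run_pipeline)

config = SyntheticConfig(n_cases=20_000, seed=1,
                         signal_pairs=[SignalPair("MONTELUKAST", "Anxiety", 8.0)])
manifest = generate_bundle(config, "bundle/")
vocab = VocabularyBundle.read(manifest.paths["drug_dict"],
                              manifest.paths["meddra"])
result = run_pipeline("bundle/", vocab)
pt = result.pt_signals
print(pt[pt["drug"] == "Montelukast"][["event", "a", "ror", "ror_lo",
                                       "ror_hi", "composite"]])
```

prints (abridged):

```
                  event    a    ror  ror_lo  ror_hi  composite
                Anxiety  258  7.112   6.062   8.343       True
             Depression   29  0.829   0.567   1.211      False
      Suicidal ideation    8  0.496   0.244   1.007      False
```

The injected pair is recovered with an ROR whose 95% CI (6.06–8.34) covers
the generating λ = 8 and fires the composite rule; the un-enriched
psychiatric PTs sit near ROR = 1 and stay unflagged. The attrition record
(`result.attrition`) documents every filtering step from raw DEMO rows to
the analyzed cohort.

The `examples/` directory has one narrative script per capability:
simulation + detection, descriptive summaries, and stratified analysis.
There is also a thin CLI (`faerspv simulate|ingest|cohort|describe|signals|
stratify|all`) that writes CSV artifacts plus an auditable run log.

## What validation does not cover

Reproducing published drug-level ROR/PRR/χ²/IC values from the full FAERS
database requires the whole-database denominators (the b, c, d cells),
which published tables do not carry; validation here is therefore against
synthetic ground truth and independent oracles, not against published
drug-level estimates. See `docs/methods.md` for the full model and design
notes.
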