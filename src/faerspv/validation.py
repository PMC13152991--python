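"""Parameter-recovery and null-calibration experiments on synthetic bundles.

These run the whole pipeline — generate a bundle on disk, ingest it,
deduplicate, remove deleted cases, classify, and evaluate PT-level
disproportionality — and compare the estimates against the generator's
known ground truth:

* recovery: bundles with injected (drug, PT) pairs at relative reporting
  rates lambda; per replicate, does the estimated ROR's 95% CI cover
  lambda, and does the composite rule fire for the strong pairs?
* null calibration: bundles with no injected pairs; what fraction of
  evaluable pairs (a >= 3) does the conservative all-four composite rule
  flag anyway?

Experiment sizes follow the package's standard validation conditions:
50,000 cases per bundle, lambda in {2, 4, 8}, 20 replicate seeds.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import pandas as pd

from .faers_io import load_cases
from .pipeline import annotate, signal_table
from .synthetic_faers import SignalPair, SyntheticConfig, generate_bundle
from .vocab import VocabularyBundle

#: Standard injected pairs: disjoint drugs and events, one per lambda,
#: each with background pair probability >= 1e-3.
RECOVERY_PAIRS = [
    SignalPair("MONTELUKAST", "Anxiety", 8.0),
    SignalPair("PROMETHAZINE", "Intentional self-injury", 4.0),
    SignalPair("DIPHENHYDRAMINE", "Depression", 2.0),
]

N_CASES = 50_000
N_SEEDS = 20


def derive_seeds(base_seed: int, n: int = N_SEEDS) -> list[int]:
    """Deterministic replicate seeds below 2^31 from one base seed."""
    return [(base_seed * 1_000_003 + 7919 * i) % (2**31) for i in range(n)]


def _pt_signals_for(config: SyntheticConfig, workdir: Path) -> pd.DataFrame:
    manifest = generate_bundle(config, workdir)
    vocab = VocabularyBundle.read(manifest.paths["drug_dict"],
                                  manifest.paths["meddra"])
    cases, _ = load_cases(manifest)
    data = annotate(cases, vocab)
    return signal_table(data, level="pt")


def recovery_experiment(base_seed: int, *, n_cases: int = N_CASES,
                        n_seeds: int = N_SEEDS,
                        pairs: list[SignalPair] | None = None,
                        workdir: str | Path | None = None) -> pd.DataFrame:
    """One row per (replicate seed, injected pair) with estimate and truth.

    Each bundle carries a single injected pair, so the generating joint's
    closed-form ROR equals lambda exactly and CI coverage of lambda is the
    right check (with several pairs per bundle the cross terms inflate the
    d cell slightly).
    """
    pairs = list(pairs if pairs is not None else RECOVERY_PAIRS)
    rows = []
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        for pair in pairs:
            for i, seed in enumerate(derive_seeds(base_seed, n_seeds)):
                config = SyntheticConfig(n_cases=n_cases, seed=seed,
                                         signal_pairs=[pair])
                tab = _pt_signals_for(
                    config, Path(tmp) / f"lam{pair.lam:g}_rep{i}")
                row = tab.set_index(["drug", "event"]).loc[
                    (pair.drug.title(), pair.pt_name)]
                rows.append({
                    "replicate": i, "seed": seed, "drug": pair.drug,
                    "pt_name": pair.pt_name, "lam": pair.lam,
                    "a": int(row["a"]), "ror": float(row["ror"]),
                    "ror_lo": float(row["ror_lo"]),
                    "ror_hi": float(row["ror_hi"]),
                    "composite": bool(row["composite"]),
                    "ci_covers_lambda": bool(row["ror_lo"] <= pair.lam
                                             <= row["ror_hi"]),
                })
    return pd.DataFrame(rows)


def null_experiment(base_seed: int, *, n_cases: int = N_CASES,
                    n_seeds: int = N_SEEDS,
                    workdir: str | Path | None = None) -> pd.DataFrame:
    """PT-level pairs from signal-free bundles, pooled over replicates."""
    rows = []
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        for i, seed in enumerate(derive_seeds(base_seed, n_seeds)):
            config = SyntheticConfig(n_cases=n_cases, seed=seed,
                                     signal_pairs=[])
            tab = _pt_signals_for(config, Path(tmp) / f"rep{i}")
            tab = tab.assign(replicate=i, seed=seed)
            rows.append(tab[["replicate", "seed", "drug", "event", "a",
                             "ror", "ror_lo", "composite"]])
    return pd.concat(rows, ignore_index=True)


def recovery_summary(recovery: pd.DataFrame) -> dict:
    """Coverage and detection rates from a recovery experiment table."""
    out = {
        "ci_coverage_overall": float(recovery["ci_covers_lambda"].mean()),
        "n_replicate_pairs": int(len(recovery)),
    }
    for lam, grp in recovery.groupby("lam"):
        out[f"ci_coverage_lambda_{lam:g}"] = float(grp["ci_covers_lambda"].mean())
        out[f"mean_ror_lambda_{lam:g}"] = float(grp["ror"].mean())
        out[f"composite_rate_lambda_{lam:g}"] = float(grp["composite"].mean())
    return out


def null_summary(null: pd.DataFrame) -> dict:
    evaluable = null[null["a"] >= 3]
    return {
        "n_pairs_evaluable": int(len(evaluable)),
        "composite_flag_rate": float(evaluable["composite"].mean())
        if len(evaluable) else float("nan"),
    }
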