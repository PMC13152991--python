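"""Synthetic FAERS-style quarterly bundles with known ground truth.

The generator emits the "$"-delimited DEMO / DRUG / REAC / OUTC / THER /
INDI tables plus a deleted-case-ID list, in the layout of a FAERS quarterly
ASCII package, together with a mock drug dictionary and MedDRA-style
hierarchy. Drug and event are independent in the background; for each
configured signal pair the joint probability is multiplied by a relative
reporting rate lambda >= 1 and the whole joint is renormalized, so the
generating reporting odds ratio is known in closed form (it equals lambda
exactly when a single pair is injected, and lambda times a factor very close
to 1 when several disjoint pairs are injected — the manifest records the
exact value).

Realism knobs deliberately exercise the awkward parts of FAERS ingestion:
duplicate case versions (same CASEID, increasing FDA_DT, with a configurable
fraction of FDA_DT ties so the PRIMARYID tie-break matters), deleted-case
lists, ages in mixed units (YR/MON/WK/DY/DEC), and partial YYYYMM / YYYY
dates. The seed fully determines the output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .vocab import (FOCUS_HLGT_CODES, PSYCHIATRIC_SOC_CODE, DrugDictionary,
                    MeddraHierarchy, VocabularyBundle)


class DrugSpec(NamedTuple):
    name: str
    atc: str
    prob: float


class EventSpec(NamedTuple):
    pt_name: str
    pt_code: int
    prob: float
    #: hierarchy placement: anxiety | depressed | suicidal | psych_other |
    #: nervous | gastro | skin | other
    group: str = "other"


class SignalPair(NamedTuple):
    drug: str
    pt_name: str
    lam: float  # relative reporting rate, >= 1


FILLER_DRUG = DrugSpec("OTHER MEDICATION", "V03AX", 0.0)
FILLER_EVENT = EventSpec("Drug ineffective", 10013709, 0.0, "other")

# group -> (hlt, hlgt_code, hlgt_name, soc_code, soc_name)
_GROUP_HIERARCHY = {
    "anxiety": ("Anxiety symptoms", 10002861,
                "Anxiety disorders and symptoms",
                PSYCHIATRIC_SOC_CODE, "Psychiatric disorders"),
    "depressed": ("Depressive disorders", 10012375,
                  "Depressed mood disorders and disturbances",
                  PSYCHIATRIC_SOC_CODE, "Psychiatric disorders"),
    "suicidal": ("Suicidal and self-injurious behaviours NEC", 10042460,
                 "Suicidal and self-injurious behaviours",
                 PSYCHIATRIC_SOC_CODE, "Psychiatric disorders"),
    "psych_other": ("Disturbances in sleep", 10040991,
                    "Sleep disorders and disturbances",
                    PSYCHIATRIC_SOC_CODE, "Psychiatric disorders"),
    "nervous": ("Headaches NEC", 10019233, "Headaches",
                10029205, "Nervous system disorders"),
    "gastro": ("Nausea and vomiting symptoms", 10028817,
               "Gastrointestinal signs and symptoms",
               10017947, "Gastrointestinal disorders"),
    "skin": ("Rashes, eruptions and exanthems NEC", 10037868,
             "Epidermal and dermal conditions",
             10040785, "Skin and subcutaneous tissue disorders"),
    "other": ("General signs and symptoms NEC", 10018073,
              "General system disorders NEC",
              10018065, "General disorders and administration site conditions"),
}

_OUTCOME_CODES = ["OT", "HO", "DS", "LT", "DE", "RI", "CA"]
_OUTCOME_PROBS = [0.540, 0.224, 0.084, 0.078, 0.053, 0.015, 0.006]
_AGE_BIN_EDGES = {"0-4": (0.0, 5.0), "5-11": (5.0, 12.0), "12-17": (12.0, 18.0)}


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic bundle.

    Background drug probabilities and event probabilities must each sum to
    at most 1; the remainder goes to a filler drug / filler event so each
    case always has exactly one primary-suspect drug and (by default) one
    reaction PT. ``signal_pairs`` multiply the joint probability of the
    named (drug, PT) cell by lambda before renormalization; every pair not
    listed has lambda = 1.
    """

    n_cases: int = 5_000
    drugs: list[DrugSpec] = field(default_factory=lambda: list(DEFAULT_DRUGS))
    events: list[EventSpec] = field(default_factory=lambda: list(DEFAULT_EVENTS))
    signal_pairs: list[SignalPair] = field(default_factory=list)
    age_dist: dict[str, float] = field(
        default_factory=lambda: {"0-4": 0.1484, "5-11": 0.3905, "12-17": 0.4611})
    sex_ratio: float = 0.5          # fraction female among cases with known sex
    duplicate_rate: float = 0.10    # fraction of cases emitted in >= 2 versions
    deletion_rate: float = 0.02     # fraction of caseids put on the deleted list
    fda_tie_rate: float = 0.25      # fraction of duplicate sets with tied FDA_DT
    partial_date_rate: float = 0.10  # fraction of event/therapy dates truncated
    missing_age_rate: float = 0.02
    missing_sex_rate: float = 0.02
    serious_rate: float = 0.826
    multi_pt_rate: float = 0.0      # chance of one extra background reaction PT
    seed: int = 0

    def __post_init__(self) -> None:
        self.drugs = [DrugSpec(*d) for d in self.drugs]
        self.events = [EventSpec(*e) for e in self.events]
        self.signal_pairs = [SignalPair(*p) for p in self.signal_pairs]
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        pd_sum = sum(d.prob for d in self.drugs)
        pe_sum = sum(e.prob for e in self.events)
        if not (0 < pd_sum <= 1 + 1e-12):
            raise ValueError(f"drug probabilities sum to {pd_sum}, need (0, 1]")
        if not (0 < pe_sum <= 1 + 1e-12):
            raise ValueError(f"event probabilities sum to {pe_sum}, need (0, 1]")
        if any(p.prob < 0 for p in self.drugs) or any(e.prob < 0 for e in self.events):
            raise ValueError("probabilities must be non-negative")
        drug_names = {d.name for d in self.drugs}
        event_names = {e.pt_name for e in self.events}
        for pair in self.signal_pairs:
            if pair.lam < 1:
                raise ValueError(f"lambda must be >= 1, got {pair.lam}")
            if pair.drug not in drug_names:
                raise ValueError(f"signal drug {pair.drug!r} not in drugs")
            if pair.pt_name not in event_names:
                raise ValueError(f"signal PT {pair.pt_name!r} not in events")
        for name, v in (("duplicate_rate", self.duplicate_rate),
                        ("deletion_rate", self.deletion_rate)):
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not (0 <= self.sex_ratio <= 1):
            raise ValueError("sex_ratio must be in [0, 1]")
        if abs(sum(self.age_dist.values()) - 1) > 1e-9:
            raise ValueError("age_dist probabilities must sum to 1")


DEFAULT_DRUGS = [
    DrugSpec("MONTELUKAST", "R03DC03", 0.06),
    DrugSpec("PROMETHAZINE", "R06AD02", 0.05),
    DrugSpec("DIPHENHYDRAMINE", "R06AA02", 0.05),
    DrugSpec("DESLORATADINE", "R06AX27", 0.02),
    DrugSpec("LEVOCETIRIZINE", "R06AE09", 0.02),
    DrugSpec("LORATADINE-PSEUDOEPHEDRINE", "R01BA52;R06AX13", 0.01),
    DrugSpec("PARACETAMOL", "N02BE01", 0.12),
    DrugSpec("IBUPROFEN", "M01AE01", 0.10),
    DrugSpec("METHYLPHENIDATE", "N06BA04", 0.07),
    DrugSpec("FLUOXETINE", "N06AB03", 0.06),
]

DEFAULT_EVENTS = [
    EventSpec("Anxiety", 10002855, 0.030, "anxiety"),
    EventSpec("Agitation", 10001497, 0.012, "anxiety"),
    EventSpec("Depression", 10012378, 0.025, "depressed"),
    EventSpec("Depressed mood", 10012374, 0.008, "depressed"),
    EventSpec("Suicidal ideation", 10042458, 0.012, "suicidal"),
    EventSpec("Suicide attempt", 10042464, 0.006, "suicidal"),
    EventSpec("Intentional self-injury", 10022524, 0.020, "suicidal"),
    EventSpec("Completed suicide", 10010144, 0.003, "suicidal"),
    EventSpec("Insomnia", 10022437, 0.020, "psych_other"),
    EventSpec("Headache", 10019211, 0.080, "nervous"),
    EventSpec("Nausea", 10028813, 0.080, "gastro"),
    EventSpec("Rash", 10037844, 0.050, "skin"),
]

#: Column subsets of the real FAERS schemas that the pipeline consumes.
BUNDLE_COLUMNS = {
    "DEMO": ["primaryid", "caseid", "fda_dt", "age", "age_cod", "sex",
             "occp_cod", "reporter_country", "event_dt"],
    "DRUG": ["primaryid", "drug_seq", "drugname", "role_cod", "route"],
    "REAC": ["primaryid", "pt"],
    "OUTC": ["primaryid", "outc_cod"],
    "THER": ["primaryid", "dsg_drug_seq", "start_dt"],
    "INDI": ["primaryid", "indi_drug_seq", "indi_pt"],
}


@dataclass
class BundleManifest:
    """Paths, consumed columns and injected ground truth for one bundle."""

    out_dir: Path
    paths: dict[str, Path]
    n_cases: int
    seed: int
    ground_truth: pd.DataFrame  # drug, pt_name, lam, generating_ror
    n_duplicate_cases: int
    n_deleted_cases: int

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n_cases": int(self.n_cases),
            "seed": int(self.seed),
            "n_duplicate_cases": int(self.n_duplicate_cases),
            "n_deleted_cases": int(self.n_deleted_cases),
            "files": {k: str(Path(v).name) for k, v in self.paths.items()},
            "columns": BUNDLE_COLUMNS,
            "ground_truth": self.ground_truth.to_dict(orient="records"),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def _joint_distribution(config: SyntheticConfig):
    """Drug x event joint probabilities (filler row/column appended last)."""
    p_drug = np.array([d.prob for d in config.drugs] +
                      [1.0 - sum(d.prob for d in config.drugs)])
    p_event = np.array([e.prob for e in config.events] +
                       [1.0 - sum(e.prob for e in config.events)])
    p_drug = np.clip(p_drug, 0.0, None)
    p_event = np.clip(p_event, 0.0, None)
    joint = np.outer(p_drug, p_event)
    drug_idx = {d.name: i for i, d in enumerate(config.drugs)}
    event_idx = {e.pt_name: j for j, e in enumerate(config.events)}
    for pair in config.signal_pairs:
        joint[drug_idx[pair.drug], event_idx[pair.pt_name]] *= pair.lam
    joint /= joint.sum()
    return joint, drug_idx, event_idx


def generating_ror(config: SyntheticConfig) -> pd.DataFrame:
    """Closed-form ROR of the generating joint for each signal pair."""
    joint, drug_idx, event_idx = _joint_distribution(config)
    rows = []
    for pair in config.signal_pairs:
        i, j = drug_idx[pair.drug], event_idx[pair.pt_name]
        a = joint[i, j]
        row, col = joint[i, :].sum(), joint[:, j].sum()
        b, c = row - a, col - a
        d = 1.0 - row - col + a
        rows.append({"drug": pair.drug, "pt_name": pair.pt_name,
                     "lam": float(pair.lam),
                     "generating_ror": float(a * d / (b * c))})
    return pd.DataFrame(rows, columns=["drug", "pt_name", "lam", "generating_ror"])


def _format_dates(dates: np.ndarray) -> np.ndarray:
    """datetime64[D] -> YYYYMMDD strings."""
    s = pd.Series(dates).dt.strftime("%Y%m%d")
    return s.to_numpy(dtype=object)


def _truncate_partial(dates: np.ndarray, rng: np.random.Generator,
                      rate: float) -> np.ndarray:
    """Truncate a random fraction of YYYYMMDD strings to YYYYMM or YYYY."""
    out = dates.copy()
    u = rng.random(len(out))
    out[u < rate / 2] = [s[:6] for s in out[u < rate / 2]]
    mask = (u >= rate / 2) & (u < rate)
    out[mask] = [s[:4] for s in out[mask]]
    return out


def _sample_ages(config: SyntheticConfig, rng: np.random.Generator, n: int):
    """Age value/unit pairs in mixed units, by age-bin distribution."""
    bins = list(config.age_dist)
    probs = np.array([config.age_dist[b] for b in bins])
    bin_idx = rng.choice(len(bins), size=n, p=probs / probs.sum())
    lo = np.array([_AGE_BIN_EDGES[b][0] for b in bins])[bin_idx]
    hi = np.array([_AGE_BIN_EDGES[b][1] for b in bins])[bin_idx]
    age_years = lo + rng.random(n) * (hi - lo)

    value = np.empty(n, dtype=object)
    unit = np.empty(n, dtype=object)
    u = rng.random(n)
    young = age_years < 5.0
    # infants/toddlers: mixed YR / MON / WK / DY
    value[young & (u < 0.5)] = np.floor(age_years[young & (u < 0.5)]).astype(int)
    unit[young & (u < 0.5)] = "YR"
    m = young & (u >= 0.5) & (u < 0.8)
    value[m] = np.floor(age_years[m] * 12).astype(int)
    unit[m] = "MON"
    m = young & (u >= 0.8) & (u < 0.9)
    value[m] = np.floor(age_years[m] * 52.18).astype(int)
    unit[m] = "WK"
    m = young & (u >= 0.9)
    value[m] = np.floor(age_years[m] * 365.25).astype(int)
    unit[m] = "DY"
    # older children: years, with the occasional exact decade coded as DEC
    older = ~young
    value[older] = np.floor(age_years[older]).astype(int)
    unit[older] = "YR"
    dec = older & (np.floor(age_years) == 10) & (rng.random(n) < 0.3)
    age_years[dec] = 10.0
    value[dec] = 1
    unit[dec] = "DEC"
    # missing ages
    miss = rng.random(n) < config.missing_age_rate
    value[miss] = ""
    unit[miss] = ""
    age_years[miss] = np.nan
    return value, unit, age_years


def _categorical(rng, n, labels, probs):
    probs = np.asarray(probs, dtype=float)
    idx = rng.choice(len(labels), size=n, p=probs / probs.sum())
    return np.array(labels, dtype=object)[idx]


def generate_tables(config: SyntheticConfig) -> dict[str, pd.DataFrame]:
    """Generate the six report tables plus the deleted-ID list in memory.

    Returns a dict with keys DEMO/DRUG/REAC/OUTC/THER/INDI (DataFrames) and
    DELETED (a sorted list of caseid strings).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases

    joint, _, _ = _joint_distribution(config)
    flat = joint.ravel()
    cell = rng.choice(flat.size, size=n, p=flat)
    drug_i, event_j = np.unravel_index(cell, joint.shape)

    drug_specs = list(config.drugs) + [FILLER_DRUG]
    event_specs = list(config.events) + [FILLER_EVENT]
    drugnames = np.array([d.name for d in drug_specs], dtype=object)[drug_i]
    pt_names = np.array([e.pt_name for e in event_specs], dtype=object)[event_j]

    caseid = np.arange(100_000_001, 100_000_001 + n)

    age_value, age_unit, _ = _sample_ages(config, rng, n)
    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M").astype(object)
    sex[rng.random(n) < config.missing_sex_rate] = ""
    country = _categorical(rng, n, ["US", "GB", "SE", "FR", "DE", "CA", "JP"],
                           [0.55, 0.16, 0.045, 0.07, 0.07, 0.06, 0.045])
    reporter = _categorical(rng, n, ["CN", "MD", "OT", "PH", "", "LW"],
                            [0.384, 0.274, 0.141, 0.128, 0.071, 0.002])
    route = _categorical(rng, n, ["Oral", "", "Subcutaneous",
                                  "Respiratory (inhalation)", "Topical"],
                         [0.61, 0.24, 0.08, 0.045, 0.025])
    indication = _categorical(
        rng, n,
        ["Asthma", "", "Dermatitis atopic", "Cystic fibrosis",
         "Rhinitis allergic", "Cough", "Pain"],
        [0.28, 0.30, 0.042, 0.042, 0.12, 0.10, 0.116])

    # event date: year by reporting-era weights, then uniform month/day
    year_bin = _categorical(rng, n, ["2004-2008", "2009-2013", "2014-2018",
                                     "2019-2024"],
                            [0.1291, 0.1735, 0.1900, 0.5074])
    year_lo = np.array([int(b.split("-")[0]) for b in year_bin])
    year_hi = np.array([int(b.split("-")[1]) for b in year_bin])
    year = year_lo + (rng.random(n) * (year_hi - year_lo + 1)).astype(int)
    month = rng.integers(1, 13, size=n)
    day = rng.integers(1, 29, size=n)
    event_date = pd.to_datetime(
        {"year": year, "month": month, "day": day}).to_numpy("datetime64[D]")
    # time to onset: mostly first week or late in the first year of therapy
    onset = np.select(
        [rng.random(n) < 0.28, rng.random(n) < 0.07, rng.random(n) < 0.16],
        [rng.integers(0, 8, size=n), rng.integers(8, 61, size=n),
         rng.integers(61, 181, size=n)],
        default=rng.integers(181, 361, size=n)).astype("timedelta64[D]")
    start_date = event_date - onset
    fda_date = event_date + rng.integers(1, 60, size=n).astype("timedelta64[D]")

    fda_dt = _format_dates(fda_date)
    event_dt = _truncate_partial(_format_dates(event_date), rng,
                                 config.partial_date_rate)
    start_dt = _truncate_partial(_format_dates(start_date), rng,
                                 config.partial_date_rate)

    # duplicate versions: version 1..k per case, canonical row is the last
    n_dup = int(round(config.duplicate_rate * n))
    dup_cases = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], int)
    extra_versions = np.zeros(n, dtype=int)
    extra_versions[dup_cases] = np.where(rng.random(n_dup) < 0.2, 2, 1)
    tied = np.zeros(n, dtype=bool)
    tied[dup_cases] = rng.random(n_dup) < config.fda_tie_rate

    version = extra_versions + 1  # canonical version number
    primaryid = caseid * 10 + version

    demo = pd.DataFrame({
        "primaryid": primaryid, "caseid": caseid, "fda_dt": fda_dt,
        "age": age_value, "age_cod": age_unit, "sex": sex,
        "occp_cod": reporter, "reporter_country": country,
        "event_dt": event_dt,
    })

    if n_dup:
        parts = [demo]
        for v in (1, 2):
            idx = np.where(extra_versions >= v)[0]
            if idx.size == 0:
                continue
            sub = demo.iloc[idx].copy()
            sub["primaryid"] = caseid[idx] * 10 + v
            back = 30 * (extra_versions[idx] - v + 1)
            prior = (pd.Series(fda_date[idx])
                     - pd.to_timedelta(back, unit="D")).dt.strftime("%Y%m%d")
            sub["fda_dt"] = np.where(tied[idx], sub["fda_dt"],
                                     prior.to_numpy(dtype=object))
            parts.append(sub)
        demo = pd.concat(parts, ignore_index=True)
    demo = demo.sort_values("primaryid", kind="mergesort").reset_index(drop=True)

    all_pids = demo["primaryid"].to_numpy()

    drug = pd.DataFrame({
        "primaryid": primaryid, "drug_seq": 1, "drugname": drugnames,
        "role_cod": "PS", "route": route,
    })
    reac = pd.DataFrame({"primaryid": primaryid, "pt": pt_names})
    if config.multi_pt_rate > 0:
        extra_mask = rng.random(n) < config.multi_pt_rate
        p_event = np.array([e.prob for e in event_specs])
        p_event[-1] = max(0.0, 1.0 - p_event[:-1].sum())
        extra_j = rng.choice(len(event_specs), size=int(extra_mask.sum()),
                             p=p_event / p_event.sum())
        extra = pd.DataFrame({
            "primaryid": primaryid[extra_mask],
            "pt": np.array([e.pt_name for e in event_specs], dtype=object)[extra_j],
        })
        reac = pd.concat([reac, extra], ignore_index=True)
        reac = reac.drop_duplicates().sort_values(
            ["primaryid", "pt"], kind="mergesort").reset_index(drop=True)

    serious = rng.random(n) < config.serious_rate
    first_code = _categorical(rng, n, _OUTCOME_CODES, _OUTCOME_PROBS)
    second_code = _categorical(rng, n, _OUTCOME_CODES, _OUTCOME_PROBS)
    outc_rows = [pd.DataFrame({"primaryid": primaryid[serious],
                               "outc_cod": first_code[serious]})]
    second = serious & (rng.random(n) < 0.15) & (first_code != second_code)
    outc_rows.append(pd.DataFrame({"primaryid": primaryid[second],
                                   "outc_cod": second_code[second]}))
    outc = pd.concat(outc_rows, ignore_index=True).sort_values(
        ["primaryid", "outc_cod"], kind="mergesort").reset_index(drop=True)

    ther = pd.DataFrame({"primaryid": primaryid, "dsg_drug_seq": 1,
                         "start_dt": start_dt})
    indi = pd.DataFrame({"primaryid": primaryid, "indi_drug_seq": 1,
                         "indi_pt": indication})

    # earlier versions reuse the canonical drug/reaction rows under their own
    # primaryid; they become orphans after deduplication, which downstream
    # assembly must drop and count
    if n_dup:
        dup_pids = np.setdiff1d(all_pids, primaryid)
        dup_case = dup_pids // 10
        pos = {int(c): i for i, c in enumerate(caseid)}
        src = np.array([pos[int(c)] for c in dup_case])
        drug = pd.concat([drug, pd.DataFrame({
            "primaryid": dup_pids, "drug_seq": 1, "drugname": drugnames[src],
            "role_cod": "PS", "route": route[src]})], ignore_index=True)
        reac = pd.concat([reac, pd.DataFrame({
            "primaryid": dup_pids, "pt": pt_names[src]})], ignore_index=True)

    for frame in (drug, reac, outc, ther, indi):
        frame.sort_values("primaryid", kind="mergesort", inplace=True,
                          ignore_index=True)

    n_del = int(round(config.deletion_rate * n))
    deleted = sorted(str(c) for c in
                     (rng.choice(caseid, size=n_del, replace=False)
                      if n_del else []))

    return {"DEMO": demo, "DRUG": drug, "REAC": reac, "OUTC": outc,
            "THER": ther, "INDI": indi, "DELETED": deleted,
            "_n_dup": n_dup, "_n_del": n_del}


def generate_bundle(config: SyntheticConfig, out_dir: str | Path) -> BundleManifest:
    """Write a complete "$"-delimited bundle plus vocab and manifest files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = generate_tables(config)

    paths: dict[str, Path] = {}
    for name in ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI"):
        p = out_dir / f"{name}.txt"
        tables[name][BUNDLE_COLUMNS[name]].to_csv(
            p, sep="$", index=False, lineterminator="\n")
        paths[name] = p
    p = out_dir / "DELETED.txt"
    p.write_text("".join(f"{c}\n" for c in tables["DELETED"]))
    paths["DELETED"] = p

    vocab = generate_vocab(config)
    vocab.write(out_dir / "drug_dict.tsv", out_dir / "meddra.tsv")
    paths["drug_dict"] = out_dir / "drug_dict.tsv"
    paths["meddra"] = out_dir / "meddra.tsv"

    manifest = BundleManifest(
        out_dir=out_dir, paths=paths, n_cases=config.n_cases,
        seed=config.seed, ground_truth=generating_ror(config),
        n_duplicate_cases=tables["_n_dup"], n_deleted_cases=tables["_n_del"],
    )
    manifest.to_yaml(out_dir / "manifest.yaml")
    return manifest


def generate_vocab(config: SyntheticConfig) -> VocabularyBundle:
    """Mock drug dictionary and MedDRA-style hierarchy for a config.

    Every synthetic drug maps to an ATC code (respiratory products to codes
    beginning "R"); every PT lies on exactly one PT -> HLT -> HLGT -> SOC
    path, and the psychiatric SOC with the three focus HLGTs is present.
    """
    drugs = DrugDictionary()
    for spec in list(config.drugs) + [FILLER_DRUG]:
        drugs.add(spec.name, spec.name.title(), spec.atc)

    rows = []
    for ev in list(config.events) + [FILLER_EVENT]:
        hlt, hlgt_code, hlgt_name, soc_code, soc_name = _GROUP_HIERARCHY[ev.group]
        rows.append((ev.pt_code, ev.pt_name, hlt, hlgt_code, hlgt_name,
                     soc_code, soc_name))
    table = pd.DataFrame(rows, columns=MeddraHierarchy.REQUIRED)
    # the three focus HLGTs must be addressable even if no configured event
    # falls under one of them
    for code, name in FOCUS_HLGT_CODES.items():
        if code not in set(table["hlgt_code"].astype(int)):
            group = {10002861: "anxiety", 10012375: "depressed",
                     10042460: "suicidal"}[code]
            hlt = _GROUP_HIERARCHY[group][0]
            placeholder = (90000000 + code % 100000,
                           f"{name} NOS", hlt, code, name,
                           PSYCHIATRIC_SOC_CODE, "Psychiatric disorders")
            table.loc[len(table)] = placeholder
    return VocabularyBundle(drugs, MeddraHierarchy(table))
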