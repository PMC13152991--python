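"""Descriptive frequency tables with exact count/percentage arithmetic.

Percentages are 100 * count / denominator rounded half-up to two decimals
(the convention that reproduces printed pharmacovigilance tables, e.g.
3,443 / 6,994 -> 49.23). Single-choice tables sum to their denominator;
multi-select tables (outcome categories — a report can have several
outcomes) may exceed it and are marked as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .cohort import AGE_GROUPS, CohortResult, ONSET_BINS, OUTCOME_CODES, YEAR_BINS

OUTCOME_LABELS = {
    "DE": "Death", "LT": "Life-threatening",
    "HO": "Hospitalization (initial or prolonged)", "DS": "Disability",
    "CA": "Congenital anomaly", "RI": "Required intervention", "OT": "Other",
}

REPORTER_LABELS = {
    "CN": "Consumer", "MD": "Physician", "PH": "Pharmacist",
    "OT": "Other health-professional", "LW": "Lawyer", "": "Not specified",
}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (5 rounds up)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: float, denominator: float, ndigits: int = 2) -> float:
    """Percentage of a denominator, rounded half-up."""
    if denominator == 0:
        return float("nan")
    return round_half_up(100.0 * count / denominator, ndigits)


@dataclass
class FrequencyTable:
    """Counts and percentages of one categorical characteristic."""

    name: str
    table: pd.DataFrame  # columns: category, count, percent
    denominator: int
    denominator_kind: str = "patients"  # patients | pairs | drug-specific reports
    multi_select: bool = False

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "characteristic", self.name)
        return out


def frequency_table(name: str, counts: pd.Series, denominator: int, *,
                    denominator_kind: str = "patients",
                    multi_select: bool = False,
                    categories: list[str] | None = None) -> FrequencyTable:
    """Build a table from a category->count mapping.

    When ``categories`` is given the rows appear in that order (absent
    categories get zero counts); otherwise rows are sorted by descending
    count then label.
    """
    counts = counts.astype(int)
    if categories is not None:
        counts = counts.reindex(categories, fill_value=0)
    else:
        counts = counts.sort_values(ascending=False)
        counts = counts.loc[sorted(counts.index,
                                   key=lambda k: (-counts[k], str(k)))]
    table = pd.DataFrame({
        "category": counts.index.astype(str),
        "count": counts.to_numpy(),
        "percent": [pct(c, denominator) for c in counts.to_numpy()],
    })
    if not multi_select and denominator and counts.sum() != denominator:
        # single-choice categories must exhaust the denominator
        raise ValueError(
            f"{name}: single-select counts sum to {counts.sum()}, "
            f"denominator is {denominator}")
    return FrequencyTable(name, table, int(denominator),
                          denominator_kind, multi_select)


def _median_iqr(values: pd.Series) -> dict[str, float]:
    """Median and IQR with linear-interpolation quartiles."""
    v = pd.to_numeric(values, errors="coerce").dropna().to_numpy()
    if v.size == 0:
        return {"median": float("nan"), "q1": float("nan"), "q3": float("nan")}
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def summarize_cohort(cohort: CohortResult, top_k_countries: int = 3,
                     top_k_indications: int = 4) -> dict:
    """Cohort-level frequency tables plus age / onset medians.

    Returns a dict with a :class:`FrequencyTable` per characteristic
    (gender, age group, reporter, country, route, indication, seriousness,
    outcomes, onset bins, reporting-year bins) and ``age_median_iqr`` /
    ``onset_median_iqr`` entries. The denominator is the patient count.
    An empty cohort yields empty tables, not an error.
    """
    cases = cohort.cases
    n = len(cases)
    out: dict = {"n_patients": n, "n_pairs": len(cohort.pair_table)}

    sex = cases["sex"].replace("", "Not specified").replace(
        {"F": "Female", "M": "Male"})
    out["gender"] = frequency_table("Gender", sex.value_counts(), n)

    out["age_group"] = frequency_table(
        "Age group (years)", cases["age_group"].value_counts(), n,
        categories=AGE_GROUPS)
    out["age_median_iqr"] = _median_iqr(cases["age_years"])

    reporter = cases["reporter"].map(
        lambda c: REPORTER_LABELS.get(str(c).upper(), str(c) or "Not specified"))
    reporter = reporter.replace("", "Not specified")
    out["reporter"] = frequency_table("Reporter", reporter.value_counts(), n)

    country = cases["country"].replace("", "Not specified")
    cc = country.value_counts()
    top = cc.head(top_k_countries)
    out["country"] = frequency_table(
        "Reported countries (top)", top, n, multi_select=True)

    route = cases["route"].replace("", "Not specified")
    out["route"] = frequency_table("Route", route.value_counts(), n)

    indication = cases["indication"].replace("", "Not specified")
    ic = indication.value_counts()
    out["indication"] = frequency_table(
        "Indication (top)", ic.head(top_k_indications), n, multi_select=True)

    degree = cases["serious"].map({True: "Serious", False: "Non-serious"})
    out["degree"] = frequency_table("Degree", degree.value_counts(), n,
                                    categories=["Serious", "Non-serious"])

    # multi-select: a report can carry several outcome codes
    code_counts = {}
    exploded = cases["outcome_codes"].str.split(";").explode()
    exploded = exploded[exploded != ""]
    vc = exploded.value_counts()
    for code in OUTCOME_CODES:
        code_counts[OUTCOME_LABELS[code]] = int(vc.get(code, 0))
    out["outcomes"] = frequency_table(
        "Outcomes", pd.Series(code_counts),
        n, multi_select=True,
        categories=[OUTCOME_LABELS[c] for c in
                    ["LT", "HO", "DS", "DE", "CA", "RI", "OT"]])

    out["onset"] = frequency_table(
        "AE occurrence time (days)", cases["onset_bin"].value_counts(), n,
        categories=ONSET_BINS)
    out["onset_median_iqr"] = _median_iqr(cases["onset_days"])

    years = cases["year_bin"].fillna("Unknown")
    year_cats = YEAR_BINS + (["Unknown"] if (years == "Unknown").any() else [])
    out["reporting_year"] = frequency_table(
        "Reporting year", years.value_counts(), n, categories=year_cats)
    return out


def drug_pt_composition(pair_table: pd.DataFrame, drug: str,
                        min_reports: int = 10) -> FrequencyTable:
    """Per-PT counts for one drug, as percent of the drug's pair total.

    Drugs whose total pair count is not strictly greater than
    ``min_reports`` return an empty table (pass ``min_reports=0`` to keep
    them). Unknown drugs also return an empty table.
    """
    mine = pair_table[pair_table["drug"] == drug]
    total = len(mine)
    if total == 0 or total <= min_reports:
        empty = pd.DataFrame(columns=["category", "count", "percent"])
        return FrequencyTable(f"{drug} PTs", empty, total,
                              "drug-specific reports")
    counts = mine["pt_name"].value_counts()
    return frequency_table(f"{drug} PTs", counts, total,
                           denominator_kind="drug-specific reports",
                           multi_select=False)


def drug_hlgt_composition(pair_table: pd.DataFrame, drug: str) -> FrequencyTable:
    """Counts over the three focus HLGTs (plus "Other") for one drug."""
    from .vocab import FOCUS_HLGT_CODES
    mine = pair_table[pair_table["drug"] == drug]
    total = len(mine)
    labels = list(FOCUS_HLGT_CODES.values())
    counts = mine["focus_hlgt"].fillna("Other").value_counts()
    table = frequency_table(
        f"{drug} focus HLGTs", counts, total,
        denominator_kind="drug-specific reports",
        categories=labels + ["Other"])
    return table


def serious_outcome_rates(pair_table: pd.DataFrame, drug: str) -> dict:
    """Death and life-threatening report counts/rates for one drug.

    Denominator is the drug's total pair count; numerators count pair rows
    whose report carries a DE (respectively LT) outcome code.
    """
    mine = pair_table[pair_table["drug"] == drug]
    total = len(mine)
    deaths = int(mine["has_death"].sum())
    lt = int(mine["has_lt"].sum())
    return {
        "drug": drug, "n_reports": total,
        "death_count": deaths, "death_pct": pct(deaths, total) if total else float("nan"),
        "life_threatening_count": lt,
        "life_threatening_pct": pct(lt, total) if total else float("nan"),
    }


def tables_to_frame(summary: dict) -> pd.DataFrame:
    """Flatten a :func:`summarize_cohort` result into one long CSV-ready frame."""
    frames = [v.to_frame() for v in summary.values()
              if isinstance(v, FrequencyTable)]
    return (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["characteristic", "category",
                                       "count", "percent"]))
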