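"""Cohort selection and per-case derived analysis fields.

Inclusion criteria for the analyzed cohort:

1. pediatric age — 0 to 17 years, implemented as [0, 18) after converting
   mixed FAERS age units (YR/MON/WK/DY/HR/DEC) to years;
2. at least one primary-suspect (PS) drug mapping to an ATC code in the
   respiratory "R" category;
3. at least one reaction preferred term under the psychiatric-disorders
   system organ class.

The analysis unit downstream is the (PS respiratory drug, psychiatric PT)
pair: one included patient contributes one pair row per such combination,
so the pair table can be larger than the patient table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .faers_io import CaseData
from .vocab import UNMAPPED, VocabularyBundle, normalize_drug_name

AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
    "DEC": 10.0,
}

AGE_GROUPS = ["0-4", "5-11", "12-17"]
ONSET_BINS = ["0-7", "8-60", "61-180", "181-360", ">360", "missing"]
YEAR_BINS = ["2004-2008", "2009-2013", "2014-2018", "2019-2024"]
OUTCOME_CODES = ["DE", "LT", "HO", "DS", "CA", "RI", "OT"]


def normalize_age(value, unit_code):
    """Convert an (age value, unit code) pair to years.

    Returns NaN for missing/negative values, missing units, and unknown
    unit codes. A decade (DEC) is ten years.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    try:
        v = float(value)
    except (TypeError, ValueError):
        return np.nan
    if np.isnan(v) or v < 0:
        return np.nan
    factor = AGE_UNIT_TO_YEARS.get(str(unit_code).strip().upper())
    if factor is None:
        return np.nan
    return v * factor


def normalize_age_series(value: pd.Series, unit: pd.Series) -> pd.Series:
    """Vectorized :func:`normalize_age`."""
    v = pd.to_numeric(value, errors="coerce")
    v = v.where(v >= 0)
    factor = unit.astype(str).str.strip().str.upper().map(AGE_UNIT_TO_YEARS)
    return v * factor


def age_group(age_years) -> str | float:
    """Pediatric age bin: 0-4, 5-11 or 12-17 years (NaN outside [0, 18))."""
    if age_years is None or np.isnan(age_years):
        return np.nan
    if 0 <= age_years < 5:
        return "0-4"
    if 5 <= age_years < 12:
        return "5-11"
    if 12 <= age_years < 18:
        return "12-17"
    return np.nan


def parse_full_dates(series: pd.Series) -> pd.Series:
    """Parse YYYYMMDD strings; partial (YYYYMM / YYYY) or bad -> NaT."""
    s = series.astype(str).str.strip()
    s = s.where(s.str.fullmatch(r"\d{8}"), other=pd.NA)
    return pd.to_datetime(s, format="%Y%m%d", errors="coerce")


def onset_days(event_dt, start_dt):
    """Days from therapy start to event onset; NaN unless both dates are
    complete YYYYMMDD and the difference is non-negative."""
    ev = parse_full_dates(pd.Series([str(event_dt)])).iloc[0]
    st = parse_full_dates(pd.Series([str(start_dt)])).iloc[0]
    if pd.isna(ev) or pd.isna(st):
        return np.nan
    delta = (ev - st).days
    return float(delta) if delta >= 0 else np.nan


def bin_onset(days) -> str:
    """Bin a time-to-onset in days: 0-7, 8-60, 61-180, 181-360, >360.

    Bin edges are inclusive integers; missing values get their own bin so
    the bins never silently exhaust the cohort.
    """
    if days is None or (isinstance(days, float) and np.isnan(days)):
        return "missing"
    d = float(days)
    if d < 0:
        return "missing"
    if d <= 7:
        return "0-7"
    if d <= 60:
        return "8-60"
    if d <= 180:
        return "61-180"
    if d <= 360:
        return "181-360"
    return ">360"


def year_bin(year) -> str | float:
    if pd.isna(year):
        return np.nan
    y = int(year)
    if 2004 <= y <= 2008:
        return "2004-2008"
    if 2009 <= y <= 2013:
        return "2009-2013"
    if 2014 <= y <= 2018:
        return "2014-2018"
    if 2019 <= y <= 2024:
        return "2019-2024"
    return np.nan


@dataclass(frozen=True)
class CaseRecord:
    """One analyzed patient with derived fields (record-style view)."""

    primaryid: str
    caseid: str
    age_years: float
    age_group: str
    sex: str
    reporter: str
    country: str
    route: str
    indication: str
    ps_drugs: tuple
    reaction_pts: tuple
    outcome_codes: frozenset
    serious: bool
    onset_days: float
    report_year: int


@dataclass
class CohortResult:
    """Included patients, the drug x PT pair table, and bookkeeping."""

    cases: pd.DataFrame
    pair_table: pd.DataFrame
    attrition: dict[str, int] = field(default_factory=dict)
    unmapped_drugs: int = 0
    unmapped_pts: int = 0


def _annotate_drugs(drugs: pd.DataFrame, vocab: VocabularyBundle):
    """Attach ingredient/ATC/respiratory flags to drug rows; count unmapped."""
    d = drugs.copy()
    norm = d["drugname"].map(normalize_drug_name)
    uniq = norm.unique()
    ing, atc, resp = {}, {}, {}
    n_unmapped = 0
    for name in uniq:
        hit = vocab.drugs.entries.get(name)
        if hit is None:
            n_unmapped += 1
            ing[name], atc[name], resp[name] = np.nan, np.nan, np.nan
        else:
            ing[name], atc[name] = hit
            resp[name] = any(code.strip().upper().startswith("R")
                             for code in str(hit[1]).split(";") if code.strip())
    d["ingredient"] = norm.map(ing)
    d["atc"] = norm.map(atc)
    d["is_respiratory"] = norm.map(resp)
    return d, n_unmapped


def _annotate_reactions(reac: pd.DataFrame, vocab: VocabularyBundle):
    r = reac.copy()
    pt_info = vocab.hierarchy.pt_frame().set_index("pt_name")
    r = r.merge(pt_info[["pt_code", "is_psychiatric", "focus_hlgt"]],
                left_on="pt", right_index=True, how="left")
    n_unmapped = int(r["is_psychiatric"].isna().sum())
    return r, n_unmapped


def select_cases(case_data: CaseData, vocab: VocabularyBundle,
                 age_range: tuple[float, float] = (0.0, 18.0)) -> CohortResult:
    """Apply the inclusion criteria and derive the analysis tables.

    Returns a :class:`CohortResult` whose ``cases`` frame has one row per
    included patient and whose ``pair_table`` has one row per (PS
    respiratory drug, psychiatric PT) combination within those patients.
    The attrition record counts cases surviving each sequential filter.
    """
    demo = case_data.demo.copy()
    demo["age_years"] = normalize_age_series(demo["age"], demo["age_cod"])
    demo["age_group"] = demo["age_years"].map(age_group)
    demo["report_year"] = pd.to_numeric(
        demo["fda_dt"].astype(str).str[:4], errors="coerce")
    demo["year_bin"] = demo["report_year"].map(year_bin)

    drugs, unmapped_drugs = _annotate_drugs(case_data.drugs, vocab)
    reac, unmapped_pts = _annotate_reactions(case_data.reactions, vocab)

    attrition = {"cases_assembled": len(demo)}

    lo, hi = age_range
    pediatric = demo[(demo["age_years"] >= lo) & (demo["age_years"] < hi)]
    attrition["cases_age_filtered"] = len(pediatric)

    ps_resp = drugs[(drugs["role_cod"].str.upper() == "PS")
                    & (drugs["is_respiratory"] == True)]  # noqa: E712
    with_rd = pediatric[pediatric["primaryid"].isin(set(ps_resp["primaryid"]))]
    attrition["cases_ps_respiratory"] = len(with_rd)

    psych = reac[reac["is_psychiatric"] == True]  # noqa: E712
    included = with_rd[with_rd["primaryid"].isin(set(psych["primaryid"]))]
    attrition["cases_psychiatric_pt"] = len(included)

    pids = set(included["primaryid"])
    ps_resp_in = ps_resp[ps_resp["primaryid"].isin(pids)]
    psych_in = psych[psych["primaryid"].isin(pids)]

    # one pair row per (case, PS respiratory drug, psychiatric PT)
    pair = ps_resp_in[["primaryid", "ingredient", "atc", "drug_seq",
                       "start_dt", "route", "indication"]].merge(
        psych_in[["primaryid", "pt", "pt_code", "focus_hlgt"]],
        on="primaryid", how="inner")
    pair = pair.drop_duplicates(["primaryid", "ingredient", "pt"])

    # outcomes: any outcome code present => serious
    outc = case_data.outcomes
    out_sets = outc.groupby("primaryid")["outc_cod"].agg(
        lambda s: ";".join(sorted(set(s.str.upper()))))
    cases = included.set_index("primaryid")
    cases["outcome_codes"] = out_sets
    cases["outcome_codes"] = cases["outcome_codes"].fillna("")
    cases["serious"] = cases["outcome_codes"] != ""
    cases["has_death"] = cases["outcome_codes"].str.contains("DE")
    cases["has_lt"] = cases["outcome_codes"].str.split(";").map(
        lambda codes: "LT" in codes)

    # attributes of the first PS respiratory drug (lowest drug_seq)
    first_rd = (ps_resp_in.assign(
        _seq=pd.to_numeric(ps_resp_in["drug_seq"], errors="coerce"))
        .sort_values(["primaryid", "_seq"], kind="mergesort")
        .groupby("primaryid").head(1).set_index("primaryid"))
    cases["route"] = first_rd["route"].reindex(cases.index).fillna("")
    cases["indication"] = first_rd["indication"].reindex(cases.index).fillna("")
    cases["ps_drugs"] = (ps_resp_in.groupby("primaryid")["ingredient"]
                         .agg(lambda s: ";".join(sorted(set(s.dropna()))))
                         .reindex(cases.index).fillna(""))

    # time to onset: event date minus the first PS drug's therapy start
    ev = parse_full_dates(cases["event_dt"])
    st = parse_full_dates(first_rd["start_dt"].reindex(cases.index))
    delta = (ev - st).dt.days.astype(float)
    cases["onset_days"] = delta.where(delta >= 0)
    cases["onset_bin"] = cases["onset_days"].map(bin_onset)

    cases = cases.reset_index()
    keep = ["primaryid", "caseid", "age_years", "age_group", "sex",
            "occp_cod", "reporter_country", "route", "indication", "ps_drugs",
            "outcome_codes", "serious", "has_death", "has_lt",
            "onset_days", "onset_bin", "report_year", "year_bin"]
    cases = cases[keep].rename(columns={"occp_cod": "reporter",
                                        "reporter_country": "country"})

    pair = pair.merge(
        cases[["primaryid", "caseid", "age_group", "sex", "serious",
               "has_death", "has_lt", "report_year", "year_bin"]],
        on="primaryid", how="left")
    pair = pair[["primaryid", "caseid", "ingredient", "atc", "pt", "pt_code",
                 "focus_hlgt", "age_group", "sex", "serious", "has_death",
                 "has_lt", "report_year", "year_bin"]].rename(
        columns={"ingredient": "drug", "pt": "pt_name"})
    pair = pair.sort_values(["drug", "pt_name", "primaryid"],
                            kind="mergesort").reset_index(drop=True)

    attrition["pair_rows"] = len(pair)
    return CohortResult(cases=cases.reset_index(drop=True), pair_table=pair,
                        attrition=attrition, unmapped_drugs=unmapped_drugs,
                        unmapped_pts=unmapped_pts)


def iter_case_records(cohort: CohortResult):
    """Yield :class:`CaseRecord` objects from a cohort result."""
    pair = cohort.pair_table
    for row in cohort.cases.itertuples(index=False):
        mine = pair[pair["primaryid"] == row.primaryid]
        yield CaseRecord(
            primaryid=row.primaryid, caseid=row.caseid,
            age_years=row.age_years, age_group=row.age_group, sex=row.sex,
            reporter=row.reporter, country=row.country, route=row.route,
            indication=row.indication,
            ps_drugs=tuple(sorted(set(zip(mine["drug"], mine["atc"])))),
            reaction_pts=tuple(sorted(set(mine["pt_name"]))),
            outcome_codes=frozenset(
                c for c in str(row.outcome_codes).split(";") if c),
            serious=bool(row.serious), onset_days=row.onset_days,
            report_year=int(row.report_year) if pd.notna(row.report_year) else -1,
        )
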