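"""End-to-end orchestration: bundle -> cohort -> signal tables.

The comparator (background) for every contingency table is the set of
deduplicated, deletion-filtered reports in the ingested bundle; by default
it is restricted to pediatric reports (ages [0, 18) after unit conversion),
with an all-ages alternative. Against that background:

* drug-level analysis: event = any PT under the psychiatric SOC;
* HLGT-level analysis: event = any PT under one focus HLGT;
* PT-level analysis: event = one psychiatric PT.

The drug margin is always "report carries the target drug as primary
suspect". All levels share the same four-algorithm evaluation and composite
rule from :mod:`faerspv.signal_stats`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import (CohortResult, _annotate_drugs, _annotate_reactions,
                     age_group, normalize_age_series, select_cases)
from .faers_io import CaseData, load_cases
from .signal_stats import compute_signal_table
from .vocab import VocabularyBundle

SOC_EVENT_LABEL = "Psychiatric disorders (SOC)"


@dataclass
class AnalysisData:
    """Annotated per-report frames shared by pooled and stratified analyses."""

    demo: pd.DataFrame       # + age_years, age_group
    ps_drugs: pd.DataFrame   # PS rows with ingredient/atc/is_respiratory
    reactions: pd.DataFrame  # + is_psychiatric, focus_hlgt
    unmapped_drugs: int
    unmapped_pts: int


def annotate(case_data: CaseData, vocab: VocabularyBundle) -> AnalysisData:
    demo = case_data.demo.copy()
    demo["age_years"] = normalize_age_series(demo["age"], demo["age_cod"])
    demo["age_group"] = demo["age_years"].map(age_group)
    drugs, und = _annotate_drugs(case_data.drugs, vocab)
    ps = drugs[drugs["role_cod"].str.upper() == "PS"]
    reac, unp = _annotate_reactions(case_data.reactions, vocab)
    return AnalysisData(demo=demo, ps_drugs=ps, reactions=reac,
                        unmapped_drugs=und, unmapped_pts=unp)


def _background_pids(data: AnalysisData, background: str) -> set[str]:
    if background == "pediatric":
        demo = data.demo[(data.demo["age_years"] >= 0)
                         & (data.demo["age_years"] < 18)]
    elif background == "all-ages":
        demo = data.demo
    else:
        raise ValueError(f"unknown background {background!r}")
    return set(demo["primaryid"].astype(str))


def _drug_sets(data: AnalysisData, pids: set[str],
               respiratory_only: bool = True) -> dict[str, set[str]]:
    ps = data.ps_drugs
    if respiratory_only:
        ps = ps[ps["is_respiratory"] == True]  # noqa: E712
    ps = ps.dropna(subset=["ingredient"])
    sets: dict[str, set[str]] = {}
    for ing, grp in ps.groupby("ingredient"):
        s = set(grp["primaryid"].astype(str)) & pids
        if s:
            sets[str(ing)] = s
    return sets


def _event_sets(data: AnalysisData, pids: set[str], level: str):
    reac = data.reactions[data.reactions["is_psychiatric"] == True]  # noqa: E712
    if level == "soc":
        return {SOC_EVENT_LABEL: set(reac["primaryid"].astype(str)) & pids}
    if level == "hlgt":
        sets = {}
        for hlgt, grp in reac.dropna(subset=["focus_hlgt"]).groupby("focus_hlgt"):
            s = set(grp["primaryid"].astype(str)) & pids
            if s:
                sets[str(hlgt)] = s
        return sets
    if level == "pt":
        sets = {}
        for pt, grp in reac.groupby("pt"):
            s = set(grp["primaryid"].astype(str)) & pids
            if s:
                sets[str(pt)] = s
        return sets
    raise ValueError(f"unknown level {level!r}; use soc, hlgt or pt")


def signal_counts(data: AnalysisData, *, level: str = "soc",
                  background: str = "pediatric",
                  stratum: tuple[str, str] | None = None) -> pd.DataFrame:
    """a/b/c/d counts per (drug, event) at the requested rollup level.

    ``stratum`` restricts the background (and therefore all four cells) to
    reports in one stratum, e.g. ``("age_group", "0-4")`` or ``("sex", "F")``
    — the operational meaning of stratified disproportionality.
    """
    pids = _background_pids(data, background)
    if stratum is not None:
        axis, value = stratum
        if axis not in ("age_group", "sex"):
            raise ValueError(f"unknown stratum axis {axis!r}")
        sub = data.demo[data.demo[axis] == value]
        pids = pids & set(sub["primaryid"].astype(str))
    n_total = len(pids)
    rows = []
    drug_sets = _drug_sets(data, pids)
    event_sets = _event_sets(data, pids, level)
    for drug in sorted(drug_sets):
        dset = drug_sets[drug]
        for event in sorted(event_sets):
            eset = event_sets[event]
            a = len(dset & eset)
            if a == 0 and level != "soc":
                continue
            b = len(dset) - a
            c = len(eset) - a
            d = n_total - a - b - c
            row = {"drug": drug, "level": level, "event": event,
                   "a": a, "b": b, "c": c, "d": d}
            if stratum is not None:
                row["stratum_axis"], row["stratum"] = stratum
            rows.append(row)
    cols = ["drug", "level", "event", "a", "b", "c", "d"]
    if stratum is not None:
        cols += ["stratum_axis", "stratum"]
    return pd.DataFrame(rows, columns=cols)


def signal_table(data: AnalysisData, *, level: str = "soc",
                 background: str = "pediatric", bcpnn_variant: str = "noren",
                 min_reports: int = 3,
                 stratum: tuple[str, str] | None = None) -> pd.DataFrame:
    """Four-algorithm signal table at one rollup level (optionally one stratum)."""
    counts = signal_counts(data, level=level, background=background,
                           stratum=stratum)
    if counts.empty:
        return counts
    return compute_signal_table(counts, bcpnn_variant=bcpnn_variant,
                                min_reports=min_reports)


@dataclass
class PipelineResult:
    """Everything one full run produces."""

    case_data: CaseData
    analysis: AnalysisData
    cohort: CohortResult
    drug_signals: pd.DataFrame
    pt_signals: pd.DataFrame
    hlgt_signals: pd.DataFrame
    attrition: dict


def run_pipeline(source, vocab: VocabularyBundle, *,
                 background: str = "pediatric", bcpnn_variant: str = "noren",
                 min_reports: int = 3) -> PipelineResult:
    """Ingest a bundle and compute cohort, descriptives inputs and signals."""
    case_data, attrition = load_cases(source)
    analysis = annotate(case_data, vocab)
    cohort = select_cases(case_data, vocab)
    attrition.update(cohort.attrition)
    kw = dict(background=background, bcpnn_variant=bcpnn_variant,
              min_reports=min_reports)
    return PipelineResult(
        case_data=case_data, analysis=analysis, cohort=cohort,
        drug_signals=signal_table(analysis, level="soc", **kw),
        pt_signals=signal_table(analysis, level="pt", **kw),
        hlgt_signals=signal_table(analysis, level="hlgt", **kw),
        attrition=attrition,
    )
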