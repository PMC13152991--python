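"""Age- and gender-stratified disproportionality and forest-plot exports.

Within each stratum the contingency background is restricted to reports in
that stratum (same-stratum non-cases), and the same four algorithms and
composite rule are applied. Drugs with fewer than the minimum number of
reports in a stratum are emitted with suppressed flags rather than dropped,
so the forest-plot export shows where the evidence is thin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cohort import AGE_GROUPS
from .pipeline import AnalysisData, signal_table

logger = logging.getLogger(__name__)

SEX_LEVELS = ["F", "M"]


@dataclass(frozen=True)
class StratumSpec:
    """One stratum: an axis (age_group or sex) and a level on it."""

    axis: str
    level: str

    def __post_init__(self) -> None:
        valid = {"age_group": AGE_GROUPS, "sex": SEX_LEVELS}
        if self.axis not in valid:
            raise ValueError(f"unknown stratum axis {self.axis!r}")
        if self.level not in valid[self.axis]:
            raise ValueError(
                f"level {self.level!r} invalid for axis {self.axis!r}")


def default_strata() -> list[StratumSpec]:
    """The five standard strata: three age groups and two sexes."""
    return ([StratumSpec("age_group", g) for g in AGE_GROUPS]
            + [StratumSpec("sex", s) for s in SEX_LEVELS])


def stratified_signals(data: AnalysisData,
                       strata: list[StratumSpec] | None = None, *,
                       level: str = "soc", background: str = "pediatric",
                       bcpnn_variant: str = "noren",
                       min_reports: int = 3) -> pd.DataFrame:
    """Signal table per (drug, stratum), stacked over the given strata.

    Strata with no reports at all contribute no rows (logged); drugs absent
    from a stratum likewise contribute no row for it.
    """
    frames = []
    for spec in (strata if strata is not None else default_strata()):
        tab = signal_table(data, level=level, background=background,
                           bcpnn_variant=bcpnn_variant,
                           min_reports=min_reports,
                           stratum=(spec.axis, spec.level))
        if tab.empty:
            logger.info("stratum %s=%s is empty", spec.axis, spec.level)
            continue
        frames.append(tab)
    if not frames:
        return pd.DataFrame()
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["drug", "stratum_axis", "stratum"],
                           kind="mergesort").reset_index(drop=True)


FOREST_COLUMNS = ["drug", "event", "stratum_axis", "stratum", "n_reports",
                  "ror", "ror_lo", "ror_hi", "composite"]


def forest_export(stratified: pd.DataFrame,
                  path: str | Path | None = None) -> pd.DataFrame:
    """Plot-ready table: one row per (drug, stratum) with ROR and CI bounds.

    Missing strata are simply absent (no NaN filler rows). When ``path`` is
    given the table is also written as CSV.
    """
    if stratified.empty:
        out = pd.DataFrame(columns=FOREST_COLUMNS)
    else:
        out = stratified[FOREST_COLUMNS].copy()
        out = out.sort_values(["drug", "stratum_axis", "stratum"],
                              kind="mergesort").reset_index(drop=True)
    if path is not None:
        out.to_csv(path, index=False)
    return out
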