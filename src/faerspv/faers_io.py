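"""Reading FAERS-style quarterly bundles and case-version deduplication.

FAERS quarterly ASCII packages ship one "$"-delimited file per table with a
header line. A safety report may appear in several versions (follow-ups and
corrections) sharing a CASEID but with distinct PRIMARYIDs and receipt dates
(FDA_DT); since 2019 each package also lists CASEIDs of deleted reports.
The cleaning contract implemented here is:

1. sort by (CASEID, FDA_DT, PRIMARYID) and keep, per CASEID, the version
   with the most recent FDA_DT, breaking ties by the highest PRIMARYID;
2. after deduplication, drop every case whose CASEID appears on any
   deleted-report list.

Malformed lines (wrong field count) are never silently dropped: they are
counted per table and quarantined so they can be audited.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .synthetic_faers import BUNDLE_COLUMNS, BundleManifest

logger = logging.getLogger(__name__)

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI")
DELIMITER = "$"


@dataclass
class RawBundle:
    """Parsed tables of one bundle, before deduplication."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    deleted_ids: set[str] = field(default_factory=set)
    malformed_counts: dict[str, int] = field(default_factory=dict)
    malformed_lines: dict[str, list[str]] = field(default_factory=dict)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name.lower())


@dataclass
class CaseData:
    """Deduplicated, deletion-filtered cases with joined satellite tables.

    ``demo`` has one row per surviving report (primaryid unique); ``drugs``
    carries therapy start dates (from THER) and indications (from INDI)
    merged onto each drug row; ``reactions`` and ``outcomes`` are filtered
    to surviving primaryids. ``orphans`` counts satellite rows whose
    primaryid had no surviving DEMO row (stale versions, deleted cases).
    """

    demo: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame
    outcomes: pd.DataFrame
    orphans: dict[str, int] = field(default_factory=dict)

    @property
    def n_cases(self) -> int:
        return len(self.demo)


def _read_table(path: Path, name: str):
    """Parse one "$"-delimited table, quarantining malformed lines.

    A line is malformed when its field count differs from the header's.
    Returns (frame, n_malformed, malformed_lines).
    """
    if not path.exists():
        raise FileNotFoundError(f"{name} file missing: {path}")
    text = path.read_text()
    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{name} file {path} is empty (no header)")
    header = lines[0]
    ncols = header.count(DELIMITER) + 1
    expected = BUNDLE_COLUMNS.get(name)
    if expected is not None:
        have = [h.strip().lower() for h in header.split(DELIMITER)]
        missing = [c for c in expected if c not in have]
        if missing:
            raise ValueError(
                f"{name} header {have} lacks required columns {missing}")
    good, bad = [header], []
    for line in lines[1:]:
        if not line.strip():
            continue
        (good if line.count(DELIMITER) + 1 == ncols else bad).append(line)
    if bad:
        logger.warning("%s: %d malformed line(s) quarantined", name, len(bad))
    frame = pd.read_csv(io.StringIO("\n".join(good)), sep=DELIMITER,
                        dtype=str, keep_default_na=False, engine="c")
    frame.columns = [c.strip().lower() for c in frame.columns]
    return frame, len(bad), bad


def read_bundle(source, quarantine_dir: str | Path | None = None) -> RawBundle:
    """Read a quarterly bundle from a manifest, directory, or path mapping.

    ``source`` may be a :class:`BundleManifest`, a directory containing
    ``DEMO.txt`` ... ``INDI.txt`` and optional ``DELETED*.txt`` lists, or a
    dict mapping table names (plus ``"DELETED"``) to paths. Missing report
    tables are a hard error; a missing deleted list simply means no
    deletions. When ``quarantine_dir`` is given, malformed lines are also
    written to ``<table>.malformed.txt`` files there.
    """
    if isinstance(source, BundleManifest):
        paths = {k: Path(v) for k, v in source.paths.items()}
        deleted_paths = [paths["DELETED"]] if "DELETED" in paths else []
    elif isinstance(source, dict):
        paths = {k: Path(v) for k, v in source.items()}
        deleted_paths = [paths[k] for k in paths if k.upper().startswith("DELETED")]
    else:
        root = Path(source)
        if not root.is_dir():
            raise FileNotFoundError(f"bundle directory not found: {root}")
        paths = {name: root / f"{name}.txt" for name in TABLE_NAMES}
        deleted_paths = sorted(root.glob("DELETED*.txt"))

    frames: dict[str, pd.DataFrame] = {}
    counts: dict[str, int] = {}
    quarantine: dict[str, list[str]] = {}
    for name in TABLE_NAMES:
        frame, n_bad, bad = _read_table(paths[name], name)
        frames[name] = frame
        counts[name] = n_bad
        if bad:
            quarantine[name] = bad
    if quarantine_dir is not None:
        qdir = Path(quarantine_dir)
        qdir.mkdir(parents=True, exist_ok=True)
        for name, bad in quarantine.items():
            (qdir / f"{name}.malformed.txt").write_text("\n".join(bad) + "\n")

    deleted: set[str] = set()
    for p in deleted_paths:
        deleted.update(line.strip() for line in Path(p).read_text().splitlines()
                       if line.strip())

    return RawBundle(
        demo=frames["DEMO"], drug=frames["DRUG"], reac=frames["REAC"],
        outc=frames["OUTC"], ther=frames["THER"], indi=frames["INDI"],
        deleted_ids=deleted, malformed_counts=counts,
        malformed_lines=quarantine,
    )


def _order_key(series: pd.Series) -> pd.Series:
    """Numeric ordering when every value parses as a number, else as-is.

    FAERS identifiers are numeric but stored as strings; comparing them
    lexicographically would rank "9" above "10".
    """
    numeric = pd.to_numeric(series, errors="coerce")
    return numeric if not numeric.isna().any() else series


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """One row per CASEID: latest FDA_DT, ties broken by highest PRIMARYID.

    Rows are sorted by (caseid, fda_dt, primaryid) ascending and the last
    row of each caseid group is kept; output is sorted by caseid. Empty
    input passes through unchanged.
    """
    if demo.empty:
        return demo.copy()
    work = demo.copy()
    work["_case"] = _order_key(work["caseid"])
    work["_fda"] = pd.to_numeric(work["fda_dt"], errors="coerce")
    work["_pid"] = _order_key(work["primaryid"])
    work = work.sort_values(["_case", "_fda", "_pid"], kind="mergesort")
    out = work.groupby("_case", sort=True).tail(1)
    return out.drop(columns=["_case", "_fda", "_pid"]).reset_index(drop=True)


def remove_deleted(demo: pd.DataFrame, deleted_ids: set[str]) -> pd.DataFrame:
    """Drop rows whose caseid is on a deleted-report list.

    Applied after deduplication. Listed ids that match no row are logged
    and ignored.
    """
    if not deleted_ids or demo.empty:
        return demo.copy()
    deleted = {str(x) for x in deleted_ids}
    mask = demo["caseid"].astype(str).isin(deleted)
    missing = deleted - set(demo.loc[mask, "caseid"].astype(str))
    if missing:
        logger.info("%d deleted id(s) not present in DEMO", len(missing))
    return demo.loc[~mask].reset_index(drop=True)


def assemble_cases(demo: pd.DataFrame, drug: pd.DataFrame, reac: pd.DataFrame,
                   outc: pd.DataFrame, ther: pd.DataFrame | None = None,
                   indi: pd.DataFrame | None = None) -> CaseData:
    """Join satellite tables onto the surviving DEMO rows by primaryid.

    ``demo`` must already be deduplicated and deletion-filtered. Therapy
    start dates are merged onto drug rows by (primaryid, drug_seq) from
    THER, indications likewise from INDI. Satellite rows referencing a
    primaryid with no surviving DEMO row are dropped and counted per table.
    """
    alive = set(demo["primaryid"].astype(str))
    orphans: dict[str, int] = {}

    def _filter(frame: pd.DataFrame, name: str) -> pd.DataFrame:
        mask = frame["primaryid"].astype(str).isin(alive)
        orphans[name] = int((~mask).sum())
        return frame.loc[mask].reset_index(drop=True)

    drugs = _filter(drug, "DRUG").copy()
    if "drug_seq" not in drugs.columns:
        drugs["drug_seq"] = "1"
    if ther is not None and not ther.empty:
        t = ther.rename(columns={"dsg_drug_seq": "drug_seq"})
        t = t[["primaryid", "drug_seq", "start_dt"]].drop_duplicates(
            ["primaryid", "drug_seq"])
        drugs = drugs.merge(t, on=["primaryid", "drug_seq"], how="left")
    if "start_dt" not in drugs.columns:
        drugs["start_dt"] = ""
    if indi is not None and not indi.empty:
        i = indi.rename(columns={"indi_drug_seq": "drug_seq",
                                 "indi_pt": "indication"})
        i = i[["primaryid", "drug_seq", "indication"]].drop_duplicates(
            ["primaryid", "drug_seq"])
        drugs = drugs.merge(i, on=["primaryid", "drug_seq"], how="left")
    if "indication" not in drugs.columns:
        drugs["indication"] = ""
    drugs[["start_dt", "indication"]] = drugs[["start_dt", "indication"]].fillna("")

    return CaseData(
        demo=demo.reset_index(drop=True),
        drugs=drugs,
        reactions=_filter(reac, "REAC"),
        outcomes=_filter(outc, "OUTC"),
        orphans=orphans,
    )


def load_cases(source, quarantine_dir=None) -> tuple[CaseData, dict[str, int]]:
    """read -> deduplicate -> remove deleted -> assemble, with attrition.

    Returns the assembled :class:`CaseData` and an attrition record of row
    counts after each cleaning step.
    """
    raw = read_bundle(source, quarantine_dir=quarantine_dir)
    attrition = {"demo_rows_raw": len(raw.demo)}
    demo = deduplicate(raw.demo)
    attrition["cases_after_dedup"] = len(demo)
    demo = remove_deleted(demo, raw.deleted_ids)
    attrition["cases_after_deletion"] = len(demo)
    cases = assemble_cases(demo, raw.drug, raw.reac, raw.outc, raw.ther, raw.indi)
    attrition["orphan_rows_dropped"] = sum(cases.orphans.values())
    return cases, attrition
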