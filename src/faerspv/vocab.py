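"""Drug dictionary (name -> ATC) and MedDRA-style hierarchy queries.

MedDRA itself is licensed and cannot be redistributed, so this module
consumes user-supplied tab-delimited tables: ``drug_dict.tsv`` with columns
(name, ingredient, atc) and ``meddra.tsv`` with columns
(pt_code, pt_name, hlt, hlgt_code, hlgt_name, soc_code, soc_name).
The synthetic generator ships a mock hierarchy in the same format.

Drug-name matching is exact after normalization (case-fold, trim, collapse
internal whitespace); there is no fuzzy matching — unmapped names are
returned as an explicit :data:`UNMAPPED` marker and counted, so they can be
curated by hand rather than silently guessed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


class _Unmapped:
    """Sentinel for names/terms absent from the vocabularies."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNMAPPED"

    def __bool__(self) -> bool:
        raise TypeError("UNMAPPED is neither True nor False; test identity instead")


UNMAPPED = _Unmapped()

# Psychiatric disorders SOC and the three focus HLGTs, by MedDRA code.
PSYCHIATRIC_SOC_CODE = 10037175
FOCUS_HLGT_CODES = {
    10002861: "Anxiety disorders and symptoms",
    10012375: "Depressed mood disorders and disturbances",
    10042460: "Suicidal and self-injurious behaviours",
}

_WS = re.compile(r"\s+")


def normalize_drug_name(name: str) -> str:
    """Case-fold, strip and collapse whitespace."""
    return _WS.sub(" ", str(name).strip()).casefold()


@dataclass
class DrugDictionary:
    """Mapping from normalized drug-name strings to (ingredient, ATC).

    Combination products carry several ATC codes separated by ``;`` in the
    atc field; a product counts as respiratory if ANY component code begins
    with "R".
    """

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def add(self, name: str, ingredient: str, atc: str) -> None:
        self.entries[normalize_drug_name(name)] = (ingredient, atc)

    def lookup(self, name: str):
        """Return (ingredient, atc) or the UNMAPPED marker."""
        return self.entries.get(normalize_drug_name(name), UNMAPPED)

    def is_respiratory(self, name: str):
        """True iff any component ATC code begins with "R".

        Unmapped names return :data:`UNMAPPED` (neither True nor False) so
        that callers must count them explicitly.
        """
        hit = self.lookup(name)
        if hit is UNMAPPED:
            return UNMAPPED
        _, atc = hit
        return any(code.strip().upper().startswith("R")
                   for code in str(atc).split(";") if code.strip())

    def to_tsv(self, path: str | Path) -> None:
        rows = [(name, ing, atc) for name, (ing, atc) in sorted(self.entries.items())]
        pd.DataFrame(rows, columns=["name", "ingredient", "atc"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DrugDictionary":
        df = pd.read_csv(path, sep="\t", dtype=str)
        d = cls()
        for row in df.itertuples(index=False):
            d.add(row.name, row.ingredient, row.atc)
        return d


@dataclass
class MeddraHierarchy:
    """PT -> HLT -> HLGT -> SOC rollup with single-parent primary paths."""

    table: pd.DataFrame  # columns: pt_code, pt_name, hlt, hlgt_code, hlgt_name, soc_code, soc_name

    REQUIRED = ["pt_code", "pt_name", "hlt", "hlgt_code", "hlgt_name",
                "soc_code", "soc_name"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"hierarchy table missing columns: {missing}")
        self._validate()
        t = self.table
        self._by_pt = {
            str(r.pt_name): r for r in t.itertuples(index=False)
        }

    def _validate(self) -> None:
        """Single-parent property: each PT one HLT, each HLT one HLGT, each
        HLGT one SOC. Level-wise uniqueness also rules out cycles, since a
        term name may appear at only one level."""
        t = self.table
        if t["pt_name"].duplicated().any():
            dup = t.loc[t["pt_name"].duplicated(), "pt_name"].iloc[0]
            raise ValueError(f"PT {dup!r} has more than one primary path")
        for child, parent in (("hlt", "hlgt_name"), ("hlgt_name", "soc_name")):
            n_parents = t.groupby(child)[parent].nunique()
            bad = n_parents[n_parents > 1]
            if len(bad):
                raise ValueError(
                    f"{child} {bad.index[0]!r} maps to multiple {parent} values")
        levels = [set(t["pt_name"]), set(t["hlt"]),
                  set(t["hlgt_name"]), set(t["soc_name"])]
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                shared = levels[i] & levels[j]
                if shared:
                    raise ValueError(
                        f"term {next(iter(shared))!r} appears at two levels")

    def classify_pt(self, pt_name: str):
        """Return (soc_name, focus_hlgt_name or None) for a PT.

        PTs under the psychiatric SOC but outside the three focus HLGTs get
        focus = None; PTs absent from the hierarchy return UNMAPPED.
        """
        row = self._by_pt.get(str(pt_name))
        if row is None:
            return UNMAPPED
        focus = FOCUS_HLGT_CODES.get(int(row.hlgt_code))
        return (str(row.soc_name), focus)

    def soc_of(self, pt_name: str):
        row = self._by_pt.get(str(pt_name))
        return UNMAPPED if row is None else str(row.soc_name)

    def is_psychiatric(self, pt_name: str):
        row = self._by_pt.get(str(pt_name))
        return UNMAPPED if row is None else int(row.soc_code) == PSYCHIATRIC_SOC_CODE

    def pt_frame(self) -> pd.DataFrame:
        """PT-level lookup frame (one row per PT) for vectorized joins."""
        t = self.table.copy()
        t["is_psychiatric"] = t["soc_code"].astype(int) == PSYCHIATRIC_SOC_CODE
        t["focus_hlgt"] = t["hlgt_code"].astype(int).map(FOCUS_HLGT_CODES)
        return t

    def to_tsv(self, path: str | Path) -> None:
        self.table[self.REQUIRED].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MeddraHierarchy":
        df = pd.read_csv(path, sep="\t", dtype={"pt_name": str, "hlt": str,
                                                "hlgt_name": str, "soc_name": str})
        return cls(df)


@dataclass
class VocabularyBundle:
    """A drug dictionary together with a hierarchy table."""

    drugs: DrugDictionary
    hierarchy: MeddraHierarchy

    def write(self, drug_path: str | Path, meddra_path: str | Path) -> None:
        self.drugs.to_tsv(drug_path)
        self.hierarchy.to_tsv(meddra_path)

    @classmethod
    def read(cls, drug_path: str | Path, meddra_path: str | Path) -> "VocabularyBundle":
        return cls(DrugDictionary.from_tsv(drug_path),
                   MeddraHierarchy.from_tsv(meddra_path))
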