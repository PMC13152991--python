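"""Bundle parsing, case-version deduplication and deleted-report removal."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv.faers_io import (assemble_cases, deduplicate, load_cases,
                              read_bundle, remove_deleted)


def demo_frame(rows):
    """rows: (primaryid, caseid, fda_dt) triples."""
    return pd.DataFrame(rows, columns=["primaryid", "caseid", "fda_dt"]).astype(str)


class TestDeduplicate:
    def test_most_recent_fda_dt_wins(self):
        demo = demo_frame([("10", "X", "20200101"), ("9", "X", "20200301")])
        out = deduplicate(demo)
        assert list(out["primaryid"]) == ["9"]

    def test_primaryid_breaks_fda_dt_ties(self):
        demo = demo_frame([("10", "X", "20200101"), ("11", "X", "20200101")])
        out = deduplicate(demo)
        assert list(out["primaryid"]) == ["11"]

    def test_single_version_kept_unchanged(self):
        demo = demo_frame([("7", "Y", "20210505")])
        out = deduplicate(demo)
        pd.testing.assert_frame_equal(out, demo)

    def test_empty_in_empty_out(self):
        demo = demo_frame([])
        assert deduplicate(demo).empty

    def test_primaryid_comparison_is_numeric(self):
        # lexicographically "9" > "10"; numerically 10 > 9
        demo = demo_frame([("9", "X", "20200101"), ("10", "X", "20200101")])
        assert list(deduplicate(demo)["primaryid"]) == ["10"]

    def test_idempotence(self):
        demo = demo_frame([("1", "A", "20200101"), ("2", "A", "20200201"),
                           ("3", "B", "20190101"), ("4", "C", "20180101"),
                           ("5", "C", "20180101")])
        once = deduplicate(demo)
        twice = deduplicate(once)
        pd.testing.assert_frame_equal(once, twice)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(
        st.tuples(st.integers(1, 8),          # caseid
                  st.integers(20190101, 20190120),  # fda_dt
                  st.integers(1, 500)),       # primaryid
        min_size=0, max_size=30, unique_by=lambda t: t[2]))
    def test_matches_brute_force_oracle(self, rows):
        """Group by caseid, keep lexicographic max on (fda_dt, primaryid)."""
        demo = demo_frame([(str(p), f"C{c}", str(f)) for c, f, p in rows])
        got = set(deduplicate(demo)["primaryid"])
        expected = set()
        by_case = {}
        for c, f, p in rows:
            by_case.setdefault(c, []).append((f, p))
        for c, versions in by_case.items():
            expected.add(str(max(versions)[1]))
        assert got == expected

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 5), st.integers(1, 9),
                              st.integers(1, 300)),
                    min_size=1, max_size=20, unique_by=lambda t: t[2]))
    def test_count_conservation(self, rows):
        demo = demo_frame([(str(p), f"C{c}", f"2020010{f}") for c, f, p in rows])
        out = deduplicate(demo)
        n_cases = demo["caseid"].nunique()
        assert len(out) == n_cases
        assert len(demo) - len(out) == len(demo) - n_cases  # versions removed


class TestRemoveDeleted:
    def test_empty_set_is_identity(self):
        demo = demo_frame([("1", "A", "20200101")])
        pd.testing.assert_frame_equal(remove_deleted(demo, set()), demo)

    def test_listed_cases_removed(self):
        demo = demo_frame([(str(i), f"C{i}", "20200101") for i in range(100)])
        deleted = {f"C{i}" for i in range(7)}
        out = remove_deleted(demo, deleted)
        assert len(out) == 93
        assert not set(out["caseid"]) & deleted

    def test_absent_id_is_noop(self):
        demo = demo_frame([("1", "A", "20200101")])
        out = remove_deleted(demo, {"ZZZ"})
        assert list(out["caseid"]) == ["A"]


class TestReadBundle:
    def test_roundtrip_counts(self, small_bundle, small_config):
        raw = read_bundle(small_bundle)
        # every case appears once plus one row per duplicate version
        assert raw.demo["caseid"].nunique() == small_config.n_cases
        assert len(raw.demo) > small_config.n_cases  # duplicates present
        assert sum(raw.malformed_counts.values()) == 0
        assert len(raw.deleted_ids) == small_bundle.n_deleted_cases

    def test_no_duplicates_no_deletions_exact_rows(self, tmp_path):
        from faerspv.synthetic_faers import SyntheticConfig, generate_bundle
        cfg = SyntheticConfig(n_cases=100, duplicate_rate=0.0,
                              deletion_rate=0.0, seed=5)
        manifest = generate_bundle(cfg, tmp_path)
        raw = read_bundle(manifest)
        assert len(raw.demo) == 100
        assert raw.deleted_ids == set()

    def test_empty_reac_table(self, tmp_path):
        for name in ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI"):
            header = {
                "DEMO": "primaryid$caseid$fda_dt$age$age_cod$sex$occp_cod$reporter_country$event_dt",
                "DRUG": "primaryid$drug_seq$drugname$role_cod$route",
                "REAC": "primaryid$pt",
                "OUTC": "primaryid$outc_cod",
                "THER": "primaryid$dsg_drug_seq$start_dt",
                "INDI": "primaryid$indi_drug_seq$indi_pt",
            }[name]
            (tmp_path / f"{name}.txt").write_text(header + "\n")
        raw = read_bundle(tmp_path)
        assert raw.reac.empty
        assert raw.malformed_counts["REAC"] == 0

    def test_malformed_line_counted_not_dropped_silently(self, tmp_path):
        (tmp_path / "REAC.txt").write_text(
            "primaryid$pt\n1$Anxiety\n2$Nausea$EXTRA$FIELDS\n3$Rash\n")
        for name, header in (("DEMO", "primaryid$caseid$fda_dt$age$age_cod$sex$occp_cod$reporter_country$event_dt"),
                             ("DRUG", "primaryid$drug_seq$drugname$role_cod$route"),
                             ("OUTC", "primaryid$outc_cod"),
                             ("THER", "primaryid$dsg_drug_seq$start_dt"),
                             ("INDI", "primaryid$indi_drug_seq$indi_pt")):
            (tmp_path / f"{name}.txt").write_text(header + "\n")
        raw = read_bundle(tmp_path, quarantine_dir=tmp_path / "q")
        assert raw.malformed_counts["REAC"] == 1
        assert len(raw.reac) == 2
        assert (tmp_path / "q" / "REAC.malformed.txt").exists()

    def test_missing_file_is_hard_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_bundle(tmp_path / "nowhere")

    def test_bad_header_is_hard_error(self, tmp_path, small_bundle):
        import shutil
        for p in small_bundle.out_dir.glob("*.txt"):
            shutil.copy(p, tmp_path / p.name)
        (tmp_path / "DEMO.txt").write_text("foo$bar\n1$2\n")
        with pytest.raises(ValueError, match="lacks required columns"):
            read_bundle(tmp_path)


class TestAssemble:
    def test_join_multiplicities(self):
        demo = pd.DataFrame({"primaryid": ["1"], "caseid": ["A"],
                             "fda_dt": ["20200101"]})
        drug = pd.DataFrame({"primaryid": ["1", "1"], "drug_seq": ["1", "2"],
                             "drugname": ["X", "Y"], "role_cod": ["PS", "SS"],
                             "route": ["Oral", ""]})
        reac = pd.DataFrame({"primaryid": ["1"] * 3,
                             "pt": ["Anxiety", "Nausea", "Rash"]})
        outc = pd.DataFrame({"primaryid": [], "outc_cod": []}, dtype=str)
        cd = assemble_cases(demo, drug, reac, outc)
        assert len(cd.drugs) == 2
        assert len(cd.reactions) == 3
        assert cd.orphans == {"DRUG": 0, "REAC": 0, "OUTC": 0}

    def test_orphan_rows_dropped_and_counted(self):
        demo = pd.DataFrame({"primaryid": ["1"], "caseid": ["A"],
                             "fda_dt": ["20200101"]})
        drug = pd.DataFrame({"primaryid": ["1"], "drug_seq": ["1"],
                             "drugname": ["X"], "role_cod": ["PS"],
                             "route": [""]})
        reac = pd.DataFrame({"primaryid": ["1", "99"],
                             "pt": ["Anxiety", "Ghost"]})
        outc = pd.DataFrame({"primaryid": [], "outc_cod": []}, dtype=str)
        cd = assemble_cases(demo, drug, reac, outc)
        assert cd.orphans["REAC"] == 1
        assert list(cd.reactions["pt"]) == ["Anxiety"]

    def test_therapy_and_indication_joined(self, small_bundle):
        cases, attrition = load_cases(small_bundle)
        assert {"start_dt", "indication"} <= set(cases.drugs.columns)
        assert attrition["cases_after_dedup"] <= attrition["demo_rows_raw"]
        assert attrition["cases_after_deletion"] <= attrition["cases_after_dedup"]
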