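"""Unit and property tests for FAERS table parsing, deduplication, deletion
filtering, case assembly and the target/background split."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from pvsignal._dates import FaersDate, parse_faers_date
from pvsignal.ingest import (
    DictionaryTables,
    ParseError,
    RawRecordSet,
    assemble_cases,
    deduplicate,
    parse_table,
    read_cases,
    remove_deleted,
    select_target_population,
    write_cases,
)


def _demo(rows):
    return RawRecordSet("DEMO", "2020Q1", rows)


def _demo_row(caseid, fda_dt, primaryid, **extra):
    return {"caseid": str(caseid), "fda_dt": str(fda_dt),
            "primaryid": str(primaryid), **extra}


class TestParsing:
    def test_row_count_and_field_split(self):
        text = "primaryid$caseid$fda_dt$sex\n1001$100$20200101$F\n1002$101$20200102$M\n1003$102$20200103$\n"
        rs = parse_table(io.StringIO(text), "DEMO", "2020Q1")
        assert len(rs) == 3
        assert rs.rows[0] == {"primaryid": "1001", "caseid": "100",
                              "fda_dt": "20200101", "sex": "F"}

    def test_unknown_columns_preserved(self):
        text = "primaryid$mystery_col\n1$x\n"
        rs = parse_table(io.StringIO(text), "REAC")
        assert rs.rows[0]["mystery_col"] == "x"

    def test_missing_primaryid_header_rejected(self):
        with pytest.raises(ParseError, match="PRIMARYID"):
            parse_table(io.StringIO("caseid$fda_dt\n100$20200101\n"), "DEMO")

    def test_malformed_line_names_line_number(self):
        text = "primaryid$caseid\n1$100\n2$200$extra\n"
        with pytest.raises(ParseError, match="line 3"):
            parse_table(io.StringIO(text), "DEMO")

    def test_partial_dates_parse_but_are_incomplete(self):
        assert parse_faers_date("20200115").complete
        assert not parse_faers_date("202001").complete
        assert not parse_faers_date("2020").complete
        with pytest.raises(ValueError):
            parse_faers_date("2020013")


class TestDeduplicate:
    def test_latest_fda_dt_retained(self):
        res = deduplicate(_demo([
            _demo_row(100, 20200101, 1001),
            _demo_row(100, 20200301, 1002),
        ]))
        assert [r["primaryid"] for r in res.kept.rows] == ["1002"]
        assert res.n_removed == 1

    def test_largest_primaryid_breaks_date_ties(self):
        res = deduplicate(_demo([
            _demo_row(100, 20200301, 1002),
            _demo_row(100, 20200301, 1005),
        ]))
        assert [r["primaryid"] for r in res.kept.rows] == ["1005"]

    def test_unparseable_fda_dt_quarantined(self):
        res = deduplicate(_demo([
            _demo_row(100, "NOTADATE", 1001),
            _demo_row(101, 20200101, 1002),
        ]))
        assert len(res.kept.rows) == 1
        assert res.rejects[0]["_reject_reason"] == "unparseable_fda_dt"

    def test_missing_caseid_quarantined(self):
        res = deduplicate(_demo([{"caseid": "", "fda_dt": "20200101",
                                  "primaryid": "1"}]))
        assert not res.kept.rows and len(res.rejects) == 1

    @settings(deadline=None, max_examples=50)
    @given(
        rows=st.lists(
            st.tuples(st.integers(100, 103), st.integers(1, 28),
                      st.integers(1000, 9999)),
            min_size=1, max_size=20,
        )
    )
    def test_matches_sort_then_keep_last_oracle(self, rows):
        """Retained PRIMARYIDs equal an independent sort-then-keep-last pass."""
        demo = _demo([_demo_row(c, 20200100 + d, p) for c, d, p in rows])
        kept = {r["primaryid"] for r in deduplicate(demo).kept.rows}
        # oracle: stable sort by (caseid, fda_dt, numeric primaryid), last wins
        last = {}
        for c, d, p in sorted(rows, key=lambda r: (r[0], r[1], r[2])):
            last[c] = str(p)
        assert kept == set(last.values())

    def test_idempotence(self):
        demo = _demo([
            _demo_row(100, 20200101, 1001), _demo_row(100, 20200301, 1002),
            _demo_row(101, 20200102, 1003), _demo_row(102, 20200102, 1004),
        ])
        once = deduplicate(demo).kept
        twice = deduplicate(once).kept
        assert once.rows == twice.rows

    def test_distinct_caseid_count(self):
        # 10 rows over 4 caseids -> 4 retained
        rows = [_demo_row(100 + i % 4, 20200101 + i, 2000 + i) for i in range(10)]
        assert len(deduplicate(_demo(rows)).kept.rows) == 4


class TestRemoveDeleted:
    def test_matching_rows_removed(self):
        demo = _demo([_demo_row(100 + i, 20200101, 1000 + i) for i in range(5)])
        kept, n = remove_deleted(demo, ["100"])
        assert n == 1 and len(kept.rows) == 4

    def test_no_match_is_identity(self):
        demo = _demo([_demo_row(1, 20200101, 10)])
        kept, n = remove_deleted(demo, ["999"])
        assert n == 0 and kept.rows == demo.rows

    def test_total_deletion_yields_empty_set(self):
        demo = _demo([_demo_row(1, 20200101, 10), _demo_row(2, 20200101, 11)])
        kept, n = remove_deleted(demo, ["1", "2"])
        assert n == 2 and kept.rows == []


@pytest.fixture()
def tiny_dict():
    return DictionaryTables(
        pt_to_soc={"stomatitis": "gastrointestinal disorders"},
        drug_synonyms={"folotyn": "pralatrexate"},
    )


class TestAssembleCases:
    def _tables(self, demo_rows, drug_rows=(), reac_rows=(), outc_rows=(), ther_rows=()):
        return {
            "DEMO": RawRecordSet("DEMO", "", list(demo_rows)),
            "DRUG": RawRecordSet("DRUG", "", list(drug_rows)),
            "REAC": RawRecordSet("REAC", "", list(reac_rows)),
            "OUTC": RawRecordSet("OUTC", "", list(outc_rows)),
            "THER": RawRecordSet("THER", "", list(ther_rows)),
        }

    def test_synonym_mapping_and_roles(self, tiny_dict):
        tables = self._tables(
            [_demo_row(100, 20200101, 1001)],
            drug_rows=[{"primaryid": "1001", "drug_seq": "1", "role_cod": "PS",
                        "drugname": "FOLOTYN"}],
        )
        reports, log = assemble_cases(tables, tiny_dict)
        assert reports[0].drugs[0].name == "pralatrexate"
        assert reports[0].drugs[0].role == "PS"
        assert log["unmapped_drug_name"] == 0

    def test_unmapped_drug_kept_verbatim_and_flagged(self, tiny_dict):
        tables = self._tables(
            [_demo_row(100, 20200101, 1001)],
            drug_rows=[{"primaryid": "1001", "drug_seq": "1", "role_cod": "PS",
                        "drugname": "Mystery Compound"}],
        )
        reports, log = assemble_cases(tables, tiny_dict)
        assert reports[0].drugs[0].name == "mystery compound"
        assert not reports[0].drugs[0].mapped
        assert log["unmapped_drug_name"] == 1

    @pytest.mark.parametrize(
        "age,cod,years,group",
        [
            ("72", "YR", 72.0, ">=65"),
            ("6", "DEC", 60.0, "45-64"),
            ("24", "MON", 2.0, "<18"),
            ("30", "XX", None, "unknown"),
            ("", "YR", None, "unknown"),
        ],
    )
    def test_age_unit_conversion(self, tiny_dict, age, cod, years, group):
        tables = self._tables([_demo_row(100, 20200101, 1001, age=age, age_cod=cod)])
        reports, _ = assemble_cases(tables, tiny_dict)
        assert reports[0].age_years == pytest.approx(years) if years else reports[0].age_years is None
        assert reports[0].age_group == group

    def test_orphan_rows_counted_and_excluded(self, tiny_dict):
        tables = self._tables(
            [_demo_row(100, 20200101, 1001)],
            reac_rows=[{"primaryid": "1001", "pt": "Stomatitis"},
                       {"primaryid": "9999", "pt": "nausea"}],
        )
        reports, log = assemble_cases(tables, tiny_dict)
        assert reports[0].events == ("stomatitis",)
        assert log["orphan_REAC"] == 1

    def test_repeated_pt_collapsed(self, tiny_dict):
        tables = self._tables(
            [_demo_row(100, 20200101, 1001)],
            reac_rows=[{"primaryid": "1001", "pt": "stomatitis"},
                       {"primaryid": "1001", "pt": "STOMATITIS"}],
        )
        reports, _ = assemble_cases(tables, tiny_dict)
        assert reports[0].events == ("stomatitis",)

    def test_seriousness_from_outcome_codes(self, tiny_dict):
        tables = self._tables(
            [_demo_row(100, 20200101, 1001), _demo_row(101, 20200101, 1002)],
            outc_rows=[{"primaryid": "1001", "outc_cod": "HO"},
                       {"primaryid": "1002", "outc_cod": "OT"}],
        )
        reports, _ = assemble_cases(tables, tiny_dict)
        assert reports[0].serious and not reports[1].serious

    def test_therapy_start_earliest_ps_row(self, tiny_dict):
        tables = self._tables(
            [_demo_row(100, 20200101, 1001)],
            drug_rows=[{"primaryid": "1001", "drug_seq": "1", "role_cod": "PS",
                        "drugname": "FOLOTYN"}],
            ther_rows=[
                {"primaryid": "1001", "dsg_drug_seq": "1", "start_dt": "20191215"},
                {"primaryid": "1001", "dsg_drug_seq": "1", "start_dt": "20191201"},
            ],
        )
        reports, _ = assemble_cases(tables, tiny_dict)
        assert reports[0].therapy_start == FaersDate(2019, 12, 1)


class TestTargetSelection:
    def test_partition_is_exhaustive_and_disjoint(self, demo_populations):
        target, background, counts = demo_populations
        assert len(target) + len(background) == counts["cases_after_deletion"]
        assert {r.primaryid for r in target}.isdisjoint(
            r.primaryid for r in background
        )

    def test_concomitant_only_goes_to_background(self, tiny_dict):
        from pvsignal.ingest import DrugEntry, Report

        r = Report(
            primaryid="1", caseid="1", fda_dt=None, sex="unknown",
            age_years=None, age_group="unknown", country="", reporter="unknown",
            report_year=None, outcomes=frozenset(),
            drugs=(DrugEntry("pralatrexate", "C"), DrugEntry("romidepsin", "PS")),
        )
        target, background = select_target_population([r], "pralatrexate")
        assert not target and background == [r]

    def test_empty_input(self):
        assert select_target_population([], "x") == ([], [])


class TestRoundTrip:
    def test_case_set_export_reimports_identically(self, demo_populations):
        target, _, _ = demo_populations
        buf = io.StringIO()
        write_cases(target, buf)
        buf.seek(0)
        assert read_cases(buf) == target

    def test_printed_fixture_round_trip(self, printed_case_set):
        buf = io.StringIO()
        write_cases(printed_case_set, buf)
        buf.seek(0)
        assert read_cases(buf) == printed_case_set
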