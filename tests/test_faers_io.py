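"""Ingest: parsing, drug normalisation, PT→SOC mapping, deduplication, assembly."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from faerspv.faers_io import (
    UNMAPPED, UNKNOWN_PT, MedDRAHierarchy, UnknownPTError,
    age_to_years, assemble_case_reports, deduplicate, map_pt_to_soc,
    normalize_drug_name, read_quarter,
)

from conftest import write_quarter


# ---------------------------------------------------------------- parsing

def test_read_quarter_preserves_row_counts(tmp_path):
    """Fixture with 3 demo / 4 drug / 5 reac rows parses to those counts."""
    q = write_quarter(
        tmp_path / "q",
        demo=[("11", "1", "1", "20150101", "F", "45", "YR", "US"),
              ("21", "2", "1", "20150202", "M", "", "", ""),
              ("31", "3", "1", "20150303", "", "30", "YR", "JP")],
        drug=[("11", "1", "1", "PS", "CYCLOSPORINE"),
              ("11", "1", "2", "C", "ASPIRIN"),
              ("21", "2", "1", "PS", "TACROLIMUS"),
              ("31", "3", "1", "PS", "PREDNISONE")],
        reac=[("11", "1", "Headache"), ("11", "1", "Nausea"), ("21", "2", "Tremor"),
              ("31", "3", "Rash"), ("31", "3", "Headache")],
        outc=[("11", "1", "HO")],
    )
    raw = read_quarter(q)
    assert (len(raw.demo_rows), len(raw.drug_rows), len(raw.reac_rows)) == (3, 4, 5)
    assert raw.malformed == {"DEMO": 0, "DRUG": 0, "REAC": 0, "OUTC": 0}


def test_read_quarter_header_only_files(tmp_path):
    raw = read_quarter(write_quarter(tmp_path / "q"))
    assert len(raw.demo_rows) == 0


def test_missing_mandatory_file_is_named(tmp_path):
    q = write_quarter(tmp_path / "q")
    (q / "REAC.txt").unlink()
    with pytest.raises(FileNotFoundError, match="REAC"):
        read_quarter(q)


def test_malformed_rows_counted_not_dropped_silently(tmp_path):
    q = write_quarter(tmp_path / "q",
                      demo=[("11", "1", "1", "20150101", "F", "45", "YR", "US")])
    with (q / "DEMO.txt").open("a") as fh:
        fh.write("21$2$1$20150101$M$30$YR$US$EXTRA$FIELDS\n")
    raw = read_quarter(q)
    assert raw.malformed["DEMO"] == 1
    assert len(raw.demo_rows) == 1


def test_orphan_rows_rejected(tmp_path):
    q = write_quarter(tmp_path / "q",
                      demo=[("11", "1", "1", "20150101", "F", "45", "YR", "US")],
                      reac=[("99", "99", "Headache")])
    with pytest.raises(ValueError, match="REAC"):
        read_quarter(q)


# ------------------------------------------------------- unit conversions

@pytest.mark.parametrize(
    "age,unit,expected",
    [
        ("45", "MON", 3.75),
        ("45", "YR", 45.0),
        ("45", "", 45.0),          # missing unit, age present -> years
        ("2", "WK", 2 / 52.18),
        ("12", "DY", 12 / 365.25),
        ("1", "HR", 1 / 8766),
        ("", "YR", math.nan),
        ("45", "DEC", math.nan),   # unrecognised unit -> missing
        ("-3", "YR", math.nan),
    ],
)
def test_age_to_years(age, unit, expected):
    got = age_to_years(age, unit)
    if math.isnan(expected):
        assert math.isnan(got)
    else:
        assert got == pytest.approx(expected)


@pytest.mark.parametrize(
    "verbatim,expected",
    [
        ("CYCLOSPORINE.", "C1"),       # edge punctuation stripped
        (" neoral ", "C1"),            # case-insensitive after trimming
        ("CYCLOSPORINE   A", "C2"),    # internal whitespace collapsed
        ("XYZZY", UNMAPPED),
    ],
)
def test_normalize_drug_name(verbatim, expected):
    mapping = {"CYCLOSPORINE": "C1", "NEORAL": "C1", "CYCLOSPORINE A": "C2"}
    assert normalize_drug_name(verbatim, mapping) == expected


# ---------------------------------------------------------- PT -> SOC map

def test_scleral_hyperaemia_maps_to_eye_disorders(hierarchy):
    code = hierarchy.pt_code_of("Scleral hyperaemia")
    assert hierarchy.soc_name(map_pt_to_soc(code, hierarchy)) == "Eye disorders"


def test_single_pt_toy_hierarchy_identity():
    h = MedDRAHierarchy(
        pd.DataFrame({"pt_code": ["1"], "pt_name": ["Only event"], "soc_code": ["9"]}),
        pd.DataFrame({"soc_code": ["9"], "soc_name": ["Only class"]}),
    )
    assert map_pt_to_soc("1", h) == "9"


def test_every_pt_maps_into_soc_terms(hierarchy):
    socs = set(hierarchy.soc_terms["soc_code"])
    for code in hierarchy.pt_terms["pt_code"]:
        assert map_pt_to_soc(code, hierarchy) in socs


def test_unknown_pt_raises_with_code(hierarchy):
    with pytest.raises(UnknownPTError, match="nonexistent"):
        map_pt_to_soc("nonexistent", hierarchy)


# ----------------------------------------------------------- deduplicate

def _demo_frame(rows):
    frame = pd.DataFrame(rows, columns=["caseid", "caseversion", "fda_dt", "file_order"])
    frame["receipt_date"] = pd.to_datetime(frame["fda_dt"], format="%Y%m%d", errors="coerce")
    return frame


def test_deduplicate_unique_ids_is_identity():
    frame = _demo_frame([("1", "1", "20150101", 0), ("2", "1", "20150202", 0)])
    pd.testing.assert_frame_equal(deduplicate(frame), frame)


def test_deduplicate_keeps_latest_receipt_date():
    frame = _demo_frame([("100", "1", "20140101", 0), ("100", "2", "20150601", 0)])
    out = deduplicate(frame)
    assert list(out["fda_dt"]) == ["20150601"]


@pytest.mark.parametrize(
    "rows,expected_version",
    [
        # same date: larger version wins
        ([("7", "1", "20150101", 0), ("7", "3", "20150101", 0), ("7", "2", "20150101", 0)], "3"),
        # same date and version: later file order wins
        ([("7", "1", "20150101", 0), ("7", "1", "20150101", 2), ("7", "1", "20150101", 1)], "2"),
        # missing date sorts before any real date
        ([("7", "9", "", 0), ("7", "1", "20100101", 0)], "1"),
    ],
)
def test_deduplicate_tie_breaks(rows, expected_version):
    out = deduplicate(_demo_frame(rows))
    assert len(out) == 1
    key = "caseversion" if rows[0][3] == rows[1][3] else "file_order"
    if key == "caseversion":
        assert out.iloc[0]["caseversion"] == expected_version
    else:
        assert str(out.iloc[0]["file_order"]) == expected_version


def test_deduplicate_groupby_oracle_and_idempotence():
    rng = np.random.default_rng(3)
    rows = [(str(rng.integers(1, 4)), str(rng.integers(1, 5)),
             f"201{rng.integers(0, 9)}0101", int(rng.integers(0, 3))) for _ in range(10)]
    frame = _demo_frame(rows)
    out = deduplicate(frame)
    assert len(out) == frame["caseid"].nunique() == 3
    pd.testing.assert_frame_equal(deduplicate(out), out)


# -------------------------------------------------------------- assembly

def test_assemble_single_complete_case(tmp_path, dictionary, hierarchy):
    q = write_quarter(
        tmp_path / "2015Q1",
        demo=[("11", "1", "1", "20150101", "F", "45", "MON", "US")],
        drug=[("11", "1", "1", "PS", "Cyclosporine.")],
        reac=[("11", "1", "Headache")],
        outc=[("11", "1", "HO"), ("11", "1", "DE")],
    )
    corpus = assemble_case_reports([read_quarter(q)], dictionary, hierarchy)
    assert corpus.n_cases == 1
    case = corpus.case_report("1")
    assert case.drugs == {("RX3008", "PS")}
    assert case.reactions == {hierarchy.pt_code_of("Headache")}
    assert case.outcomes == {"HO", "DE"}
    assert case.age_years == pytest.approx(3.75)
    assert case.gender == "female"
    assert case.country == "US"


def test_assemble_deduplicates_across_quarters(tmp_path, dictionary, hierarchy):
    q1 = write_quarter(tmp_path / "2013Q1",
                       demo=[("11", "1", "1", "20130101", "M", "", "", "")],
                       drug=[("11", "1", "1", "PS", "NEORAL")],
                       reac=[("11", "1", "Tremor")])
    q2 = write_quarter(tmp_path / "2014Q2",
                       demo=[("12", "1", "2", "20140501", "M", "", "", "")],
                       drug=[("12", "1", "1", "PS", "NEORAL")],
                       reac=[("12", "1", "Tremor"), ("12", "1", "Rash")])
    corpus = assemble_case_reports([read_quarter(q1), read_quarter(q2)], dictionary, hierarchy)
    assert corpus.n_cases == 1
    case = corpus.case_report("1")
    # the retained record is the later version, including its reactions
    assert case.reactions == {hierarchy.pt_code_of("Tremor"), hierarchy.pt_code_of("Rash")}
    assert case.receipt_date == pd.Timestamp("2014-05-01")


def test_assemble_excludes_reactionless_cases_with_count(tmp_path, dictionary, hierarchy):
    q = write_quarter(tmp_path / "q",
                      demo=[("11", "1", "1", "20150101", "F", "", "", ""),
                            ("21", "2", "1", "20150101", "M", "", "", "")],
                      drug=[("11", "1", "1", "PS", "ASPIRIN"), ("21", "2", "1", "PS", "ASPIRIN")],
                      reac=[("11", "1", "Headache")])
    corpus = assemble_case_reports([read_quarter(q)], dictionary, hierarchy)
    assert corpus.n_cases == 1
    assert corpus.log["cases_without_reactions"] == 1


def test_assemble_unknown_pt_error_vs_bucket(tmp_path, dictionary, hierarchy):
    q = write_quarter(tmp_path / "q",
                      demo=[("11", "1", "1", "20150101", "F", "", "", "")],
                      drug=[("11", "1", "1", "PS", "ASPIRIN")],
                      reac=[("11", "1", "Not a real PT")])
    with pytest.raises(UnknownPTError):
        assemble_case_reports([read_quarter(q)], dictionary, hierarchy)
    corpus = assemble_case_reports([read_quarter(q)], dictionary, hierarchy, unknown_pt="bucket")
    assert corpus.case_report("1").reactions == {UNKNOWN_PT}


def test_assemble_flags_unparseable_dates(tmp_path, dictionary, hierarchy):
    q = write_quarter(tmp_path / "q",
                      demo=[("11", "1", "1", "2015AB01", "F", "", "", "")],
                      drug=[("11", "1", "1", "PS", "ASPIRIN")],
                      reac=[("11", "1", "Headache")])
    corpus = assemble_case_reports([read_quarter(q)], dictionary, hierarchy)
    assert corpus.log["unparseable_dates"] == 1
    assert corpus.case_report("1").receipt_date is None
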