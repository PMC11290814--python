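"""The four disproportionality statistics against frozen hand-arithmetic oracles.

The (10, 90, 100, 9900) reference values below were computed by hand in log
space from the printed formulas (point estimates, Woolf / delta-method
dispersions) and frozen; scipy's Pearson statistic serves as the independent
χ² oracle.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from faerspv.contingency import ContingencyTable
from faerspv.disprop_stats import (
    chi2_stat, classify, compute_stats, ebgm_stat, ic_stat, prr_stat, ror_stat, signal_table,
)
from faerspv.synthetic_data import ImplantedPair, SyntheticConfig, simulate_corpus

T_REF = ContingencyTable(10, 90, 100, 9900)
T_NULL = ContingencyTable(5, 5, 5, 5)

cells = st.integers(min_value=1, max_value=5000)


@st.composite
def tables(draw):
    return ContingencyTable(draw(cells), draw(cells), draw(cells), draw(cells))


# ------------------------------------------------------------- point + CI

def test_ror_reference_table():
    est = ror_stat(T_REF)
    assert est.point == pytest.approx(11.0)
    assert est.lower95 == pytest.approx(5.559515, rel=1e-5)
    assert est.upper95 == pytest.approx(21.764489, rel=1e-5)


def test_prr_and_chi2_reference_table():
    est, chi2 = prr_stat(T_REF)
    assert est.point == pytest.approx(10.0)
    assert est.lower95 == pytest.approx(5.382154, rel=1e-5)
    assert est.upper95 == pytest.approx(18.579922, rel=1e-5)
    assert chi2 == pytest.approx(74.447174, rel=1e-6)


def test_ebgm_reference_table():
    est = ebgm_stat(T_REF)
    assert est.point == pytest.approx(9.181818, rel=1e-6)
    assert est.lower95 == pytest.approx(4.640587, rel=1e-5)
    assert est.upper95 == pytest.approx(18.167053, rel=1e-5)


def test_ic_reference_table():
    est = ic_stat(T_REF)
    assert est.point == pytest.approx(3.198780, rel=1e-6)  # log2 of RRR 9.1818
    assert est.lower95 == pytest.approx(2.194216, rel=1e-5)
    assert est.upper95 == pytest.approx(4.203344, rel=1e-5)


def test_uniform_table_is_null():
    assert ror_stat(T_NULL).point == pytest.approx(1.0)
    assert ror_stat(T_NULL).lower95 < 1 < ror_stat(T_NULL).upper95
    est, chi2 = prr_stat(T_NULL)
    assert est.point == pytest.approx(1.0)
    assert chi2 == 0.0
    assert ic_stat(T_NULL).point == pytest.approx(0.0)
    assert ebgm_stat(T_NULL).point == pytest.approx(1.0)
    flags = classify(compute_stats(T_NULL))
    assert not flags.any_positive


def test_chi2_equals_generic_pearson_statistic():
    expected = scipy.stats.chi2_contingency(
        np.array([[10, 90], [100, 9900]]), correction=False
    ).statistic
    assert chi2_stat(T_REF) == pytest.approx(expected, rel=1e-12)


# ----------------------------------------------------------- zero cells

def test_zero_cell_flagged_and_classified_negative():
    t = ContingencyTable(0, 5, 5, 5)
    for est in (ror_stat(t), ebgm_stat(t), ic_stat(t)):
        assert est.zero_cell and not est.defined
    flags = classify(compute_stats(t))
    assert not flags.any_positive


def test_haldane_correction_defines_zero_cell_tables():
    t = ContingencyTable(0, 5, 5, 5)
    est = ror_stat(t, zero_cell="haldane")
    assert est.defined
    assert est.point == pytest.approx((0.5 * 5.5) / (5.5 * 5.5))


def test_unknown_vic_strategy_rejected():
    with pytest.raises(ValueError, match="V\\(IC\\)"):
        ic_stat(T_REF, vic="bayes")


# ----------------------------------------------------- algebraic identities

@given(tables())
def test_ic_is_log2_of_ebgm(t):
    assert ic_stat(t).point == pytest.approx(math.log2(ebgm_stat(t).point), abs=1e-12)


@given(tables())
def test_ordering_ror_ge_prr_ge_ebgm_when_positive_association(t):
    if t.a * t.d > t.b * t.c:
        ror = ror_stat(t).point
        prr, _ = prr_stat(t)
        ebgm = ebgm_stat(t).point
        assert ror >= prr.point - 1e-12
        assert prr.point >= ebgm - 1e-12


@given(tables())
def test_chi2_matches_scipy_on_random_tables(t):
    expected = scipy.stats.chi2_contingency(
        np.array([[t.a, t.b], [t.c, t.d]]), correction=False
    ).statistic
    assert chi2_stat(t) == pytest.approx(expected, rel=1e-12)


@given(tables())
def test_ror_and_prr_strictly_increase_in_a(t):
    """A new target drug–event case (b, c, d fixed) raises ROR and PRR.

    The observed/expected ratios (IC, EBGM) are deliberately excluded: a
    new case in cell a also inflates both margins of the expected count,
    and e.g. (1,1,1,5) -> (2,1,1,5) leaves the ratio at exactly 2.0."""
    t2 = ContingencyTable(t.a + 1, t.b, t.c, t.d)
    assert ror_stat(t2).point > ror_stat(t).point
    assert prr_stat(t2)[0].point > prr_stat(t)[0].point


@given(tables())
def test_all_four_increase_when_event_case_moves_to_target_drug(t):
    """Transferring an event case from the comparator (c) to the target (a)
    — margins a+c and N fixed — strictly raises all four estimates."""
    t1 = ContingencyTable(t.a, t.b, t.c + 1, t.d)
    t2 = ContingencyTable(t.a + 1, t.b, t.c, t.d)
    assert ror_stat(t2).point > ror_stat(t1).point
    assert prr_stat(t2)[0].point > prr_stat(t1)[0].point
    assert ic_stat(t2).point > ic_stat(t1).point
    assert ebgm_stat(t2).point > ebgm_stat(t1).point


@given(tables())
def test_ci_brackets_point(t):
    for est in (ror_stat(t), prr_stat(t)[0], ic_stat(t), ebgm_stat(t)):
        assert est.lower95 <= est.point <= est.upper95


# ------------------------------------------------------------- classify

def test_reference_table_flags():
    flags = classify(compute_stats(T_REF))
    assert flags.ror_positive and flags.prr_positive
    # with the Woolf-based intervals these also clear their thresholds
    assert flags.bcpnn_positive and flags.ebgm_positive
    assert flags.any_positive and flags.all_positive


def test_case_count_floor_blocks_tiny_a():
    """a = 2 with an enormous ROR still classifies negative (a >= 3 rule)."""
    t = ContingencyTable(2, 1, 1, 10000)
    s = compute_stats(t)
    assert s.ror.point > 100
    flags = classify(s)
    assert not flags.ror_positive and not flags.prr_positive


# ----------------------------------------------------------- signal_table

@pytest.fixture(scope="module")
def implanted_run():
    cfg = SyntheticConfig(
        n_cases=50_000, seed=0,
        implanted=(ImplantedPair("RX3008", "Hepatotoxicity", 10.0),),
    )
    corpus, truth = simulate_corpus(cfg)
    return corpus, truth


def test_implanted_pair_ranks_first_by_ebgm(implanted_run, hierarchy):
    corpus, _ = implanted_run
    frame = signal_table(corpus, "RX3008", level="PT", hierarchy=hierarchy,
                         min_a=3, sort_by="ebgm")
    assert frame.iloc[0]["event_code"] == hierarchy.pt_code_of("Hepatotoxicity")
    row = frame.iloc[0]
    assert row[["ror_positive", "prr_positive", "bcpnn_positive", "ebgm_positive"]].all()


def test_signal_table_single_event_corpus(hierarchy):
    from conftest import corpus_from_cases

    corpus = corpus_from_cases(
        [{"id": i, "drugs": [("X", "PS")] if i < 3 else [("Y", "PS")], "pts": ["Headache"]}
         for i in range(10)],
        hierarchy,
    )
    frame = signal_table(corpus, "X", level="PT", hierarchy=hierarchy)
    assert len(frame) == 1
    assert frame.iloc[0]["event_name"] == "Headache"


def test_signal_table_rows_preserve_ordering_invariant(implanted_run):
    corpus, _ = implanted_run
    frame = signal_table(corpus, "RX3008", level="SOC")
    pos = frame[(frame["ror"] > 1) & frame["ror"].notna()]
    assert not pos.empty
    assert (pos["ror"] >= pos["prr"] - 1e-12).all()
    assert (pos["prr"] >= pos["ebgm"] - 1e-12).all()
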