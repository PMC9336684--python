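"""Adverse-reaction incidence arithmetic and proportion comparisons."""

import math

import numpy as np
import pandas as pd
import pytest

from pegtk import reference
from pegtk.clinical import (
    ARTable,
    compare_proportions,
    incidence,
    period_table,
)
from pegtk.errors import InputError
from pegtk.util import trim_number


@pytest.mark.parametrize(
    "events, n, expected",
    [(72, 228, 31.58), (5, 686, 0.73), (0, 115, 0.0), (115, 115, 100.0)],
)
def test_incidence_examples(events, n, expected):
    assert incidence(events, n) == expected


def test_incidence_validates_counts():
    with pytest.raises(InputError):
        incidence(1, 0)
    with pytest.raises(InputError):
        incidence(5, 4)


#: every printed AR% / CNS-AR% cell of the clinical report, keyed by
#: (arm, period) in the packaged count table
EXPECTED_CELLS = {
    ("phase3_peg_rhgh_0.2qw", "overall"): ("31.58", "1.75"),
    ("phase3_daily_rhgh_0.25qd", "overall"): ("22.61", "0.87"),
    ("phase3_peg_rhgh_0.2qw", "week_1_4"): ("25.88", "0.88"),
    ("phase3_daily_rhgh_0.25qd", "week_1_4"): ("13.04", "0"),
    ("phase3_peg_rhgh_0.2qw", "week_5_13"): ("18.14", "0.88"),
    ("phase3_daily_rhgh_0.25qd", "week_5_13"): ("12.17", "0.87"),
    ("phase3_peg_rhgh_0.2qw", "week_14_25"): ("10", "0"),
    ("phase3_daily_rhgh_0.25qd", "week_14_25"): ("8.77", "0.88"),
    ("phase4_1_peg_rhgh_0.2qw", "overall"): ("10.79", "0.73"),
    ("phase4_1_daily_rhgh_0.25qd", "overall"): ("9.89", "0"),
    ("phase4_2_peg_rhgh_lt0.15", "overall"): ("3.66", "0"),
    ("phase4_2_peg_rhgh_0.15_0.17", "overall"): ("6.99", "0.54"),
    ("phase4_2_peg_rhgh_0.17_0.2", "overall"): ("14.38", "0.65"),
    ("phase4_2_peg_rhgh_0.2", "overall"): ("8.18", "0.74"),
    ("phase4_followup_peg_rhgh_0.2qw", "year_1"): ("9.94", "0.47"),
    ("phase4_followup_peg_rhgh_0.2qw", "year_2"): ("2.19", "0.24"),
    ("phase4_followup_peg_rhgh_0.2qw", "year_3"): ("1.25", "0"),
}


def test_period_table_reproduces_every_published_cell():
    """AR% and CNS-AR% computed from the packaged count columns must
    reproduce every printed percentage, including the trailing-zero
    display convention ("10", "0")."""
    out = period_table(reference.clinical_ar_table())
    assert len(out) == len(EXPECTED_CELLS)
    for _, row in out.iterrows():
        ar, cns = EXPECTED_CELLS[(row["arm"], row["period"])]
        assert row["ar_pct_display"] == ar
        assert row["cns_ar_pct_display"] == cns


def test_period_table_zero_events_everywhere():
    tbl = ARTable(pd.DataFrame(
        [("a", "p", 10, 0, 0), ("b", "p", 7, 0, 0)],
        columns=["arm", "period", "n", "n_ar", "n_cns_ar"],
    ))
    out = period_table(tbl)
    assert (out["ar_pct"] == 0).all() and (out["cns_ar_pct_display"] == "0").all()


def test_ar_table_validates_rows():
    df = pd.DataFrame([("a", "p", 5, 7, 0)], columns=["arm", "period", "n", "n_ar", "n_cns_ar"])
    with pytest.raises(InputError, match="row 0"):
        ARTable(df)


# ---------------------------------------------------------------- comparisons
@pytest.mark.parametrize(
    "e1, n1, e2, n2",
    [(72, 228, 26, 115), (74, 686, 9, 91)],
)
def test_published_group_comparisons_not_significant(e1, n1, e2, n2):
    """Both reported PEG-rhGH vs daily-rhGH comparisons must flag
    p > 0.05 (no significant difference in AR incidence)."""
    res = compare_proportions(e1, n1, e2, n2)
    assert res.p_value > 0.05
    assert not res.significant
    assert res.flag == "not significant"


def test_identical_proportions_fisher_p_is_one():
    res = compare_proportions(10, 100, 10, 100, method="fisher")
    assert res.p_value == pytest.approx(1.0)


def fisher_two_sided_enumeration(e1, n1, e2, n2):
    """Exact enumeration oracle: sum hypergeometric probabilities of all
    tables (same margins) no more probable than the observed one."""
    m = e1 + e2

    def prob(k):
        return (
            math.comb(n1, k) * math.comb(n2, m - k) / math.comb(n1 + n2, m)
        )

    p_obs = prob(e1)
    return sum(
        prob(k)
        for k in range(max(0, m - n2), min(n1, m) + 1)
        if prob(k) <= p_obs * (1 + 1e-9)
    )


@pytest.mark.parametrize("counts", [(3, 10, 1, 12), (5, 8, 2, 9), (0, 6, 4, 7)])
def test_fisher_matches_hypergeometric_enumeration(counts):
    e1, n1, e2, n2 = counts
    res = compare_proportions(e1, n1, e2, n2, method="fisher")
    assert res.p_value == pytest.approx(
        fisher_two_sided_enumeration(e1, n1, e2, n2), rel=1e-9
    )


def test_small_expected_counts_auto_select_fisher():
    res = compare_proportions(1, 10, 0, 12)
    assert res.method == "fisher"


def test_degenerate_table_warns_and_returns_one():
    with pytest.warns(UserWarning, match="degenerate"):
        res = compare_proportions(0, 10, 0, 12)
    assert res.p_value == 1.0 and not res.significant


def test_display_trimming_convention():
    assert trim_number(10.0) == "10"
    assert trim_number(0.0) == "0"
    assert trim_number(31.58) == "31.58"
    assert trim_number(0.5) == "0.5"
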