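from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from brcascreen.famhist import (
    Contingency2x2,
    binomial_tail,
    build_contingency,
    category_positive,
    family_history_screen,
    fisher_exact,
    qc_records,
    yates_chi2,
)
from oracles import (
    binomial_upper_tail,
    chi2_uncorrected_closed_form,
    fisher_two_sided_exact,
    yates_chi2_closed_form,
)

ITEMS = [
    "self__breast", "self__ovary", "self__lung",
    "father__lung", "mother__breast", "brother__lung",
    "sister__breast", "sister__ovary", "offspring__leukemia",
    "spouse__lung",
]


def _records(rows):
    """rows: list of (pid, sex, carrier, set-of-checked-items)."""
    data = []
    for pid, sex, carrier, checked in rows:
        row = {"participant_id": pid, "sex": sex, "carrier": int(carrier)}
        for item in ITEMS:
            row[item] = int(item in checked)
        data.append(row)
    return pd.DataFrame(data)


def _wide_records(n_items: int, checked_counts: dict[str, int]):
    cols = [f"sister__site{i:03d}" for i in range(n_items)]
    rows = []
    for pid, k in checked_counts.items():
        row = {"participant_id": pid, "sex": "female", "carrier": 0}
        for i, c in enumerate(cols):
            row[c] = int(i < k)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_qc_drop_rule_boundary():
    df = _wide_records(80, {"at50": 50, "at51": 51, "none": 0})
    kept, report = qc_records(df, max_items=50)
    assert sorted(kept["participant_id"]) == ["at50", "none"]
    assert report.dropped["participant_id"].tolist() == ["at51"]
    assert report.dropped["n_checked"].tolist() == [51]


def test_contradictions_are_flagged_not_dropped():
    df = _records([
        ("m1", "male", 0, {"self__ovary"}),
        ("f1", "female", 0, {"self__ovary"}),
        ("m2", "male", 0, {"father__lung"}),
    ])
    kept, report = qc_records(df)
    assert len(kept) == 3
    assert report.contradictions["participant_id"].tolist() == ["m1"]


# ---------------------------------------------------------------------------
# contingency building
# ---------------------------------------------------------------------------

def test_contingency_counts_participants_once():
    rows = [("c1", "female", 1, {"sister__breast", "sister__ovary"}),
            ("c2", "male", 1, set())]
    rows += [(f"n{i}", "female", 0, {"sister__breast"} if i < 2 else set())
             for i in range(8)]
    t = build_contingency(_records(rows), "sister")
    assert (t.a, t.b, t.c, t.d) == (1, 1, 2, 6)


def test_any_family_ignores_spouse_and_self():
    df = _records([
        ("p1", "female", 1, {"spouse__lung"}),            # spouse only
        ("p2", "female", 1, {"self__breast"}),            # self only
        ("p3", "female", 1, {"offspring__leukemia"}),     # blood relative
        ("p4", "female", 0, set()),
    ])
    pos = category_positive(df, "any_family")
    assert pos.tolist() == [False, False, True, False]
    with pytest.raises(ValueError, match="unknown category"):
        build_contingency(df, "cousin")


def test_contingency_matches_nested_loop(rng):
    n = 200
    rows = []
    for i in range(n):
        checked = {item for item in ITEMS if rng.random() < 0.1}
        rows.append((f"p{i}", "female", int(rng.random() < 0.3), checked))
    df = _records(rows)
    t = build_contingency(df, "sister")
    a = b = c = d = 0
    for pid, sex, carrier, checked in rows:
        pos = any(item.startswith("sister__") for item in checked)
        if carrier and pos:
            a += 1
        elif carrier:
            b += 1
        elif pos:
            c += 1
        else:
            d += 1
    assert (t.a, t.b, t.c, t.d) == (a, b, c, d)
    assert t.n == n  # participants conserved


# ---------------------------------------------------------------------------
# Yates chi-squared
# ---------------------------------------------------------------------------

def test_yates_null_table():
    res = yates_chi2(Contingency2x2(10, 10, 10, 10))
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_yates_matches_closed_form():
    t = Contingency2x2(20, 80, 10, 190)
    res = yates_chi2(t)
    stat, p = yates_chi2_closed_form(20, 80, 10, 190)
    assert res.statistic == pytest.approx(stat, rel=1e-12)
    assert res.p_value == pytest.approx(p, rel=1e-10)


def test_yates_is_conservative_and_scales(rng):
    for _ in range(30):
        a, b, c, d = (int(x) for x in rng.integers(1, 40, size=4))
        t = Contingency2x2(a, b, c, d)
        res_y = yates_chi2(t)
        stat_u, p_u = chi2_uncorrected_closed_form(a, b, c, d)
        assert res_y.p_value >= p_u - 1e-12
        if a * d != b * c:
            t10 = Contingency2x2(10 * a, 10 * b, 10 * c, 10 * d)
            assert yates_chi2(t10).statistic > res_y.statistic
            assert yates_chi2(t10).p_value < res_y.p_value


def test_yates_rejects_zero_margin():
    with pytest.raises(ValueError, match="[Ff]isher"):
        yates_chi2(Contingency2x2(0, 0, 5, 5))


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def test_fisher_degenerate_margin():
    assert fisher_exact(Contingency2x2(0, 0, 5, 7)).p_value == pytest.approx(1.0)


def test_fisher_matches_enumeration():
    res = fisher_exact(Contingency2x2(1, 9, 11, 3))
    assert res.p_value == pytest.approx(fisher_two_sided_exact(1, 9, 11, 3), rel=1e-9)


def test_fisher_transpose_symmetry():
    p1 = fisher_exact(Contingency2x2(3, 1, 1, 3)).p_value
    p2 = fisher_exact(Contingency2x2(1, 3, 3, 1)).p_value
    p3 = fisher_exact(Contingency2x2(3, 1, 1, 3)).p_value
    assert p1 == pytest.approx(p2, rel=1e-12)
    assert p1 == pytest.approx(p3, rel=1e-12)


# ---------------------------------------------------------------------------
# binomial tail
# ---------------------------------------------------------------------------

def test_binomial_tail_values():
    assert binomial_tail(0, 10, 0.3).p_value == pytest.approx(1.0)
    assert binomial_tail(3, 10, 0.1).p_value == pytest.approx(
        binomial_upper_tail(3, 10, 0.1), rel=1e-12
    )
    assert binomial_tail(10, 10, 0.4).p_value == pytest.approx(0.4**10, rel=1e-12)


def test_binomial_tail_monotone_in_k():
    ps = [binomial_tail(k, 25, 0.2).p_value for k in range(26)]
    assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


def test_binomial_tail_validates():
    with pytest.raises(ValueError):
        binomial_tail(3, 10, 0.0)
    with pytest.raises(ValueError):
        binomial_tail(11, 10, 0.5)


# ---------------------------------------------------------------------------
# screen
# ---------------------------------------------------------------------------

def test_screen_requires_carriers():
    df = _records([("p1", "female", 0, set()), ("p2", "male", 0, set())])
    with pytest.raises(ValueError, match="carrier"):
        family_history_screen(df)


def test_screen_flags_enriched_sister_category(rng):
    rows = []
    for i in range(60):  # carriers with strongly elevated sister histories
        rows.append((f"c{i}", "female", 1,
                     {"sister__breast"} if rng.random() < 0.5 else set()))
    for i in range(2000):
        rows.append((f"n{i}", "female", 0,
                     {"sister__breast"} if rng.random() < 0.05 else set()))
    df = _records(rows)
    screen = family_history_screen(df, categories=("sister", "father"))
    sister = screen[screen.category == "sister"].iloc[0]
    father = screen[screen.category == "father"].iloc[0]
    assert sister.significant and sister.stars in ("*", "**")
    assert not father.significant
    # conservation: every table covers all participants
    for _, row in screen.iterrows():
        assert row.carrier_pos + row.carrier_neg + row.noncarrier_pos + row.noncarrier_neg == len(df)


def test_screen_switches_to_fisher_for_sparse_tables():
    rows = [("c1", "female", 1, {"sister__breast"}), ("c2", "female", 1, set())]
    rows += [(f"n{i}", "female", 0, set()) for i in range(30)]
    screen = family_history_screen(_records(rows), categories=("sister",))
    assert screen.iloc[0].method == "fisher_exact"


def test_screen_bonferroni_inflates_p(rng):
    rows = [("c1", "female", 1, {"sister__breast"}), ("c2", "female", 1, set())]
    rows += [(f"n{i}", "female", 0, {"sister__breast"} if i < 3 else set())
             for i in range(50)]
    df = _records(rows)
    plain = family_history_screen(df, categories=("sister", "father", "mother"))
    adj = family_history_screen(
        df, categories=("sister", "father", "mother"), bonferroni=True
    )
    assert adj.iloc[0].p_value >= plain.iloc[0].p_value
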