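"""Descriptive statistics and Duncan's multiple range test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from provtrial.summaries import (duncan_mrt, provenance_descriptives,
                                 trait_variation_summary)


def _frame(**groups):
    rows = []
    for prov, values in groups.items():
        rows += [dict(provenance=prov, y=v) for v in values]
    return pd.DataFrame(rows)


def test_hand_computed_descriptives():
    desc = provenance_descriptives(_frame(A=[1.0, 2.0, 3.0]), "y")
    row = desc[desc["provenance"] == "A"].iloc[0]
    assert row["mean"] == pytest.approx(2.0)
    assert row["cv"] == pytest.approx(50.0)
    assert row["se_mean"] == pytest.approx(0.577, abs=5e-4)
    assert (row["minimum"], row["maximum"], row["n"]) == (1.0, 3.0, 3)


def test_constant_trait_has_zero_cv():
    desc = provenance_descriptives(_frame(A=[5.0, 5.0, 5.0]), "y")
    row = desc.iloc[0]
    assert row["cv"] == 0.0
    assert row["minimum"] == row["maximum"] == row["mean"] == 5.0


def test_descriptives_order_invariant():
    df = _frame(A=[1.0, 2.0], B=[4.0, 6.0])
    shuffled = df.iloc[::-1].reset_index(drop=True)
    pd.testing.assert_frame_equal(provenance_descriptives(df, "y"),
                                  provenance_descriptives(shuffled, "y"))


def test_overall_row_pools_provenance_means():
    desc = provenance_descriptives(_frame(A=[1.0, 3.0], B=[10.0, 14.0]), "y")
    overall = desc[desc["provenance"] == "Overall"].iloc[0]
    assert overall["mean"] == pytest.approx((2.0 + 12.0) / 2)
    # SE over the two provenance means 2 and 12
    assert overall["se_mean"] == pytest.approx(np.std([2, 12], ddof=1) / np.sqrt(2))


def test_single_observation_provenance_flagged():
    desc = provenance_descriptives(_frame(A=[1.0], B=[2.0, 4.0]), "y")
    row = desc[desc["provenance"] == "A"].iloc[0]
    assert not row["cv_defined"] and np.isnan(row["cv"])


def _desc_frame(rows):
    return pd.DataFrame(rows, columns=["provenance", "mean", "se_mean",
                                       "minimum", "maximum", "cv"])


def test_variation_summary_single_provenance():
    d = _desc_frame([("A", 5.0, 0.1, 2.0, 10.0, 30.0)])
    out = trait_variation_summary(d)
    assert out["mean_cv"] == pytest.approx(30.0)
    assert out["fold_ratio"] == pytest.approx(5.0)


def test_variation_summary_widest_range_and_skips_nonpositive():
    d = _desc_frame([
        ("A", 5.0, 0.1, 1.0, 9.0, 30.0),     # width 8, ratio 9
        ("B", 5.0, 0.1, 4.0, 11.0, 40.0),    # width 7
        ("C", 5.0, 0.1, 0.0, 100.0, 50.0),   # nonpositive min: skipped
    ])
    out = trait_variation_summary(d)
    assert out["widest_range_provenance"] == "A"
    assert out["fold_ratio"] == pytest.approx(9.0)
    assert out["skipped"] == ["C"]
    assert out["mean_cv"] == pytest.approx(40.0)


def test_duncan_identical_means_share_one_letter():
    df = _frame(A=[10.0, 10.1, 9.9], B=[10.0, 10.1, 9.9], C=[10.0, 10.1, 9.9])
    res = duncan_mrt(df, "y")
    assert set(res.letters.values()) == {"a"}


def test_duncan_separated_groups_get_distinct_letters(two_group_frame):
    res = duncan_mrt(two_group_frame, "y")
    assert res.letters[res.order[0]] != res.letters[res.order[1]]


def test_duncan_two_groups_equals_pooled_t_test():
    """For k=2 the Duncan critical range reduces to a two-sample t-test on
    the pooled mean square: q(alpha, 2, df) = sqrt(2) t(alpha/2, df)."""
    rng = np.random.default_rng(12)
    agree = 0
    trials = 50
    for _ in range(trials):
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(0.6, 1.0, 8)
        df = _frame(A=a, B=b)
        res = duncan_mrt(df, "y", alpha=0.05)
        duncan_separate = res.letters[res.order[0]] != res.letters[res.order[1]]
        t, p = stats.ttest_ind(a, b)
        agree += duncan_separate == (p < 0.05)
    assert agree == trials


def test_duncan_letters_contiguous_over_sorted_means():
    rng = np.random.default_rng(3)
    for _ in range(20):
        df = _frame(**{f"P{j}": rng.normal(j * 0.4, 1.0, 6) for j in range(6)})
        res = duncan_mrt(df, "y")
        for letter in set("".join(res.letters.values())):
            idx = [i for i, p in enumerate(res.order)
                   if letter in res.letters[p]]
            assert idx == list(range(min(idx), max(idx) + 1))


def test_duncan_zero_residual_variance_groups_exact_ties_only():
    df = _frame(A=[1.0, 1.0], B=[1.0, 1.0], C=[2.0, 2.0])
    res = duncan_mrt(df, "y")
    assert res.letters["A"] == res.letters["B"]
    assert res.letters["C"] != res.letters["A"]


def test_duncan_requires_two_provenances():
    with pytest.raises(ValueError):
        duncan_mrt(_frame(A=[1.0, 2.0]), "y")
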