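"""Heritability, genetic CV, correlations, gain and selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from provtrial import datasets
from provtrial.quantgen import (genetic_correlation, genetic_cv,
                                phenotypic_correlation,
                                provenance_heritability, realized_gain,
                                select_superior, correlation_matrix)
from provtrial.reml import CovComponents, VarComponents


def _vc(trait, v_p, v_e, v_pb=None, se_p=0.1, se_e=0.1):
    return VarComponents(trait=trait, v_p=v_p, v_pb=v_pb, v_e=v_e,
                         se_p=se_p, se_e=se_e)


def _cc(v_p1, v_p2, cov_p, v_e1=1.0, v_e2=1.0, cov_e=0.0):
    vs = _vc("s", v_p1 + v_p2 + 2 * cov_p, v_e1 + v_e2 + 2 * cov_e)
    return CovComponents("a", "b", cov_p=cov_p, cov_e=cov_e,
                         vc_a=_vc("a", v_p1, v_e1),
                         vc_b=_vc("b", v_p2, v_e2), vc_sum=vs)


def test_heritability_published_component_values():
    h2 = provenance_heritability(v_p=0.47, v_pb=0.08, v_e=8.97, n_h=4.0, b=10)
    assert round(h2, 2) == 0.67
    h2_height = provenance_heritability(v_p=0.23, v_pb=0.26, v_e=5.46,
                                        n_h=4.0, b=10)
    assert round(h2_height, 2) == 0.59


def test_heritability_boundary_cases():
    assert provenance_heritability(v_p=0.0, v_pb=0.1, v_e=1.0, n_h=4, b=10) == 0.0
    assert provenance_heritability(v_p=0.5, v_pb=0.0, v_e=0.0, n_h=4, b=10) == 1.0
    with pytest.raises(ValueError):
        provenance_heritability(v_p=0.0, v_pb=0.0, v_e=0.0, n_h=4, b=10)


@given(v_p=st.floats(0.01, 10), v_pb=st.floats(0, 10), v_e=st.floats(0, 10),
       bump=st.floats(0.01, 5))
@settings(max_examples=50, derandomize=True)
def test_heritability_monotonicity(v_p, v_pb, v_e, bump):
    base = provenance_heritability(v_p=v_p, v_pb=v_pb, v_e=v_e, n_h=4, b=10)
    assert provenance_heritability(v_p=v_p + bump, v_pb=v_pb, v_e=v_e,
                                   n_h=4, b=10) >= base
    assert provenance_heritability(v_p=v_p, v_pb=v_pb + bump, v_e=v_e,
                                   n_h=4, b=10) <= base
    assert provenance_heritability(v_p=v_p, v_pb=v_pb, v_e=v_e + bump,
                                   n_h=4, b=10) <= base


def test_genetic_cv_published_values():
    assert genetic_cv(9.98e-5, 0.0844) == pytest.approx(11.83, abs=0.05)
    assert round(genetic_cv(0.23, 11.98), 2) == 4.00
    assert genetic_cv(0.0, 5.0) == 0.0
    with pytest.raises(ValueError):
        genetic_cv(1.0, 0.0)


@pytest.mark.parametrize("sup,overall,expected", [
    (0.09, 0.08, 12.50),
    (157.31, 162.43, -3.15),
    (5.0, 5.0, 0.0),
])
def test_realized_gain_values(sup, overall, expected):
    assert round(realized_gain(sup, overall), 2) == expected


@given(sup=st.floats(-100, 100), overall=st.floats(0.01, 100),
       c=st.floats(0.01, 50))
@settings(max_examples=50, derandomize=True)
def test_realized_gain_scale_invariant(sup, overall, c):
    assert realized_gain(c * sup, c * overall) == pytest.approx(
        realized_gain(sup, overall), rel=1e-9, abs=1e-9)


def test_genetic_correlation_formula_and_ne():
    r, se = genetic_correlation(_cc(1.0, 4.0, cov_p=0.5 * math.sqrt(4.0)))
    assert r == pytest.approx(0.5)
    assert se is not None and se > 0
    # self-pair: covariance equals the variance
    r_self, _ = genetic_correlation(_cc(2.0, 2.0, cov_p=2.0))
    assert r_self == pytest.approx(1.0)
    cc_ne = CovComponents("a", "b", cov_p=None, cov_e=0.0,
                          vc_a=_vc("a", 0.0, 1.0), vc_b=_vc("b", 1.0, 1.0),
                          vc_sum=_vc("s", 1.0, 2.0))
    assert genetic_correlation(cc_ne) == (None, None)


def test_phenotypic_correlation_hand_value():
    r, se = phenotypic_correlation(_cc(1.0, 1.0, cov_p=0.3, cov_e=0.2,
                                       v_e1=1.0, v_e2=1.0))
    assert r == pytest.approx((0.3 + 0.2) / 2.0)
    zero, _ = phenotypic_correlation(_cc(1.0, 1.0, cov_p=0.0, cov_e=0.0))
    assert zero == 0.0


def test_correlation_matrix_layout():
    ccs = {("a", "b"): _cc(1.0, 1.0, cov_p=0.5, cov_e=0.1)}
    table = correlation_matrix(ccs, ["a", "b"])
    assert table.loc["a", "b"].startswith("0.50(")
    assert table.loc["b", "a"] != "" and table.loc["a", "a"] == ""


def test_selection_reproduces_published_sets():
    means = datasets.provenance_means()
    wood = select_superior(means, "volume", "wbd", purpose="wood products")
    assert wood.superior == ("YNMS",)
    pulp = select_superior(means, "volume", "fl", purpose="pulpwood")
    assert pulp.superior == ("GXFCG", "GXLZ", "GXNN")
    # pooled superior mean over the three pulpwood provenances
    assert round(pulp.superior_means["dbh"], 2) == 13.16


def test_selection_with_unreachable_threshold_is_empty():
    means = pd.DataFrame({"provenance": ["A", "B"], "x": [1.0, 1.0],
                          "y": [2.0, 2.0]})
    rep = select_superior(means, "x", "y")
    assert rep.empty and rep.gains == {}


def test_selection_threshold_is_strict():
    means = pd.DataFrame({"provenance": ["A", "B", "C"],
                          "x": [1.0, 2.0, 3.0], "y": [3.0, 2.0, 1.0]})
    # overall means are (2, 2); B ties both and must not be selected
    rep = select_superior(means, "x", "y")
    assert rep.superior == ()


def test_gain_report_on_recovered_trial(recovery_study):
    """Sanity: per-replicate heritabilities live in (0, 1)."""
    h2 = recovery_study["h2"]
    assert np.all((h2 >= 0) & (h2 <= 1))
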