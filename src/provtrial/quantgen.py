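"""Quantitative-genetics summaries: provenance heritability, genetic
variation coefficient, genetic/phenotypic correlations, realized gain and
two-trait superior-provenance selection.

Provenance heritability measures how repeatable provenance means are:

    h^2 = V_P / (V_e / (n_h b) + V_PB / b + V_P),

with V_P the provenance variance, V_PB the provenance-by-block
interaction, V_e the residual, b the number of blocks and n_h the
harmonic-mean surviving plot size (the unbalanced-design correction).
For the wood-trait model V_PB is absent and enters as zero.

The genetic variation coefficient CV_G = 100 * sqrt(V_P) / mean is a
scale-free measure of exploitable genetic variation, and realized gain
G = 100 * (mean_selected - mean_overall) / mean_overall is the yield of
truncation selection on provenance means.

Genetic correlation r_g = Cov_P(a, b) / sqrt(V_P(a) V_P(b)) uses the
provenance covariance component; the phenotypic correlation

    r_P = (Cov_P + Cov_e) / sqrt((V_P(a) + V_e(a)) (V_P(b) + V_e(b)))

deliberately excludes the provenance-by-block component, following the
formula as printed in the trial's analysis protocol.  Standard errors
come from the delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reml import CovComponents, VarComponents

__all__ = [
    "HeritabilityResult",
    "GainReport",
    "provenance_heritability",
    "genetic_cv",
    "genetic_correlation",
    "phenotypic_correlation",
    "correlation_matrix",
    "realized_gain",
    "select_superior",
]


@dataclass(frozen=True)
class HeritabilityResult:
    trait: str
    h2: float
    cv_g: float | None
    v_p: float
    v_pb: float
    v_e: float
    n_h: float
    b: int


@dataclass(frozen=True)
class GainReport:
    """Two-trait truncation selection outcome.

    ``superior`` lists provenances whose means strictly exceed the overall
    mean of both selection traits; ``gains`` maps every reported trait to
    its realized gain (%) of the superior-set pooled mean (unweighted mean
    of the selected provenances' means) over the overall mean.
    """

    purpose: str
    selection_traits: tuple[str, str]
    superior: tuple[str, ...]
    overall_means: dict = field(default_factory=dict)
    superior_means: dict = field(default_factory=dict)
    gains: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return len(self.superior) == 0


def provenance_heritability(vc: VarComponents | None = None, n_h: float = None,
                            b: int = None, *, v_p=None, v_pb=None, v_e=None,
                            ) -> float:
    """Provenance heritability from variance components.

    Accepts either a :class:`VarComponents` or explicit ``v_p``/``v_pb``/
    ``v_e`` keywords; a missing interaction component is treated as zero
    (the wood-trait model).
    """
    if vc is not None:
        v_p, v_pb, v_e = vc.v_p, vc.v_pb, vc.v_e
    v_pb = 0.0 if v_pb is None else v_pb
    if v_p is None or v_e is None:
        raise ValueError("need v_p and v_e")
    if v_p < 0 or v_pb < 0 or v_e < 0:
        raise ValueError("variance components must be non-negative")
    if n_h is None or n_h <= 0 or b is None or b < 1:
        raise ValueError("need n_h > 0 and b >= 1")
    denom = v_e / (n_h * b) + v_pb / b + v_p
    if denom == 0:
        raise ValueError("all variance components are zero; h2 undefined")
    return v_p / denom


def genetic_cv(v_p: float, trait_mean: float) -> float:
    """Genetic variation coefficient CV_G (%) = 100 sqrt(V_P) / mean."""
    if trait_mean <= 0:
        raise ValueError("trait mean must be positive")
    if v_p < 0:
        raise ValueError("provenance variance must be non-negative")
    return 100.0 * math.sqrt(v_p) / trait_mean


def _corr_se(f, theta, var_theta):
    """Delta-method SE of f(theta) with diagonal parameter covariance."""
    theta = np.asarray(theta, dtype=float)
    var_theta = np.asarray(var_theta, dtype=float)
    grad = np.zeros_like(theta)
    for i in range(len(theta)):
        h = 1e-6 * max(abs(theta[i]), 1e-8)
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        grad[i] = (f(tp) - f(tm)) / (2 * h)
    var = float(np.sum(grad**2 * var_theta))
    return math.sqrt(var) if var >= 0 and np.isfinite(var) else float("nan")


def genetic_correlation(cc: CovComponents) -> tuple[float | None, float | None]:
    """(r_g, SE) from covariance components; (None, None) when either
    marginal provenance variance is at the zero boundary."""
    if cc.cov_p is None:
        return None, None
    v1, v2 = cc.vc_a.v_p, cc.vc_b.v_p
    r = float(np.clip(cc.cov_p / math.sqrt(v1 * v2), -1.0, 1.0))

    def f(th):
        vs, va, vb = th
        c = 0.5 * (vs - va - vb)
        if va <= 0 or vb <= 0:
            return np.nan
        return c / math.sqrt(va * vb)

    se = _corr_se(f, [cc.vc_sum.v_p, v1, v2],
                  [(cc.vc_sum.se_p or 0) ** 2, (cc.vc_a.se_p or 0) ** 2,
                   (cc.vc_b.se_p or 0) ** 2])
    return r, se


def phenotypic_correlation(cc: CovComponents) -> tuple[float, float]:
    """(r_P, SE); the provenance-by-block component is excluded from the
    phenotypic variance by construction."""
    vp1 = cc.vc_a.v_p
    vp2 = cc.vc_b.v_p
    d1 = vp1 + cc.vc_a.v_e
    d2 = vp2 + cc.vc_b.v_e
    if d1 <= 0 or d2 <= 0:
        raise ValueError("zero total variance; r_P undefined")
    cov_p = cc.cov_p if cc.cov_p is not None else 0.0
    r = float(np.clip((cov_p + cc.cov_e) / math.sqrt(d1 * d2), -1.0, 1.0))

    def f(th):
        vsp, vap, vbp, vse, vae, vbe = th
        cp = 0.5 * (vsp - vap - vbp)
        ce = 0.5 * (vse - vae - vbe)
        da, db = vap + vae, vbp + vbe
        if da <= 0 or db <= 0:
            return np.nan
        return (cp + ce) / math.sqrt(da * db)

    se = _corr_se(
        f,
        [cc.vc_sum.v_p, vp1, vp2, cc.vc_sum.v_e, cc.vc_a.v_e, cc.vc_b.v_e],
        [(cc.vc_sum.se_p or 0) ** 2, (cc.vc_a.se_p or 0) ** 2,
         (cc.vc_b.se_p or 0) ** 2, (cc.vc_sum.se_e or 0) ** 2,
         (cc.vc_a.se_e or 0) ** 2, (cc.vc_b.se_e or 0) ** 2],
    )
    return r, se


def correlation_matrix(cov_components: dict, traits: list[str]) -> pd.DataFrame:
    """Assemble the two-sided correlation table: genetic correlations (SE)
    above the diagonal, phenotypic below, NE where not estimable.

    ``cov_components`` maps unordered trait pairs (frozenset or tuple) to
    :class:`CovComponents`.
    """

    def lookup(a, b):
        for key in ((a, b), (b, a), frozenset((a, b))):
            if key in cov_components:
                return cov_components[key]
        raise KeyError(f"no covariance components for pair ({a}, {b})")

    out = pd.DataFrame("", index=traits, columns=traits, dtype=object)
    for i, a in enumerate(traits):
        for j, b in enumerate(traits):
            if i == j:
                continue
            cc = lookup(a, b)  # correlations are symmetric in the pair
            if i < j:
                r, se = genetic_correlation(cc)
                out.iloc[i, j] = "NE" if r is None else f"{r:.2f}({se:.2f})"
            else:
                r, se = phenotypic_correlation(cc)
                out.iloc[i, j] = f"{r:.2f}({se:.2f})"
    return out


def realized_gain(superior_mean: float, overall_mean: float) -> float:
    """Realized gain G (%) of a selected mean over the overall mean."""
    if overall_mean == 0:
        raise ValueError("overall mean is zero; gain undefined")
    return 100.0 * (superior_mean - overall_mean) / overall_mean


def select_superior(provenance_means: pd.DataFrame, trait_a: str, trait_b: str,
                    purpose: str = "") -> GainReport:
    """Two-trait threshold selection on a provenance-means table.

    ``provenance_means`` has one row per provenance (index or a
    ``provenance`` column) and one column per trait.  A provenance is
    superior when its mean strictly exceeds the overall (mean-of-means)
    threshold for *both* selection traits.  Gains are reported for every
    trait column, using the unweighted mean of the selected provenances'
    means.  An empty superior set yields a report with no gains rather
    than an error.
    """
    df = provenance_means.copy()
    if "provenance" in df.columns:
        df = df.set_index("provenance")
    df = df.astype(float)
    for t in (trait_a, trait_b):
        if t not in df.columns:
            raise ValueError(f"selection trait {t!r} missing from the table")
        if df[t].isna().any():
            raise ValueError(f"selection trait {t!r} has missing provenance means")
    overall = df.mean(axis=0)
    mask = (df[trait_a] > overall[trait_a]) & (df[trait_b] > overall[trait_b])
    superior = tuple(sorted(df.index[mask]))
    sup_means = df.loc[list(superior)].mean(axis=0) if superior else None
    gains = {}
    sup_dict = {}
    for t in df.columns:
        if superior and not math.isnan(overall[t]) and overall[t] != 0:
            gains[t] = realized_gain(float(sup_means[t]), float(overall[t]))
            sup_dict[t] = float(sup_means[t])
    return GainReport(
        purpose=purpose,
        selection_traits=(trait_a, trait_b),
        superior=superior,
        overall_means={t: float(overall[t]) for t in df.columns},
        superior_means=sup_dict,
        gains=gains,
    )
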