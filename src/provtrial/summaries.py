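"""Per-provenance descriptive statistics and Duncan's multiple range test.

Descriptives reproduce the structure of a provenance-trial summary table:
per-provenance mean, standard error, min, max and coefficient of
variation (CV = 100 * sample sd / mean), plus an overall row whose mean
and SE are taken over the provenance means (the convention used when an
overall mean serves as a selection threshold).

Duncan's multiple range test ranks the provenance means and compares the
span of every k adjacent means against the critical range

    R_k = q*(alpha_k, k, df_e) * sqrt(MS_e / n_e),

where q* is the upper studentized-range quantile, MS_e the residual mean
square of the one-way provenance ANOVA, n_e the harmonic mean of group
sizes (the common field-trial convention for unequal groups), and
alpha_k = 1 - (1 - alpha)^(k-1) is Duncan's step-dependent protection
level.  The step-down sweep assigns the usual letter display: provenances
sharing a letter are not significantly different, and letters are
contiguous over the sorted means.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProvenanceDescriptives",
    "DuncanResult",
    "provenance_descriptives",
    "trait_variation_summary",
    "duncan_mrt",
]


@dataclass(frozen=True)
class ProvenanceDescriptives:
    provenance: str
    mean: float
    se_mean: float
    minimum: float
    maximum: float
    cv: float
    n: int
    cv_defined: bool = True


@dataclass(frozen=True)
class DuncanResult:
    """Ranked means with their letter groups.

    ``order`` lists provenances by descending mean; ``letters`` maps each
    provenance to its letter string (e.g. ``"ab"``).
    """

    order: tuple[str, ...]
    means: tuple[float, ...]
    letters: dict
    alpha: float
    ms_error: float
    df_error: int
    n_effective: float


def _trait_series(data, trait: str) -> pd.DataFrame:
    """Normalize input (records or frame) to columns provenance, value."""
    if not isinstance(data, pd.DataFrame):
        from .trial_data import records_to_frame

        data = records_to_frame(data)
        if "alive" in data.columns:
            data = data[data["alive"].astype(bool)]
    df = data[["provenance", trait]].dropna()
    return df.rename(columns={trait: "value"})


def provenance_descriptives(data, trait: str) -> pd.DataFrame:
    """Table-style descriptives: one row per provenance plus an overall row.

    The overall row pools by provenance means: its mean is the arithmetic
    mean of the per-provenance means and its SE the standard error of
    those means.  Provenances with a single observation get an undefined
    CV (NaN) and ``cv_defined=False``.
    """
    df = _trait_series(data, trait)
    rows = []
    for prov, g in df.groupby("provenance", sort=True):
        v = g["value"].to_numpy(dtype=float)
        n = len(v)
        sd = float(np.std(v, ddof=1)) if n > 1 else np.nan
        mean = float(np.mean(v))
        rows.append(dict(
            provenance=prov, mean=mean,
            se_mean=sd / np.sqrt(n) if n > 1 else np.nan,
            minimum=float(np.min(v)), maximum=float(np.max(v)),
            cv=100.0 * sd / mean if n > 1 and mean != 0 else np.nan,
            n=n, cv_defined=bool(n > 1 and mean != 0),
        ))
    out = pd.DataFrame(rows)
    pm = out["mean"].to_numpy()
    overall = dict(
        provenance="Overall", mean=float(np.mean(pm)),
        se_mean=float(np.std(pm, ddof=1) / np.sqrt(len(pm))) if len(pm) > 1 else np.nan,
        minimum=float(out["minimum"].min()), maximum=float(out["maximum"].max()),
        cv=float(out["cv"].mean()), n=int(out["n"].sum()),
        cv_defined=bool(out["cv_defined"].all()),
    )
    return pd.concat([out, pd.DataFrame([overall])], ignore_index=True)


def trait_variation_summary(descriptives: pd.DataFrame) -> dict:
    """Cross-provenance variation summary for one trait.

    Returns the arithmetic mean of the per-provenance CVs, and the
    max/min fold ratio of the provenance with the widest absolute range
    (max - min).  Provenances whose minimum is <= 0 cannot contribute a
    fold ratio and are skipped with a warning flag in the output.
    """
    df = descriptives[descriptives["provenance"] != "Overall"]
    if df.empty:
        raise ValueError("no provenance rows")
    mean_cv = float(df["cv"].mean())
    ok = df[df["minimum"] > 0]
    skipped = sorted(set(df["provenance"]) - set(ok["provenance"]))
    if ok.empty:
        return dict(mean_cv=mean_cv, fold_ratio=np.nan,
                    widest_range_provenance=None, skipped=skipped)
    widths = ok["maximum"] - ok["minimum"]
    i = widths.idxmax()
    return dict(
        mean_cv=mean_cv,
        fold_ratio=float(ok.loc[i, "maximum"] / ok.loc[i, "minimum"]),
        widest_range_provenance=str(ok.loc[i, "provenance"]),
        skipped=skipped,
    )


@lru_cache(maxsize=4096)
def _duncan_quantile(alpha: float, span: int, df_e: int) -> float:
    """Studentized-range quantile at Duncan's protection level
    alpha_k = 1 - (1 - alpha)^(k-1); cached, as the quantile is expensive
    and depends only on (alpha, span, df)."""
    a_k = 1.0 - (1.0 - alpha) ** (span - 1)
    return float(stats.studentized_range.ppf(1.0 - a_k, span, df_e))


def _letters_from_homogeneous(order, homog) -> dict:
    """Standard letter display from the homogeneous-span matrix."""
    m = len(order)
    # maximal homogeneous intervals [i, j]
    intervals = []
    for i in range(m):
        j = i
        while j + 1 < m and homog[i][j + 1]:
            j += 1
        intervals.append((i, j))
    # keep only intervals not contained in an earlier (wider) one
    maximal = []
    for i, j in intervals:
        if not any(a <= i and j <= b for a, b in maximal):
            maximal.append((i, j))
    letters = {prov: "" for prov in order}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, (a, b) in enumerate(maximal):
        ch = alphabet[idx % len(alphabet)] * (idx // len(alphabet) + 1)
        for k in range(a, b + 1):
            letters[order[k]] += ch
    return letters


def duncan_mrt(data, trait: str, alpha: float = 0.05) -> DuncanResult:
    """Duncan's multiple range test on provenance means.

    Requires >= 2 provenances and positive residual degrees of freedom
    from the one-way (provenance) ANOVA.  Ties among means are broken by
    provenance code so the ranking is deterministic.
    """
    df = _trait_series(data, trait)
    groups = {p: g["value"].to_numpy(dtype=float)
              for p, g in df.groupby("provenance", sort=True)}
    if len(groups) < 2:
        raise ValueError("need >= 2 provenances")
    n_total = sum(len(v) for v in groups.values())
    df_e = n_total - len(groups)
    if df_e < 1:
        raise ValueError("residual df < 1; cannot run the test")
    ss_e = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values())
    ms_e = ss_e / df_e
    n_h = len(groups) / sum(1.0 / len(v) for v in groups.values())

    order = sorted(groups, key=lambda p: (-float(np.mean(groups[p])), p))
    means = [float(np.mean(groups[p])) for p in order]
    m = len(order)

    homog = [[False] * m for _ in range(m)]
    if ms_e <= 0:
        # degenerate: no residual variance; only exactly equal means group
        for i in range(m):
            homog[i][i] = True
            for j in range(i + 1, m):
                homog[i][j] = homog[j][i] = bool(means[i] == means[j])
    else:
        se = np.sqrt(ms_e / n_h)
        # step-down: a span of k means is homogeneous if its range is below
        # the Duncan critical range, or if a containing span already is
        for span in range(m, 1, -1):
            crit = _duncan_quantile(alpha, span, df_e) * se
            for i in range(0, m - span + 1):
                j = i + span - 1
                inside_homog = any(
                    homog[a][b] for a in range(0, i + 1)
                    for b in range(j, m) if (a, b) != (i, j) and b - a > j - i
                )
                if inside_homog or (means[i] - means[j]) <= crit:
                    homog[i][j] = homog[j][i] = True
        for i in range(m):
            homog[i][i] = True

    letters = _letters_from_homogeneous(order, homog)
    return DuncanResult(order=tuple(order), means=tuple(means),
                        letters=letters, alpha=alpha, ms_error=ms_e,
                        df_error=df_e, n_effective=n_h)
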