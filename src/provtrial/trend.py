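"""Binary quadratic trend-surface analysis of geographic trait variation.

A trend surface summarizes how a trait varies over the seed-source
geography by ordinary least squares on the six-term quadratic basis

    Z = b0 + b1*x + b2*y + b3*x^2 + b4*y^2 + b5*x*y,

with x = latitude (decimal degrees N) and y = longitude (decimal degrees
E), fitted directly on unprojected coordinates.  Observations are
individual trees (or wood samples), each tagged with its provenance's
coordinates — with only a handful of distinct locations the fit has a
small R^2 ("fitting coefficient") yet can be strongly significant, which
is exactly the regime these trials produce.  Significance is the overall
regression F test with (5, n - 6) degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["TrendSurfaceFit", "TrendSurfaceRegression", "fit_trend_surface",
           "evaluate_surface"]

TERMS = ("1", "x", "y", "x^2", "y^2", "x*y")


def _basis(lat, lon):
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    return np.column_stack([np.ones_like(lat), lat, lon, lat**2, lon**2, lat * lon])


@dataclass(frozen=True)
class TrendSurfaceFit:
    """Six coefficients (intercept, x, y, x^2, y^2, x*y) with fit stats."""

    coefficients: tuple[float, ...]
    r_squared: float
    p_value: float
    n: int

    def predict(self, lat, lon):
        B = _basis(np.atleast_1d(lat), np.atleast_1d(lon))
        out = B @ np.asarray(self.coefficients)
        return float(out[0]) if np.isscalar(lat) or np.ndim(lat) == 0 else out

    def equation(self, digits: int = 4) -> str:
        c = self.coefficients
        parts = [f"{c[0]:.{digits}g}"]
        for coef, term in zip(c[1:], TERMS[1:]):
            parts.append(f"{'+' if coef >= 0 else '-'} {abs(coef):.{digits}g}*{term}")
        return "Z = " + " ".join(parts)


class TrendSurfaceRegression(RegressorMixin, BaseEstimator):
    """Sklearn-style OLS on the binary quadratic geographic basis.

    ``fit`` takes ``X`` of shape (n, 2) — columns latitude, longitude —
    and the trait values ``y``.  Fitted attributes: ``coef_`` (6 terms,
    intercept first), ``r_squared_``, ``f_statistic_``, ``p_value_``,
    ``n_``.  A condition-number warning is emitted above 1e10 (raw
    degree-squared coordinates are badly scaled by construction; the fit
    itself uses a pivoted least-squares solve).
    """

    def __init__(self, cond_warn: float = 1e10):
        self.cond_warn = cond_warn

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2): latitude, longitude")
        n = len(y)
        if n < 7:
            raise ValueError("need >= 7 observations for the 6-term surface")
        if len(np.unique(X, axis=0)) < 3:
            raise ValueError("need >= 3 distinct locations")
        B = _basis(X[:, 0], X[:, 1])
        rank = np.linalg.matrix_rank(B)
        if rank < 6:
            raise ValueError(
                f"rank-deficient quadratic basis (rank {rank} < 6); "
                "locations are collinear or too few"
            )
        cond = np.linalg.cond(B)
        if cond > self.cond_warn:
            warnings.warn(f"ill-conditioned basis (cond={cond:.2e}); "
                          "consider centering coordinates", RuntimeWarning)
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        fitted = B @ coef
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        ss_res = float(np.sum((y - fitted) ** 2))
        if ss_tot == 0:
            r2, f_stat, p = 0.0, 0.0, 1.0
        else:
            r2 = 1.0 - ss_res / ss_tot
            df1, df2 = 5, n - 6
            if ss_res <= ss_tot * 1e-14:
                f_stat, p = np.inf, 0.0
            else:
                f_stat = ((ss_tot - ss_res) / df1) / (ss_res / df2)
                p = float(stats.f.sf(f_stat, df1, df2))
        self.coef_ = coef
        self.r_squared_ = float(r2)
        self.f_statistic_ = float(f_stat)
        self.p_value_ = float(max(p, np.finfo(float).tiny))
        self.n_ = n
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return _basis(X[:, 0], X[:, 1]) @ self.coef_

    @property
    def fit_(self) -> TrendSurfaceFit:
        return TrendSurfaceFit(coefficients=tuple(map(float, self.coef_)),
                               r_squared=self.r_squared_,
                               p_value=self.p_value_, n=self.n_)


def fit_trend_surface(observations) -> TrendSurfaceFit:
    """Fit the surface to (lat, lon, value) observations.

    ``observations`` is an iterable of triples or a DataFrame with
    columns ``latitude``, ``longitude`` and a single value column.
    """
    if isinstance(observations, pd.DataFrame):
        lat = observations["latitude"].to_numpy(dtype=float)
        lon = observations["longitude"].to_numpy(dtype=float)
        value_cols = [c for c in observations.columns
                      if c not in ("latitude", "longitude")]
        if len(value_cols) != 1:
            raise ValueError("frame must have exactly one value column")
        z = observations[value_cols[0]].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(observations), dtype=float)
        lat, lon, z = arr[:, 0], arr[:, 1], arr[:, 2]
    est = TrendSurfaceRegression().fit(np.column_stack([lat, lon]), z)
    return est.fit_


def evaluate_surface(fit: TrendSurfaceFit, lat_grid=None, lon_grid=None,
                     bounds=None, num: int = 100, pad: float = 0.5,
                     ) -> pd.DataFrame:
    """Evaluate a fitted surface on a lat/lon lattice.

    Either pass explicit 1-D ``lat_grid``/``lon_grid`` vectors, or
    ``bounds`` = (lat_min, lat_max, lon_min, lon_max) with ``num`` points
    per axis; ``pad`` (degrees) widens the bounds.  Returns a long-format
    frame (latitude, longitude, value) suitable for any contouring layer.
    """
    if lat_grid is None or lon_grid is None:
        if bounds is None:
            raise ValueError("need lat_grid/lon_grid or bounds")
        lat_min, lat_max, lon_min, lon_max = bounds
        lat_grid = np.linspace(lat_min - pad, lat_max + pad, num)
        lon_grid = np.linspace(lon_min - pad, lon_max + pad, num)
    LAT, LON = np.meshgrid(np.asarray(lat_grid), np.asarray(lon_grid),
                           indexing="ij")
    Z = _basis(LAT.ravel(), LON.ravel()) @ np.asarray(fit.coefficients)
    return pd.DataFrame({"latitude": LAT.ravel(), "longitude": LON.ravel(),
                         "value": Z})
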