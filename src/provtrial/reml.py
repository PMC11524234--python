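"""REML variance components for the provenance-trial mixed model.

The observation model for a trait measured on living trees of a
randomized-complete-block provenance trial is

    y = X beta + Z u + e,

with block as a fixed effect (intercept + block dummies), provenance and
optionally provenance-by-block interaction as independent random effects
(u ~ N(0, diag(V_P I, V_PB I))), and i.i.d. residuals e ~ N(0, V_e I).
The design is unbalanced: mortality makes plot counts n_ij unequal, so no
closed form exists and the components are estimated by restricted maximum
likelihood.

The estimator runs EM-REML accelerated by an average-information (AI)
step: each iteration computes both the EM update (monotone in the
restricted log-likelihood, but linearly convergent) and an AI/Newton
candidate, and keeps whichever has the higher restricted log-likelihood.
Since the EM candidate never decreases it, the log-likelihood path is
non-decreasing by construction.  All per-iteration quantities come from
one Cholesky factorization of the mixed-model-equation (MME) coefficient
matrix

    C = [[X'X, X'Z], [Z'X, Z'Z + D_lambda]],   lambda_k = V_e / V_k,

using the standard identities  P w = (w - T C^{-1} T' w) / V_e  with
T = [X, Z], and

    -2 l_R = (n - rank X) log V_e + sum_k q_k log(V_k / V_e)
             + log|C| + y'P y + const.

Components are constrained to [0, inf); a component pinned at the zero
boundary for several consecutive iterations is dropped and flagged NE
("not estimated, assumed zero").  Standard errors come from the inverse
average-information matrix at the optimum.

Covariance components for trait pairs use the variance-of-sum identity
Cov(a, b) = [Var(a + b) - Var(a) - Var(b)] / 2 applied to the provenance
(and error) components of three univariate fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.linalg import LinAlgError
from scipy import linalg
from sklearn.base import BaseEstimator

from .trial_data import TreeRecord, TrialDesign, records_to_frame

__all__ = [
    "VarComponents",
    "CovComponents",
    "ConvergenceError",
    "MixedModelREML",
    "fit_lmm_reml",
    "fit_bivariate_reml",
    "harmonic_mean_n",
    "growth_frame",
    "wood_frame",
]


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the last iterate."""

    def __init__(self, message, last_estimates=None, gradient_norm=None):
        super().__init__(message)
        self.last_estimates = last_estimates
        self.gradient_norm = gradient_norm


@dataclass
class VarComponents:
    """Univariate REML estimates for one trait.

    ``v_pb``/``se_pb`` are ``None`` when the model had no
    provenance-by-block term (the wood-trait model).  A component flagged
    in ``ne`` converged to the zero boundary and is reported as exactly 0.
    """

    trait: str
    v_p: float
    v_e: float
    v_pb: float | None = None
    se_p: float | None = None
    se_e: float | None = None
    se_pb: float | None = None
    ne: dict = field(default_factory=dict)
    loglik: float = float("nan")
    n_iter: int = 0
    n_obs: int = 0

    @property
    def total(self) -> float:
        return self.v_p + (self.v_pb or 0.0) + self.v_e


@dataclass
class CovComponents:
    """Provenance and error covariances for a trait pair, with the
    univariate components they came from."""

    trait_a: str
    trait_b: str
    cov_p: float | None
    cov_e: float
    vc_a: VarComponents
    vc_b: VarComponents
    vc_sum: VarComponents

    @property
    def ne(self) -> bool:
        return self.cov_p is None


def growth_frame(records: Sequence[TreeRecord]) -> pd.DataFrame:
    """Living trees as an analysis frame (provenance, block, dbh, height,
    volume)."""
    df = records_to_frame(records)
    df = df[df["alive"].astype(bool)].reset_index(drop=True)
    return df.drop(columns=["alive", "tree"], errors="ignore")


def wood_frame(samples) -> pd.DataFrame:
    """Wood samples as an analysis frame (provenance + trait columns)."""
    return records_to_frame(samples)


def _dummies(codes: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(codes))
    idx = {lv: i for i, lv in enumerate(levels)}
    Z = np.zeros((len(codes), len(levels)))
    Z[np.arange(len(codes)), [idx[c] for c in codes]] = 1.0
    return Z, levels


class _Workspace:
    """Precomputed cross-products for one response/design."""

    def __init__(self, y, X, Z_list):
        self.y = y
        self.X = X
        self.Z_list = Z_list
        self.n = len(y)
        self.p = X.shape[1]
        self.q = [Z.shape[1] for Z in Z_list]
        self.T = np.hstack([X] + Z_list) if Z_list else X
        self.TtT = self.T.T @ self.T
        self.Tty = self.T.T @ y
        self.yty = float(y @ y)
        # index slices of each random term inside T
        self.slices = []
        start = self.p
        for q in self.q:
            self.slices.append(slice(start, start + q))
            start += q

    def factor(self, v_terms, v_e):
        """Cholesky of the MME matrix for current components."""
        C = self.TtT.copy()
        for sl, vk in zip(self.slices, v_terms):
            lam = v_e / vk
            C[sl, sl] += np.eye(sl.stop - sl.start) * lam
        return linalg.cho_factor(C, lower=True)

    def logdet(self, cf):
        L = cf[0]
        return 2.0 * float(np.sum(np.log(np.diag(L))))


def _loglik(ws: _Workspace, cf, s, v_terms, v_e):
    """Restricted log-likelihood from the factored MME."""
    n, p = ws.n, ws.p
    ePy = (ws.yty - s @ ws.Tty) / v_e  # y'Py
    val = (n - p) * math.log(v_e) + ws.logdet(cf) + ePy
    for q, vk in zip(ws.q, v_terms):
        val += q * math.log(vk / v_e)
    return -0.5 * (val + (n - p) * math.log(2.0 * math.pi))


def _P_apply(ws: _Workspace, cf, W, v_e):
    """Apply the REML projection P to columns of W via the MME identity."""
    TtW = ws.T.T @ W
    return (W - ws.T @ linalg.cho_solve(cf, TtW)) / v_e


def _score_ai(ws: _Workspace, cf, s, active, v_terms, v_e):
    """REML score vector and average-information matrix for the active
    components (order: active random terms..., residual)."""
    y = ws.y
    ehat = y - ws.T @ s
    Py = ehat / v_e
    # tr(P) = (n - m + sum_k lambda_k tr(C^{kk})) / v_e
    Cinv = linalg.cho_solve(cf, np.eye(ws.TtT.shape[0]))
    m = ws.TtT.shape[0]
    trP = ws.n - m
    trPVk = []
    for j, k in enumerate(active):
        sl = ws.slices[k]
        lam = v_e / v_terms[j]
        tr_ckk = float(np.trace(Cinv[sl, sl]))
        trP += lam * tr_ckk
        # tr(P Z_k Z_k') = (tr(Z_k'Z_k) - tr(W' C^{-1} W)) / v_e, W = T'Z_k
        Wk = ws.TtT[:, sl]  # columns of T'T for Z_k (no ridge stored here)
        tr_pzz = (float(np.trace(ws.TtT[sl, sl]))
                  - float(np.sum(Wk * linalg.cho_solve(cf, Wk))))
        trPVk.append(tr_pzz / v_e)
    trP /= v_e

    # score
    score = []
    vs = []
    for j, k in enumerate(active):
        Zk = ws.Z_list[k]
        u = Zk.T @ Py
        score.append(-0.5 * (trPVk[j] - float(u @ u)))
        vs.append(Zk @ u)
    score.append(-0.5 * (trP - float(Py @ Py)))
    vs.append(Py)
    V = np.column_stack(vs)
    PV = _P_apply(ws, cf, V, v_e)
    AI = 0.5 * (V.T @ PV)
    return np.asarray(score), AI, Py


class MixedModelREML(BaseEstimator):
    """REML variance-component estimator for a provenance trial.

    Parameters
    ----------
    include_pb : bool, default True
        Fit a provenance-by-block interaction component.  Use ``False``
        for the wood-trait model, where each provenance contributes a few
        cored trees with no block replication and the interaction is
        structurally absent.
    include_block_fixed : bool, default True
        Put block in the fixed part (intercept + block dummies).  Ignored
        when the data carry no ``block`` column.
    tol : float, default 1e-8
        Relative parameter-change convergence threshold.
    loglik_tol : float, default 1e-10
        Alternative stop: absolute restricted-log-likelihood change.
    max_iter : int, default 500
    drop_after : int, default 5
        Iterations a component must sit at the zero boundary before it is
        dropped and flagged NE.
    use_ai : bool, default True
        Attempt the average-information step each iteration (falling back
        to plain EM whenever it does not improve the log-likelihood).

    Attributes
    ----------
    v_p_, v_pb_, v_e_ : float
        Estimated components (``v_pb_`` is None without the PB term).
    se_ : dict
        Standard errors from the inverse AI matrix, keys ``"p"``,
        ``"pb"``, ``"e"``.
    ne_ : dict
        Boundary flags per component.
    loglik_, loglik_path_, n_iter_, converged_ : fit diagnostics.
    """

    def __init__(self, include_pb=True, include_block_fixed=True, tol=1e-8,
                 loglik_tol=1e-10, max_iter=500, drop_after=5, use_ai=True):
        self.include_pb = include_pb
        self.include_block_fixed = include_block_fixed
        self.tol = tol
        self.loglik_tol = loglik_tol
        self.max_iter = max_iter
        self.drop_after = drop_after
        self.use_ai = use_ai

    # ------------------------------------------------------------------
    def _design(self, data: pd.DataFrame, response: str):
        y = np.asarray(data[response], dtype=float)
        if np.any(~np.isfinite(y)):
            raise ValueError(f"response '{response}' has missing values")
        if np.var(y) == 0:
            raise ValueError(f"response '{response}' is constant")
        n = len(y)
        has_block = "block" in data.columns and self.include_block_fixed
        if has_block:
            B, b_levels = _dummies(data["block"])
            X = np.hstack([np.ones((n, 1)), B[:, 1:]])  # drop-first coding
        else:
            X = np.ones((n, 1))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular fixed-effect design (block dummies)")
        Zp, p_levels = _dummies(data["provenance"])
        if len(p_levels) < 2:
            raise ValueError("need >= 2 provenance levels")
        Z_list = [Zp]
        names = ["p"]
        if self.include_pb:
            if "block" not in data.columns:
                raise ValueError("include_pb requires a block column")
            combo = data["block"].astype(str) + ":" + data["provenance"].astype(str)
            Zpb, _ = _dummies(combo)
            if Zpb.shape[1] < 2:
                raise ValueError("need >= 2 provenance-by-block cells")
            Z_list.append(Zpb)
            names.append("pb")
        if n < X.shape[1] + len(p_levels):
            raise ValueError("too few observations for the model")
        return y, X, Z_list, names

    def fit(self, data, response: str):
        """Fit the model to an analysis frame.

        Parameters
        ----------
        data : DataFrame with columns ``provenance`` (and ``block`` for the
            growth model) plus the response trait.
        response : name of the trait column.
        """
        y, X, Z_list, names = self._design(pd.DataFrame(data), response)
        ws = _Workspace(y, X, Z_list)
        vary = float(np.var(y, ddof=1))
        floor = 1e-10 * vary
        zero_tol = 1e-7 * vary

        K = len(Z_list)
        v_terms = [vary / (2.0 * K)] * K
        v_e = vary / 2.0
        active = list(range(K))
        pinned_count = {k: 0 for k in range(K)}
        dropped: set[int] = set()

        loglik_path = []
        converged = False
        it = 0
        cur_ll = -np.inf
        sub = ws
        for it in range(1, self.max_iter + 1):
            cf = sub.factor(v_terms, v_e)
            s = linalg.cho_solve(cf, sub.Tty)
            cur_ll = _loglik(sub, cf, s, v_terms, v_e)
            loglik_path.append(cur_ll)

            # --- EM candidate -------------------------------------------
            Cinv = linalg.cho_solve(cf, np.eye(sub.TtT.shape[0]))
            em_terms = []
            for j, k in enumerate(active):
                sl = sub.slices[j]
                u = s[sl]
                tr_ckk = float(np.trace(Cinv[sl, sl]))
                em_terms.append((float(u @ u) + v_e * tr_ckk) / sub.q[j])
            em_e = (sub.yty - float(s @ sub.Tty)) / (sub.n - sub.p)
            cand = [(em_terms, em_e)]

            # --- AI candidate -------------------------------------------
            if self.use_ai:
                try:
                    score, AI, _ = _score_ai(sub, cf, s,
                                             list(range(len(active))),
                                             v_terms, v_e)
                    step = np.linalg.solve(AI, score)
                    theta = np.array(v_terms + [v_e])
                    ai_theta = theta + step
                    ai_theta = np.maximum(ai_theta, floor)  # truncate at boundary
                    if ai_theta[-1] > 0:
                        cand.append((list(ai_theta[:-1]), float(ai_theta[-1])))
                except LinAlgError:
                    pass

            # pick the candidate with the higher restricted loglik
            best, best_ll = None, -np.inf
            for terms_c, e_c in cand:
                terms_c = [max(t, floor) for t in terms_c]
                e_c = max(e_c, floor)
                try:
                    cf_c = sub.factor(terms_c, e_c)
                    s_c = linalg.cho_solve(cf_c, sub.Tty)
                    ll_c = _loglik(sub, cf_c, s_c, terms_c, e_c)
                except LinAlgError:
                    continue
                if ll_c > best_ll:
                    best, best_ll = (terms_c, e_c), ll_c
            if best is None:  # pragma: no cover - numerically degenerate
                raise ConvergenceError("all candidate updates failed",
                                       last_estimates=(v_terms, v_e))
            new_terms_active, new_e = best

            old = np.array(v_terms + [v_e])
            new = np.array(new_terms_active + [new_e])
            rel = float(np.max(np.abs(new - old) / (np.abs(old) + 1e-300)))
            dll = best_ll - cur_ll

            v_terms = list(new_terms_active)
            v_e = new_e

            # boundary bookkeeping on the active set
            to_drop = []
            for j, k in enumerate(list(active)):
                if v_terms[j] < zero_tol:
                    pinned_count[k] += 1
                    if pinned_count[k] >= self.drop_after:
                        to_drop.append(k)
                else:
                    pinned_count[k] = 0
            if to_drop:
                for k in to_drop:
                    j = active.index(k)
                    active.pop(j)
                    v_terms.pop(j)
                    dropped.add(k)
                sub = _Workspace(y, X, [Z_list[k] for k in active]) if active else None
                if not active:
                    # pure fixed-effects residual model
                    v_e = self._residual_only(y, X)
                    converged = True
                    cur_ll = self._residual_loglik(y, X, v_e)
                    loglik_path.append(cur_ll)
                    break
                continue

            if rel < self.tol or abs(dll) < self.loglik_tol:
                converged = True
                cur_ll = best_ll
                break

        if not converged:
            sub_f = _Workspace(y, X, [Z_list[k] for k in active])
            cf = sub_f.factor(v_terms, v_e)
            s = linalg.cho_solve(cf, sub_f.Tty)
            score, _, _ = _score_ai(sub_f, cf, s, list(range(len(active))),
                                    v_terms, v_e)
            raise ConvergenceError(
                f"REML did not converge in {self.max_iter} iterations",
                last_estimates=(dict(zip([names[k] for k in active], v_terms)), v_e),
                gradient_norm=float(np.linalg.norm(score)),
            )

        # assemble estimates over the original component list
        est = {}
        for k, name in enumerate(names):
            if k in dropped:
                est[name] = 0.0
            else:
                est[name] = v_terms[active.index(k)]
        est["e"] = v_e

        se = self._standard_errors(ws, names, est)

        self.response_ = response
        self.component_names_ = names
        self.v_p_ = est["p"]
        self.v_pb_ = est.get("pb") if self.include_pb else None
        self.v_e_ = est["e"]
        self.se_ = se
        self.ne_ = {name: (k in dropped) for k, name in enumerate(names)}
        self.ne_["e"] = False
        self.loglik_ = float(cur_ll)
        self.loglik_path_ = np.asarray(loglik_path)
        self.n_iter_ = it
        self.converged_ = converged
        self.n_obs_ = ws.n
        return self

    # ------------------------------------------------------------------
    @staticmethod
    def _residual_only(y, X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r) / (len(y) - X.shape[1])

    @staticmethod
    def _residual_loglik(y, X, v_e):
        n, p = len(y), X.shape[1]
        r = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        _, logdet_xx = np.linalg.slogdet(X.T @ X)
        # -2 l_R = (n-p) log v_e + log|X'X| + r'r/v_e + const
        val = ((n - p) * math.log(v_e) + logdet_xx + float(r @ r) / v_e)
        return -0.5 * (val + (n - p) * math.log(2 * math.pi))

    def _standard_errors(self, ws: _Workspace, names, est):
        """SEs from the inverse AI matrix at the optimum, with boundary
        components held at (numerical) zero but still differentiated."""
        vary = float(np.var(ws.y, ddof=1))
        eps = 1e-12 * vary
        v_terms = [max(est[name], eps) for name in names]
        v_e = est["e"]
        try:
            cf = ws.factor(v_terms, v_e)
            s = linalg.cho_solve(cf, ws.Tty)
            _, AI, _ = _score_ai(ws, cf, s, list(range(len(names))), v_terms, v_e)
            cov = np.linalg.pinv(AI)
            ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except LinAlgError:  # pragma: no cover
            ses = np.full(len(names) + 1, np.nan)
        out = {name: float(ses[k]) for k, name in enumerate(names)}
        out["e"] = float(ses[-1])
        return out

    # convenience -------------------------------------------------------
    @property
    def var_components_(self) -> VarComponents:
        return VarComponents(
            trait=self.response_,
            v_p=self.v_p_,
            v_pb=self.v_pb_,
            v_e=self.v_e_,
            se_p=self.se_.get("p"),
            se_pb=self.se_.get("pb"),
            se_e=self.se_.get("e"),
            ne={k: v for k, v in self.ne_.items()},
            loglik=self.loglik_,
            n_iter=self.n_iter_,
            n_obs=self.n_obs_,
        )


def fit_lmm_reml(data, trait: str, model: str = "growth", **options) -> VarComponents:
    """Fit the provenance mixed model by REML and return the components.

    ``model="growth"`` fits block (fixed) + provenance + provenance-by-block;
    ``model="wood"`` fits intercept + provenance only (no block structure in
    the wood-sample design).
    """
    if model not in ("growth", "wood"):
        raise ValueError(f"unknown model {model!r}")
    if not isinstance(data, pd.DataFrame):
        data = growth_frame(data) if model == "growth" else wood_frame(data)
    est = MixedModelREML(
        include_pb=(model == "growth"),
        include_block_fixed=(model == "growth"),
        **options,
    )
    est.fit(data, trait)
    return est.var_components_


def fit_bivariate_reml(data, trait_a: str, trait_b: str, model: str = "growth",
                       **options) -> CovComponents:
    """Provenance and error covariance components for a trait pair.

    Uses the variance-of-sum identity on three univariate REML fits.
    Implied correlations are kept in [-1, 1] by clipping the covariance at
    the geometric-mean bound.  If either marginal provenance variance is
    at the zero boundary the provenance covariance is flagged NE (None).
    """
    if not isinstance(data, pd.DataFrame):
        data = growth_frame(data) if model == "growth" else wood_frame(data)
    data = data.copy()
    # traits can live on different scales; standardize the sum trait by
    # nothing -- the identity is exact on the raw scale
    sum_col = f"__sum_{trait_a}_{trait_b}"
    data[sum_col] = data[trait_a].astype(float) + data[trait_b].astype(float)
    vc_a = fit_lmm_reml(data, trait_a, model=model, **options)
    vc_b = fit_lmm_reml(data, trait_b, model=model, **options)
    vc_s = fit_lmm_reml(data, sum_col, model=model, **options)

    cov_e = 0.5 * (vc_s.v_e - vc_a.v_e - vc_b.v_e)
    bound_e = math.sqrt(vc_a.v_e * vc_b.v_e)
    cov_e = float(np.clip(cov_e, -bound_e, bound_e))

    if vc_a.ne.get("p") or vc_b.ne.get("p") or vc_a.v_p <= 0 or vc_b.v_p <= 0:
        cov_p = None
    else:
        cov_p = 0.5 * (vc_s.v_p - vc_a.v_p - vc_b.v_p)
        bound_p = math.sqrt(vc_a.v_p * vc_b.v_p)
        cov_p = float(np.clip(cov_p, -bound_p, bound_p))
    return CovComponents(trait_a=trait_a, trait_b=trait_b, cov_p=cov_p,
                         cov_e=cov_e, vc_a=vc_a, vc_b=vc_b, vc_sum=vc_s)


def harmonic_mean_n(design: TrialDesign) -> float:
    """Harmonic-mean surviving plot size n_h.

    n_h = (number of non-empty plots) / sum over those plots of 1/n_ij.
    Empty plots are excluded from the sum with the numerator reduced
    accordingly (the harmonic mean is undefined at zero).  Balanced data
    give n_h = n exactly.
    """
    counts = [c for c in design.n_ij.values() if c > 0]
    if not counts:
        raise ValueError("all plots are empty; n_h undefined")
    return len(counts) / sum(1.0 / c for c in counts)
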