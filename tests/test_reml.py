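"""REML variance components: closed-form oracles, likelihood
monotonicity, invariances and an external mixed-model cross-check."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from provtrial.reml import (ConvergenceError, MixedModelREML,
                            fit_bivariate_reml, fit_lmm_reml, growth_frame,
                            harmonic_mean_n)
from provtrial.simulate import SimulationConfig, simulate_trial
from provtrial.trial_data import TrialDesign


def _one_way(p=6, n=20, v_p=4.0, v_e=9.0, seed=1):
    rng = np.random.default_rng(seed)
    eff = rng.normal(0, np.sqrt(v_p), p)
    rows = []
    for j in range(p):
        for _ in range(n):
            rows.append(dict(provenance=f"P{j}",
                             y=10 + eff[j] + rng.normal(0, np.sqrt(v_e))))
    return pd.DataFrame(rows), n


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_balanced_reml_equals_anova_closed_form(seed):
    """On a balanced one-way design REML reproduces the method-of-moments
    estimators v_e = MS_within, v_p = (MS_between - MS_within)/n."""
    df, n = _one_way(seed=seed)
    vc = fit_lmm_reml(df, "y", model="wood")
    g = df.groupby("provenance")["y"]
    ms_w = g.apply(lambda v: v.var(ddof=1)).mean()
    ms_b = n * g.mean().var(ddof=1)
    assert vc.v_e == pytest.approx(ms_w, abs=1e-6)
    assert vc.v_p == pytest.approx((ms_b - ms_w) / n, abs=1e-6)


def test_loglik_never_decreases_across_iterations(small_trial):
    records, _ = small_trial
    frame = growth_frame(records)
    for trait in ("dbh", "height"):
        est = MixedModelREML().fit(frame, trait)
        steps = np.diff(est.loglik_path_)
        assert steps.min() > -1e-6 * max(1.0, abs(est.loglik_))


def test_estimates_invariant_to_order_and_shift(small_trial):
    records, _ = small_trial
    frame = growth_frame(records)
    vc = fit_lmm_reml(frame, "dbh")
    shuffled = frame.sample(frac=1.0, random_state=0).reset_index(drop=True)
    vc2 = fit_lmm_reml(shuffled, "dbh")
    shifted = frame.assign(dbh=frame["dbh"] + 100.0)
    vc3 = fit_lmm_reml(shifted, "dbh")
    for other in (vc2, vc3):
        assert other.v_p == pytest.approx(vc.v_p, rel=1e-5, abs=1e-8)
        assert other.v_pb == pytest.approx(vc.v_pb, rel=1e-5, abs=1e-8)
        assert other.v_e == pytest.approx(vc.v_e, rel=1e-5, abs=1e-8)


def test_agrees_with_lme4_on_unbalanced_trial(tmp_path, small_trial):
    """Independent cross-check: lme4 REML on the same unbalanced data."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript unavailable; cross-check cannot run")
    records, _ = small_trial
    frame = growth_frame(records)
    csv = tmp_path / "trial.csv"
    frame.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv('{csv}')
        d$block <- factor(d$block)
        m <- lmer(dbh ~ block + (1|provenance) + (1|provenance:block),
                  data=d, REML=TRUE,
                  control=lmerControl(check.conv.singular='ignore'))
        vc <- as.data.frame(VarCorr(m))
        cat(vc$vcov[vc$grp=='provenance'],
            vc$vcov[vc$grp=='provenance:block'],
            vc$vcov[vc$grp=='Residual'], sep='\\n')
    """))
    out = subprocess.run(["Rscript", "--vanilla", str(script)],
                         capture_output=True, text=True, check=True)
    r_vp, r_vpb, r_ve = (float(x) for x in out.stdout.split())
    vc = fit_lmm_reml(frame, "dbh")
    scale = vc.v_e
    assert vc.v_p == pytest.approx(r_vp, abs=1e-4 * scale)
    assert vc.v_pb == pytest.approx(r_vpb, abs=1e-4 * scale)
    assert vc.v_e == pytest.approx(r_ve, abs=1e-4 * scale)


def test_zero_provenance_variance_reaches_boundary():
    """Simulated with v_p = 0, the provenance component is flagged NE in a
    substantial share of replicates and is near zero on average."""
    ne, est = 0, []
    for seed in range(20):
        cfg = SimulationConfig(p=8, b=6, n=4, traits=("dbh",),
                               grand_mean=(12.0,), g_p=((0.0,),),
                               v_pb=(0.3,), r=((6.0,),), survival=1.0,
                               seed=400 + seed)
        records, _ = simulate_trial(cfg)
        vc = fit_lmm_reml(growth_frame(records), "dbh")
        ne += vc.ne["p"]
        est.append(vc.v_p)
    assert ne >= 5
    assert np.mean(est) < 0.35  # half-normal mass near the boundary


def test_nonconvergence_raises_with_last_iterate(small_trial):
    records, _ = small_trial
    frame = growth_frame(records)
    with pytest.raises(ConvergenceError) as err:
        MixedModelREML(max_iter=1, tol=0.0, loglik_tol=0.0).fit(frame, "dbh")
    assert err.value.last_estimates is not None
    assert err.value.gradient_norm is not None


def test_constant_response_rejected(small_trial):
    records, _ = small_trial
    frame = growth_frame(records).assign(flat=1.0)
    with pytest.raises(ValueError, match="constant"):
        fit_lmm_reml(frame, "flat")


def test_reported_se_calibrated_for_identified_components(recovery_study):
    """Across 200 replicates the empirical spread of the well-identified
    components (v_p, v_e) matches the mean AI-based SE within 30%."""
    est = recovery_study["estimates"]
    ses = recovery_study["ses"]
    for col in (0, 2):  # v_p, v_e
        empirical = est[:, col].std(ddof=1)
        reported = np.nanmean(ses[:, col].astype(float))
        assert abs(empirical - reported) <= 0.3 * reported


def test_bivariate_self_pair_gives_unit_correlation(small_trial):
    records, _ = small_trial
    frame = growth_frame(records)
    frame["dbh2"] = frame["dbh"]
    cc = fit_bivariate_reml(frame, "dbh", "dbh2")
    assert cc.cov_p == pytest.approx(cc.vc_a.v_p, rel=1e-3)
    assert cc.cov_p / np.sqrt(cc.vc_a.v_p * cc.vc_b.v_p) == pytest.approx(1.0, abs=1e-6)


def test_bivariate_independent_traits_have_null_covariance():
    covs = []
    for seed in range(30):
        cfg = SimulationConfig(
            p=10, b=10, n=5, traits=("dbh", "height"),
            grand_mean=(12.5, 12.0),
            g_p=((0.5, 0.0), (0.0, 0.3)), v_pb=(0.1, 0.1),
            r=((8.0, 0.0), (0.0, 5.0)), survival=0.9, seed=600 + seed)
        records, _ = simulate_trial(cfg)
        cc = fit_bivariate_reml(growth_frame(records), "dbh", "height")
        if cc.cov_p is not None:
            covs.append(cc.cov_p)
    mc_se = np.std(covs, ddof=1) / np.sqrt(len(covs))
    assert abs(np.mean(covs)) <= max(3 * mc_se, 0.05)


def test_harmonic_mean_n_balanced_and_hand_value():
    balanced = TrialDesign(p=2, b=2, n=3,
                           n_ij={(1, "A"): 3, (1, "B"): 3,
                                 (2, "A"): 3, (2, "B"): 3})
    assert harmonic_mean_n(balanced) == pytest.approx(3.0)
    uneven = TrialDesign(p=2, b=2, n=4,
                         n_ij={(1, "A"): 2, (1, "B"): 4,
                               (2, "A"): 4, (2, "B"): 4})
    assert harmonic_mean_n(uneven) == pytest.approx(3.2)


def test_harmonic_mean_n_excludes_empty_plots():
    design = TrialDesign(p=2, b=2, n=4,
                         n_ij={(1, "A"): 2, (1, "B"): 4,
                               (2, "A"): 4, (2, "B"): 0})
    # three counted plots: 3 / (1/2 + 1/4 + 1/4)
    assert harmonic_mean_n(design) == pytest.approx(3.0)
    empty = TrialDesign(p=1, b=1, n=4, n_ij={(1, "A"): 0})
    with pytest.raises(ValueError):
        harmonic_mean_n(empty)
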