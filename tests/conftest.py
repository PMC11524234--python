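"""Shared fixtures: small deterministic trials and the 200-replicate
parameter-recovery studies reused across estimator tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from provtrial.quantgen import genetic_correlation, provenance_heritability
from provtrial.reml import (fit_bivariate_reml, fit_lmm_reml, growth_frame,
                            harmonic_mean_n)
from provtrial.simulate import SimulationConfig, simulate_trial
from provtrial.trial_data import validate_trial

STUDY_TRUTH = dict(v_p=0.47, v_pb=0.08, v_e=8.97)
RG_TRUE = 0.8
N_REPS = 200


def univariate_study_config(seed: int) -> SimulationConfig:
    """One replicate of the study-condition trial, single DBH-like trait."""
    return SimulationConfig(
        p=10, b=10, n=5, traits=("dbh",), grand_mean=(12.52,),
        g_p=((STUDY_TRUTH["v_p"],),), v_pb=(STUDY_TRUTH["v_pb"],),
        r=((STUDY_TRUTH["v_e"],),), survival=0.8, seed=seed,
    )


def bivariate_study_config(seed: int) -> SimulationConfig:
    """Two growth-like traits with genetic correlation RG_TRUE."""
    cov = RG_TRUE * np.sqrt(0.47 * 0.23)
    return SimulationConfig(
        p=10, b=10, n=5, traits=("dbh", "height"),
        grand_mean=(12.52, 11.98),
        g_p=((0.47, cov), (cov, 0.23)), v_pb=(0.08, 0.26),
        r=((8.97, 0.0), (0.0, 5.46)), survival=0.8, seed=seed,
    )


@pytest.fixture(scope="session")
def recovery_study():
    """200 replicate REML fits at the study conditions.

    Returns a dict of arrays: estimated components, their reported SEs,
    per-replicate heritability, harmonic-mean plot sizes and the realized
    (true) provenance-effect variances.
    """
    rows, ses, nhs, h2s, true_var = [], [], [], [], []
    for i in range(N_REPS):
        records, truth = simulate_trial(univariate_study_config(20_000 + i))
        frame = growth_frame(records)
        design = validate_trial(records)
        nh = harmonic_mean_n(design)
        vc = fit_lmm_reml(frame, "dbh")
        rows.append((vc.v_p, vc.v_pb, vc.v_e))
        ses.append((vc.se_p, vc.se_pb, vc.se_e))
        nhs.append(nh)
        h2s.append(provenance_heritability(vc, n_h=nh, b=design.b))
        true_var.append(float(np.var(truth["prov_effects"][:, 0], ddof=1)))
    return dict(
        estimates=np.array(rows), ses=np.array(ses), n_h=np.array(nhs),
        h2=np.array(h2s), true_prov_var=np.array(true_var),
    )


@pytest.fixture(scope="session")
def rg_recovery_study():
    """200 replicate genetic-correlation estimates at true r_g = 0.8."""
    rgs = []
    for i in range(N_REPS):
        records, _ = simulate_trial(bivariate_study_config(31_000 + i))
        cc = fit_bivariate_reml(growth_frame(records), "dbh", "height")
        r, _ = genetic_correlation(cc)
        if r is not None:
            rgs.append(r)
    return np.array(rgs)


@pytest.fixture
def small_trial():
    """A compact deterministic trial (5 provenances x 4 blocks x 4 trees)."""
    cfg = SimulationConfig(
        p=5, b=4, n=4, traits=("dbh", "height"),
        grand_mean=(12.5, 12.0),
        g_p=((0.6, 0.2), (0.2, 0.4)), v_pb=(0.1, 0.1),
        r=((6.0, 2.0), (2.0, 4.0)), survival=0.9, seed=99,
    )
    records, truth = simulate_trial(cfg)
    return records, truth


@pytest.fixture
def two_group_frame():
    """Two clearly separated groups for post-hoc test checks."""
    rng = np.random.default_rng(5)
    return pd.DataFrame({
        "provenance": ["A"] * 30 + ["B"] * 30,
        "y": np.concatenate([rng.normal(10, 1, 30), rng.normal(20, 1, 30)]),
    })
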