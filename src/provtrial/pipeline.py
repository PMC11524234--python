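"""End-to-end trial analysis: simulate or ingest, derive, summarize,
estimate, select, map.

``run_pipeline`` drives the full chain on one growth table (and
optionally a wood table), writing the six report tables a provenance
analysis produces — descriptives with Duncan letters, variance
components with heritability and CV_G, the correlation matrix, the gain
report, trend-surface equations and a prediction lattice — plus a JSON
manifest recording the seed, package version and per-stage row counts.
The same configuration and seed always produce a byte-identical bundle.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .quantgen import (correlation_matrix, genetic_cv, provenance_heritability,
                       select_superior)
from .reml import (fit_bivariate_reml, fit_lmm_reml, growth_frame,
                   harmonic_mean_n)
from .simulate import SimulationConfig, default_growth_config, simulate_trial
from .summaries import duncan_mrt, provenance_descriptives
from .trend import evaluate_surface, fit_trend_surface
from .trial_data import read_trial_table, validate_trial
from .wood_traits import add_volume

log = logging.getLogger("provtrial")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """What to analyse and how.

    Either ``growth_path`` (a growth CSV) or ``simulation`` (a
    :class:`~provtrial.simulate.SimulationConfig`) must be given; with
    neither, the default study-condition simulation is run with ``seed``.
    """

    growth_path: str | None = None
    provenance_path: str | None = None
    simulation: SimulationConfig | None = None
    traits: tuple[str, ...] = ("dbh", "height", "volume")
    alpha: float = 0.05
    selection_pairs: tuple[tuple[str, str], ...] = (("volume", "dbh"),)
    correlate: bool = True
    trend: bool = False
    grid: int = 100
    out_dir: str = "provtrial_out"
    seed: int = 0

    def __post_init__(self):
        for a, b in self.selection_pairs:
            if a not in self.traits or b not in self.traits:
                raise ValueError(f"selection pair ({a}, {b}) not in traits")


def _stage(manifest, name, t0, rows_in, rows_out, **extra):
    dt = time.perf_counter() - t0
    log.info("stage=%s wall=%.2fs rows_in=%d rows_out=%d", name, dt,
             rows_in, rows_out)
    manifest["stages"].append(dict(stage=name, rows_in=rows_in,
                                   rows_out=rows_out, **extra))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns the manifest dict (also written as ``manifest.json``).  Any
    stage failure raises with the stage name; the partial manifest is
    still written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed, "stages": []}
    stage = "ingest"
    try:
        # ---- ingest / simulate ---------------------------------------
        t0 = time.perf_counter()
        if config.growth_path is not None:
            provs = None
            if config.provenance_path:
                provs = read_trial_table(config.provenance_path, "provenance")
            records = read_trial_table(config.growth_path, "growth", provs)
        else:
            sim = config.simulation or default_growth_config(seed=config.seed)
            if sim.seed is None:
                sim.seed = config.seed
            records, _ = simulate_trial(sim)
        _stage(manifest, stage, t0, 0, len(records))

        # ---- derive ---------------------------------------------------
        stage = "derive"
        t0 = time.perf_counter()
        records = add_volume(records)
        design = validate_trial(records)
        frame = growth_frame(records)
        n_h = harmonic_mean_n(design)
        _stage(manifest, stage, t0, len(records), len(frame),
               p=design.p, b=design.b, n_h=round(n_h, 4))

        # ---- summarize ------------------------------------------------
        stage = "summarize"
        t0 = time.perf_counter()
        tables = []
        for trait in config.traits:
            desc = provenance_descriptives(frame, trait)
            mrt = duncan_mrt(frame, trait, alpha=config.alpha)
            desc.insert(0, "trait", trait)
            desc["letters"] = desc["provenance"].map(mrt.letters).fillna("")
            tables.append(desc)
        descriptives = pd.concat(tables, ignore_index=True)
        descriptives.to_csv(out / "descriptives.csv", index=False)
        _stage(manifest, stage, t0, len(frame), len(descriptives))

        # ---- variance components -------------------------------------
        stage = "varcomp"
        t0 = time.perf_counter()
        rows = []
        vcs = {}
        for trait in config.traits:
            vc = fit_lmm_reml(frame, trait, model="growth")
            vcs[trait] = vc
            mean = float(frame[trait].mean())
            rows.append(dict(
                trait=trait,
                v_p=vc.v_p, se_p=vc.se_p, v_pb=vc.v_pb, se_pb=vc.se_pb,
                v_e=vc.v_e, se_e=vc.se_e,
                ne_p=vc.ne.get("p", False), ne_pb=vc.ne.get("pb", False),
                h2=(provenance_heritability(vc, n_h=n_h, b=design.b)
                    if vc.total > 0 else float("nan")),
                cv_g=genetic_cv(vc.v_p, mean) if mean > 0 else float("nan"),
                n_h=n_h, loglik=vc.loglik, n_iter=vc.n_iter,
            ))
        varcomp = pd.DataFrame(rows)
        varcomp.to_csv(out / "varcomp.csv", index=False)
        _stage(manifest, stage, t0, len(frame), len(varcomp))

        # ---- correlations --------------------------------------------
        if config.correlate and len(config.traits) > 1:
            stage = "correlate"
            t0 = time.perf_counter()
            ccs = {}
            for a, b in combinations(config.traits, 2):
                ccs[(a, b)] = fit_bivariate_reml(frame, a, b, model="growth")
            corr = correlation_matrix(ccs, list(config.traits))
            corr.to_csv(out / "correlations.csv")
            _stage(manifest, stage, t0, len(frame), len(corr))

        # ---- selection ------------------------------------------------
        stage = "select"
        t0 = time.perf_counter()
        means = (descriptives[descriptives["provenance"] != "Overall"]
                 .pivot(index="provenance", columns="trait", values="mean"))
        sel_rows = []
        for a, b in config.selection_pairs:
            rep = select_superior(means, a, b, purpose=f"{a}+{b}")
            for trait in means.columns:
                sel_rows.append(dict(
                    purpose=rep.purpose, trait=trait,
                    overall_mean=rep.overall_means.get(trait),
                    superior=";".join(rep.superior),
                    superior_mean=rep.superior_means.get(trait),
                    gain_pct=rep.gains.get(trait),
                ))
        selection = pd.DataFrame(sel_rows)
        selection.to_csv(out / "selection.csv", index=False)
        _stage(manifest, stage, t0, len(means), len(selection))

        # ---- trend surfaces ------------------------------------------
        if config.trend:
            stage = "trend"
            t0 = time.perf_counter()
            if config.provenance_path:
                provs = read_trial_table(config.provenance_path, "provenance")
                coords = {p.code: (p.latitude, p.longitude) for p in provs}
            elif config.simulation and config.simulation.provenance_coords:
                coords = config.simulation.provenance_coords
            else:
                raise ValueError("trend stage needs provenance coordinates")
            tr_rows = []
            df = frame.copy()
            df["latitude"] = df["provenance"].map(lambda c: coords[c][0])
            df["longitude"] = df["provenance"].map(lambda c: coords[c][1])
            for trait in config.traits:
                fit = fit_trend_surface(df[["latitude", "longitude", trait]])
                tr_rows.append(dict(trait=trait,
                                    **{f"b{i}": c for i, c in
                                       enumerate(fit.coefficients)},
                                    r_squared=fit.r_squared,
                                    p_value=fit.p_value, n=fit.n))
                lat = df["latitude"]
                lon = df["longitude"]
                lattice = evaluate_surface(
                    fit, bounds=(lat.min(), lat.max(), lon.min(), lon.max()),
                    num=config.grid)
                lattice.to_csv(out / f"surface_{trait}.csv", index=False)
            trend = pd.DataFrame(tr_rows)
            trend.to_csv(out / "trend.csv", index=False)
            _stage(manifest, stage, t0, len(df), len(trend))

        # manifest self-consistency: recorded counts match tables written
        manifest["tables"] = sorted(p.name for p in out.glob("*.csv"))
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
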