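"""Synthetic provenance trials with the exact variance structure the
mixed model assumes.

The generator exists so every stage of the pipeline — derived traits,
descriptives, REML, heritability, correlations, selection, trend
surfaces — can be exercised and validated without the original field
data.  A simulated phenotype of tree k in plot (block i, provenance j) is

    y_ijk = grand_mean + block_i + prov_j + pb_ij + e_ijk

with provenance effects drawn once per trial from MVN(0, G_P) across
traits, provenance-by-block effects N(0, V_PB) independently per trait,
and residuals MVN(0, R) per tree.  Blocks are fixed draws (block is a
fixed effect in the analysis model); survival is i.i.d. Bernoulli per
tree, which is what produces the unbalanced plot counts n_ij.

All randomness flows from one seeded generator in a fixed draw order
(blocks, provenance effects, provenance-by-block effects, residuals,
survival), so a seed fully determines a trial.

Defaults mirror the study conditions the package targets: a 10-provenance
x 10-block x 5-tree trial with survival 0.8 and DBH/height-like traits
whose components are the trial's own published estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trial_data import TreeRecord, WoodSample

__all__ = [
    "SimulationConfig",
    "simulate_trial",
    "simulate_wood_samples",
    "default_growth_config",
    "default_wood_config",
]

# Published variance components for the growth traits (DBH cm, H m) and
# their genetic/phenotypic correlation structure, used as defaults so a
# default simulation is a realistic trial.
_DBH = dict(mean=12.52, v_p=0.47, v_pb=0.08, v_e=8.97)
_H = dict(mean=11.98, v_p=0.23, v_pb=0.26, v_e=5.46)
_RG_DBH_H = 0.97
_RE_DBH_H = 0.86  # residual correlation implied by the phenotypic 0.87


def _check_psd(mat, name):
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(mat)
    if np.min(w) < -1e-10 * max(1.0, np.max(np.abs(w))):
        raise ValueError(f"{name} is not positive semi-definite")
    return mat


@dataclass
class SimulationConfig:
    """Parameters of one synthetic trial.

    Trait names must be record fields: growth trials use ``dbh``/``height``
    (volume is derived, not simulated), wood simulations any of the
    :class:`~provtrial.trial_data.WoodSample` measurement fields.

    ``block_effects`` may be an explicit vector (length ``b``) or ``None``,
    in which case blocks are drawn once from N(0, ``block_sd``^2) and then
    treated as fixed.  ``provenance_coords`` plus ``surface_coefs`` add a
    deterministic geographic mean structure (the six-coefficient quadratic
    in latitude/longitude) on top of the random provenance effects.
    """

    p: int = 10
    b: int = 10
    n: int = 5
    traits: tuple[str, ...] = ("dbh",)
    grand_mean: tuple[float, ...] = (12.52,)
    g_p: Sequence[Sequence[float]] = ((0.47,),)
    v_pb: tuple[float, ...] = (0.08,)
    r: Sequence[Sequence[float]] = ((8.97,),)
    survival: float = 0.8
    seed: int | None = None
    block_effects: tuple[float, ...] | None = None
    block_sd: float = 1.0
    random_blocks: bool = True  # draw block effects (still analysed as fixed)
    provenance_codes: tuple[str, ...] | None = None
    provenance_coords: dict[str, tuple[float, float]] | None = None
    surface_coefs: dict[str, tuple[float, ...]] | None = None

    def __post_init__(self):
        t = len(self.traits)
        if len(self.grand_mean) != t or len(self.v_pb) != t:
            raise ValueError("grand_mean and v_pb must have one entry per trait")
        g = _check_psd(self.g_p, "G_P")
        r = _check_psd(self.r, "R")
        if g.shape[0] != t or r.shape[0] != t:
            raise ValueError("G_P and R dimensions must equal the number of traits")
        if any(v < 0 for v in self.v_pb):
            raise ValueError("V_PB must be non-negative")
        if not 0.0 < self.survival <= 1.0:
            raise ValueError("survival must be in (0, 1]")
        if self.p < 2 or self.b < 1 or self.n < 1:
            raise ValueError("need p >= 2, b >= 1, n >= 1")

    @property
    def codes(self) -> tuple[str, ...]:
        if self.provenance_codes is not None:
            if len(self.provenance_codes) != self.p:
                raise ValueError("provenance_codes length must equal p")
            return self.provenance_codes
        return tuple(f"P{j + 1:02d}" for j in range(self.p))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("traits", "grand_mean", "v_pb", "block_effects",
                    "provenance_codes"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def default_growth_config(seed: int | None = None, **overrides) -> SimulationConfig:
    """The study-condition growth trial: 10 x 10 x 5, survival 0.8,
    correlated DBH- and height-like traits."""
    cov_g = _RG_DBH_H * np.sqrt(_DBH["v_p"] * _H["v_p"])
    cov_e = _RE_DBH_H * np.sqrt(_DBH["v_e"] * _H["v_e"])
    cfg = dict(
        p=10, b=10, n=5,
        traits=("dbh", "height"),
        grand_mean=(_DBH["mean"], _H["mean"]),
        g_p=((_DBH["v_p"], cov_g), (cov_g, _H["v_p"])),
        v_pb=(_DBH["v_pb"], _H["v_pb"]),
        r=((_DBH["v_e"], cov_e), (cov_e, _H["v_e"])),
        survival=0.8,
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def default_wood_config(seed: int | None = None, **overrides) -> SimulationConfig:
    """Wood-density sampling defaults (per-tree WBD, g/cm^3)."""
    cfg = dict(
        p=10, b=1, n=5,
        traits=("wbd",),
        grand_mean=(0.339,),
        g_p=((1.01e-4,),),
        v_pb=(0.0,),
        r=((7.35e-4,),),
        survival=1.0,
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def _draw_effects(config: SimulationConfig, rng: np.random.Generator):
    """Fixed draw order: blocks, provenance, provenance-by-block."""
    t = len(config.traits)
    if config.block_effects is not None:
        blocks = np.tile(np.asarray(config.block_effects, dtype=float)[:, None], (1, t))
        if blocks.shape[0] != config.b:
            raise ValueError("block_effects length must equal b")
    elif config.random_blocks:
        blocks = rng.normal(0.0, config.block_sd, size=(config.b, t))
    else:
        blocks = np.zeros((config.b, t))
    g_p = np.asarray(config.g_p, dtype=float)
    prov = rng.multivariate_normal(np.zeros(t), g_p, size=config.p,
                                   method="cholesky" if _is_pd(g_p) else "svd")
    pb = np.empty((config.b, config.p, t))
    for k in range(t):
        sd = np.sqrt(config.v_pb[k])
        pb[:, :, k] = rng.normal(0.0, sd, size=(config.b, config.p)) if sd > 0 else 0.0
    return blocks, prov, pb


def _is_pd(mat):
    return np.min(np.linalg.eigvalsh(np.asarray(mat, dtype=float))) > 1e-12


def _surface_shift(config: SimulationConfig, code: str, trait: str) -> float:
    if config.provenance_coords is None or config.surface_coefs is None:
        return 0.0
    if trait not in config.surface_coefs:
        return 0.0
    lat, lon = config.provenance_coords[code]
    b0, b1, b2, b3, b4, b5 = config.surface_coefs[trait]
    return b0 + b1 * lat + b2 * lon + b3 * lat**2 + b4 * lon**2 + b5 * lat * lon


def simulate_trial(config: SimulationConfig,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[list[TreeRecord], dict]:
    """Simulate one trial; returns (records, truth).

    ``truth`` carries the drawn block, provenance and provenance-by-block
    effects (arrays indexed block x provenance x trait) so tests can
    compare estimates against the realized effects.  Phenotypes are
    floored at a small positive value because living trees must have
    positive measurements; with realistic parameters the floor is
    essentially never hit.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    t = len(config.traits)
    blocks, prov, pb = _draw_effects(config, rng)
    r_cov = np.asarray(config.r, dtype=float)
    n_trees = config.b * config.p * config.n
    resid = rng.multivariate_normal(np.zeros(t), r_cov, size=n_trees,
                                    method="cholesky" if _is_pd(r_cov) else "svd")
    alive = rng.random(n_trees) < config.survival

    codes = config.codes
    records: list[TreeRecord] = []
    idx = 0
    for i in range(config.b):
        for j in range(config.p):
            for k in range(config.n):
                vals = {}
                for m, trait in enumerate(config.traits):
                    v = (config.grand_mean[m] + blocks[i, m] + prov[j, m]
                         + pb[i, j, m] + resid[idx, m]
                         + _surface_shift(config, codes[j], trait))
                    vals[trait] = max(v, 1e-3)
                records.append(TreeRecord(
                    provenance=codes[j], block=i + 1, tree=k + 1,
                    alive=bool(alive[idx]),
                    dbh=vals.get("dbh") if alive[idx] else None,
                    height=vals.get("height") if alive[idx] else None,
                ))
                idx += 1
    truth = {"block_effects": blocks, "prov_effects": prov, "pb_effects": pb,
             "codes": codes, "traits": config.traits}
    return records, truth


def simulate_wood_samples(config: SimulationConfig, trees_per_provenance: int = 5,
                          rng: np.random.Generator | None = None,
                          ) -> tuple[list[WoodSample], dict]:
    """Simulate per-tree wood samples: provenance effect + residual only.

    The wood-sample design has a handful of cored trees per provenance and
    no block replication, so no provenance-by-block term is simulated (it
    is structurally absent from the wood-trait analysis model).
    """
    if trees_per_provenance < 1:
        raise ValueError("trees_per_provenance must be >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    t = len(config.traits)
    g_p = np.asarray(config.g_p, dtype=float)
    r_cov = np.asarray(config.r, dtype=float)
    prov = rng.multivariate_normal(np.zeros(t), g_p, size=config.p,
                                   method="cholesky" if _is_pd(g_p) else "svd")
    resid = rng.multivariate_normal(np.zeros(t), r_cov,
                                    size=config.p * trees_per_provenance,
                                    method="cholesky" if _is_pd(r_cov) else "svd")
    codes = config.codes
    wood_fields = {"fl", "fd", "vl", "vd", "fl_fd", "vl_vd", "wbd", "cr"}
    samples: list[WoodSample] = []
    idx = 0
    for j in range(config.p):
        for k in range(trees_per_provenance):
            vals = {}
            for m, trait in enumerate(config.traits):
                if trait not in wood_fields:
                    raise ValueError(f"{trait!r} is not a wood-sample field")
                v = (config.grand_mean[m] + prov[j, m] + resid[idx, m]
                     + _surface_shift(config, codes[j], trait))
                vals[trait] = max(v, 1e-6)
            samples.append(WoodSample(provenance=codes[j], tree=k + 1, **vals))
            idx += 1
    truth = {"prov_effects": prov, "codes": codes, "traits": config.traits}
    return samples, truth
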