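"""Recompute the published trial results from the bundled summary tables.

Every function here is a thin composition of package operations applied
to the published provenance-level summaries in :mod:`provtrial.datasets`:
mean coefficients of variation, the volume fold ratio, heritabilities
and the genetic variation coefficient from the published variance
components, realized gains of the two published selections, and the
largest individual stem volume from its DBH/height measurements.

Selection gains follow the published computation exactly: provenance and
overall means are rounded to two decimals — the display precision of the
published gain table — before the gain formula is applied.  (On the raw
means the volume gains would differ; the published figures are functions
of the rounded means.)
"""

from __future__ import annotations

from . import datasets
from .quantgen import (genetic_cv, provenance_heritability, realized_gain,
                       select_superior)
from .summaries import trait_variation_summary
from .wood_traits import stem_volume

__all__ = [
    "mean_cv",
    "volume_fold_ratio",
    "heritability_from_components",
    "volume_genetic_cv",
    "selection_report",
    "selection_gain",
    "largest_tree_volume",
]

#: Harmonic-mean plot size consistent with the published growth-trait
#: heritabilities (10 blocks, 5-tree plots, ~80% survival); the published
#: analysis does not print its own n_h, and this value reproduces the
#: heritability table from its components.
DEFAULT_N_H = 4.0
N_BLOCKS = 10


def _summary(trait: str):
    growth = datasets.load_growth_summary()
    wood = datasets.load_wood_summary()
    table = growth if trait in set(growth["trait"]) else wood
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise KeyError(trait)
    return sub


def mean_cv(trait: str) -> float:
    """Arithmetic mean of the published per-provenance CVs (%) of a trait."""
    return trait_variation_summary(_summary(trait))["mean_cv"]


def volume_fold_ratio() -> float:
    """Max/min fold ratio of the published widest volume range.

    Uses the narrative endpoints of the GXFCG volume range (the published
    fold figure is a function of those printed values).
    """
    lo, hi = datasets.NARRATIVE_V_RANGE_GXFCG
    return hi / lo


def heritability_from_components(trait: str, n_h: float = DEFAULT_N_H,
                                 b: int = N_BLOCKS) -> float:
    """Provenance heritability recomputed from the published variance
    components of ``trait``."""
    vc = datasets.load_variance_components().set_index("trait").loc[trait]
    v_pb = None if vc.isna().get("v_pb", False) else float(vc["v_pb"])
    return provenance_heritability(v_p=float(vc["v_p"]), v_pb=v_pb,
                                   v_e=float(vc["v_e"]), n_h=n_h, b=b)


def volume_genetic_cv() -> float:
    """CV_G (%) of stem volume from the published provenance variance and
    the published overall mean volume."""
    vc = datasets.load_variance_components().set_index("trait").loc["volume"]
    return genetic_cv(float(vc["v_p"]), datasets.PRINTED_OVERALL_V_MEAN)


def selection_report(purpose: str):
    """Superior-provenance selection on the published provenance means.

    ``purpose`` is ``"wood_products"`` (select on volume and wood basic
    density) or ``"pulpwood"`` (volume and fiber length).
    """
    pairs = {"wood_products": ("volume", "wbd"), "pulpwood": ("volume", "fl")}
    if purpose not in pairs:
        raise ValueError(f"unknown purpose {purpose!r}")
    a, b = pairs[purpose]
    return select_superior(datasets.provenance_means(), a, b, purpose=purpose)


def selection_gain(purpose: str, trait: str, digits: int = 2) -> float:
    """Realized gain (%) of ``trait`` under a published selection,
    computed from display-rounded means as the published table does."""
    rep = selection_report(purpose)
    sup = round(rep.superior_means[trait], digits)
    overall = round(rep.overall_means[trait], digits)
    return realized_gain(sup, overall)


def largest_tree_volume() -> float:
    """Stem volume (m^3) of the largest recorded tree, from its published
    DBH (cm) and height (m) maxima."""
    growth = datasets.load_growth_summary()
    dbh = growth[growth["trait"] == "dbh"]["maximum"].max()
    height = growth[growth["trait"] == "height"]["maximum"].max()
    return stem_volume(float(dbh), float(height))
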