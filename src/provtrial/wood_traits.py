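"""Closed-form derived traits: stem volume, wood basic density,
crystallinity, slenderness ratios.

Volume uses the species-specific two-entry formula for *Neolamarckia
cadamba*, V = 3.69e-5 * DBH^2 * H, with DBH in cm and H in m giving V in
m^3; the constant absorbs the unit conversion and form factor and is
treated as exact.

Wood basic density is oven-dry weight over green volume, measured by water
displacement: the displaced volume w1 (cm^3, numerically the displaced
mass in g) and oven-dry weight w2 (g) give WBD = w2/w1 in g/cm^3.

Crystallinity follows the Segal X-ray diffraction method: with Iu the
integrated intensity of the crystalline peak at 2-theta = 22 deg and Ia
the amorphous scattering at 18 deg, Cr = (Iu - Ia)/Iu * 100%.

Slenderness ratios (FL/FD, VL/VD) are computed per tree and averaged,
never as ratios of averages — provenance means of ratio traits are means
of per-tree ratios.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable

import numpy as np

from .trial_data import TreeRecord, WoodSample

__all__ = [
    "VOLUME_COEF",
    "stem_volume",
    "wood_basic_density",
    "crystallinity",
    "trait_ratios",
    "add_volume",
]

VOLUME_COEF = 3.69e-5
"""Species-specific volume coefficient (cm^2 * m -> m^3)."""


def stem_volume(dbh, height):
    """Individual stem volume in m^3 from DBH (cm) and height (m).

    Vectorized over array inputs.
    """
    dbh = np.asarray(dbh, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(dbh < 0) or np.any(height < 0):
        raise ValueError("dbh and height must be non-negative")
    out = VOLUME_COEF * dbh**2 * height
    return float(out) if out.ndim == 0 else out


def wood_basic_density(w1, w2):
    """Wood basic density (g/cm^3) from displaced water volume ``w1``
    (cm^3) and oven-dry weight ``w2`` (g)."""
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if np.any(w1 <= 0):
        raise ValueError("displaced-water measure w1 must be positive")
    if np.any(w2 < 0):
        raise ValueError("oven-dry weight w2 must be non-negative")
    out = w2 / w1
    return float(out) if out.ndim == 0 else out


def crystallinity(iu, ia):
    """Cellulose crystallinity (%) from integrated X-ray intensities.

    ``iu`` is the crystalline-peak intensity (2-theta = 22 deg), ``ia`` the
    amorphous-trough intensity (18 deg); ``ia`` may not exceed ``iu``.
    """
    iu = np.asarray(iu, dtype=float)
    ia = np.asarray(ia, dtype=float)
    if np.any(iu <= 0):
        raise ValueError("iu must be positive")
    if np.any(ia < 0) or np.any(ia > iu):
        raise ValueError("ia must lie in [0, iu]")
    out = 100.0 * (iu - ia) / iu
    return float(out) if out.ndim == 0 else out


def trait_ratios(sample: WoodSample) -> WoodSample:
    """Return a copy of ``sample`` with fl_fd and vl_vd filled in."""
    updates = {}
    if sample.fl is not None and sample.fd is not None:
        if sample.fd == 0:
            raise ValueError("fd is zero; FL/FD undefined")
        updates["fl_fd"] = sample.fl / sample.fd
    if sample.vl is not None and sample.vd is not None:
        if sample.vd == 0:
            raise ValueError("vd is zero; VL/VD undefined")
        updates["vl_vd"] = sample.vl / sample.vd
    return replace(sample, **updates) if updates else sample


def add_volume(records: Iterable[TreeRecord]) -> list[TreeRecord]:
    """Attach stem volume to every living tree record."""
    out = []
    for r in records:
        if r.alive and r.dbh is not None and r.height is not None:
            out.append(replace(r, volume=stem_volume(r.dbh, r.height)))
        else:
            out.append(r)
    return out
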