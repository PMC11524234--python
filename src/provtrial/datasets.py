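"""Published provenance-level summary statistics bundled as reference data.

These tables are the provenance-level results of a 10-provenance
*Neolamarckia cadamba* trial in southern China (randomized complete
blocks, 10 blocks, 5-tree plots, planted 2014 and assessed at half
rotation age): per-provenance descriptives for three growth traits and
eight wood properties, REML variance components with provenance
heritabilities, and the geographic origins of the seed sources.  The raw
tree-level data were never deposited, so these summaries are the only
published quantities; the package uses them as inputs for selection,
gain and reproduction computations, and its estimation machinery is
validated on synthetic trials instead.

Notes on internal consistency: the growth summary prints the GXFCG
maximum volume as 0.3143 m^3 (consistent with the volume formula at the
largest tree's DBH 20.90 cm and height 19.5 m), while the accompanying
narrative quotes the GXFCG volume range as 0.0127-0.3134 m^3 and derives
a 24.68-fold max/min ratio from it.  Both readings are retained:
:func:`load_growth_summary` carries the tabulated values and
``NARRATIVE_V_RANGE_GXFCG`` the narrative endpoints.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "GROWTH_TRAITS",
    "WOOD_TRAITS",
    "load_growth_summary",
    "load_wood_summary",
    "load_variance_components",
    "load_provenance_locations",
    "provenance_means",
    "NARRATIVE_V_RANGE_GXFCG",
    "PRINTED_OVERALL_V_MEAN",
]

GROWTH_TRAITS = ("dbh", "height", "volume")
WOOD_TRAITS = ("fl", "fd", "fl_fd", "vl", "vd", "vl_vd", "wbd", "cr")

#: Volume range for GXFCG as quoted in the published narrative (m^3);
#: its max/min ratio is the published 24.68-fold figure.
NARRATIVE_V_RANGE_GXFCG = (0.0127, 0.3134)

#: Overall mean volume (m^3) as printed in the provenance-performance text.
PRINTED_OVERALL_V_MEAN = 0.0844

# per-provenance descriptives: trait, provenance, mean, se, min, max, cv(%)
_GROWTH = """\
trait,provenance,mean,se_mean,minimum,maximum,cv
dbh,GXLZ,12.92,0.52,4.10,20.80,28.88
dbh,GXFCG,13.31,0.45,7.00,20.90,24.74
dbh,GXNN,13.26,0.52,4.40,20.10,28.84
dbh,GDGZ,11.41,0.49,5.60,19.30,28.07
dbh,GDYF,12.03,0.56,4.80,20.10,30.12
dbh,YNBS,11.66,0.50,4.20,17.80,27.86
dbh,YNDH,12.20,0.54,3.90,19.80,31.54
dbh,YNJH,13.22,0.44,6.50,18.20,21.94
dbh,YNMS,13.01,0.47,5.70,20.80,26.00
dbh,YNMN,12.14,0.55,5.20,19.70,29.86
height,GXLZ,12.01,0.54,1.00,19.00,32.22
height,GXFCG,12.98,0.44,7.00,19.50,24.79
height,GXNN,13.09,0.46,6.00,19.00,25.64
height,GDGZ,10.91,0.51,4.00,17.30,30.44
height,GDYF,11.28,0.52,5.00,17.00,29.91
height,YNBS,11.29,0.56,5.00,18.00,32.74
height,YNDH,11.91,0.53,4.00,19.00,31.75
height,YNJH,12.78,0.46,7.00,18.00,23.64
height,YNMS,12.12,0.48,5.00,18.00,28.60
height,YNMN,11.43,0.53,5.00,18.00,30.81
volume,GXLZ,0.0907,0.0096,0.0025,0.3033,75.40
volume,GXFCG,0.0991,0.0091,0.0127,0.3143,67.23
volume,GXNN,0.1022,0.0095,0.0043,0.2833,68.04
volume,GDGZ,0.0647,0.0078,0.0058,0.2378,78.95
volume,GDYF,0.0745,0.0085,0.0043,0.2236,73.91
volume,YNBS,0.0695,0.0080,0.0040,0.2104,75.09
volume,YNDH,0.0833,0.0094,0.0022,0.2504,80.04
volume,YNJH,0.0930,0.0083,0.0109,0.2128,58.79
volume,YNMS,0.0890,0.0079,0.0060,0.2249,64.20
volume,YNMN,0.0784,0.0096,0.0060,0.2291,81.63
"""

_WOOD = """\
trait,provenance,mean,se_mean,minimum,maximum,cv
fl,GXLZ,1525.52,21.43,1442.72,1635.32,3.97
fl,GXFCG,1459.09,45.27,1191.38,1630.81,9.81
fl,GXNN,1432.45,23.75,1334.34,1555.94,5.50
fl,GDGZ,1411.77,38.03,1127.74,1547.69,9.33
fl,GDYF,1303.55,70.03,1152.66,1428.27,10.74
fl,YNBS,1450.56,35.81,1072.86,1692.28,11.84
fl,YNDH,1415.46,24.41,1180.88,1619.33,8.27
fl,YNJH,1398.71,21.27,1100.28,1661.14,9.86
fl,YNMS,1403.86,34.67,1259.07,1554.06,6.98
fl,YNMN,1428.68,31.09,1184.37,1618.10,8.70
fd,GXLZ,32.99,0.40,30.86,34.26,3.47
fd,GXFCG,32.11,0.44,29.11,33.39,4.29
fd,GXNN,32.65,0.28,31.51,34.56,2.80
fd,GDGZ,32.60,0.38,29.61,34.24,4.08
fd,GDYF,31.35,0.35,30.36,32.02,2.25
fd,YNBS,32.31,0.32,28.45,35.85,4.73
fd,YNDH,32.57,0.21,30.54,34.27,3.03
fd,YNJH,32.38,0.18,28.66,34.20,3.67
fd,YNMS,31.96,0.35,30.24,32.97,3.14
fd,YNMN,32.30,0.25,30.30,33.84,3.11
fl_fd,GXLZ,46.27,0.72,44.18,50.27,4.40
fl_fd,GXFCG,45.37,0.98,40.93,48.85,6.81
fl_fd,GXNN,43.87,0.57,41.84,47.78,4.30
fl_fd,GDGZ,43.23,0.74,36.96,45.73,5.94
fl_fd,GDYF,41.53,1.89,37.97,44.99,9.10
fl_fd,YNBS,44.77,0.77,37.71,49.41,8.24
fl_fd,YNDH,43.42,0.59,37.50,50.06,6.55
fl_fd,YNJH,43.15,0.54,36.98,50.55,8.15
fl_fd,YNMS,43.90,0.78,40.96,47.38,5.00
fl_fd,YNMN,44.22,0.86,37.16,50.98,7.82
vl,GXLZ,696.34,33.29,572.87,873.28,13.52
vl,GXFCG,656.88,26.47,522.80,802.90,12.74
vl,GXNN,601.42,20.41,521.48,732.25,11.26
vl,GDGZ,643.94,19.49,551.55,748.09,10.48
vl,GDYF,676.82,60.44,549.34,823.63,17.86
vl,YNBS,691.06,20.35,547.53,875.98,14.12
vl,YNDH,651.15,23.54,491.42,866.51,17.34
vl,YNJH,659.95,12.82,532.67,833.18,12.59
vl,YNMS,654.00,26.61,550.01,787.49,11.51
vl,YNMN,639.87,16.40,551.43,822.21,10.25
vd,GXLZ,176.31,5.97,151.27,195.29,9.58
vd,GXFCG,164.43,9.94,108.29,207.51,19.11
vd,GXNN,165.83,6.23,140.70,203.94,12.46
vd,GDGZ,168.49,10.19,120.39,243.96,20.95
vd,GDYF,144.87,12.75,118.55,177.27,17.60
vd,YNBS,158.96,5.95,107.95,226.68,17.97
vd,YNDH,162.25,6.13,111.55,231.30,18.11
vd,YNJH,160.13,3.27,99.36,193.57,13.25
vd,YNMS,157.31,7.60,120.70,176.66,13.67
vd,YNMN,165.72,5.31,129.60,213.93,12.81
vl_vd,GXLZ,3.95,0.12,3.57,4.60,8.73
vl_vd,GXFCG,4.06,0.15,3.56,4.83,11.75
vl_vd,GXNN,3.65,0.12,3.06,4.50,10.81
vl_vd,GDGZ,3.93,0.19,2.86,4.90,16.33
vl_vd,GDYF,4.68,0.21,4.16,5.17,8.90
vl_vd,YNBS,4.41,0.11,3.52,5.64,12.43
vl_vd,YNDH,4.08,0.15,3.28,5.68,17.72
vl_vd,YNJH,4.16,0.09,3.10,5.63,13.27
vl_vd,YNMS,4.22,0.24,3.12,5.19,15.88
vl_vd,YNMN,3.89,0.10,3.33,4.77,10.07
wbd,GXLZ,0.3275,0.0101,0.2886,0.3782,8.74
wbd,GXFCG,0.3389,0.0099,0.2878,0.3896,9.20
wbd,GXNN,0.3274,0.0081,0.2980,0.3820,8.21
wbd,GDGZ,0.3457,0.0067,0.3188,0.3900,6.69
wbd,GDYF,0.3435,0.0160,0.3146,0.3892,9.31
wbd,YNBS,0.3600,0.0046,0.3302,0.4128,6.15
wbd,YNDH,0.3253,0.0048,0.2656,0.3660,7.13
wbd,YNJH,0.3381,0.0042,0.2960,0.3958,8.14
wbd,YNMS,0.3533,0.0085,0.3252,0.3872,6.83
wbd,YNMN,0.3298,0.0092,0.2606,0.4000,11.13
cr,GXLZ,50.24,0.89,47.90,53.96,5.04
cr,GXFCG,50.15,0.45,47.44,51.81,2.87
cr,GXNN,52.17,0.70,47.84,56.36,4.43
cr,GDGZ,50.62,0.85,45.17,55.38,5.80
cr,GDYF,51.19,0.62,49.87,52.77,2.43
cr,YNBS,51.90,0.67,45.91,55.79,6.22
cr,YNDH,51.87,0.47,47.93,58.23,4.33
cr,YNJH,52.10,0.47,40.95,61.11,5.87
cr,YNMS,52.62,0.84,50.05,57.39,4.50
cr,YNMN,50.63,0.76,45.73,56.01,6.00
"""

# REML variance components, provenance heritability and CV_G per trait;
# empty cells mean "not part of the model" (V_PB for wood traits) and NE
# means estimated at the zero boundary ("not estimated, assumed zero").
_VARCOMP = """\
trait,v_p,se_p,v_pb,se_pb,v_e,se_e,h2,cv_g
dbh,0.47,0.22,0.08,0.07,8.97,0.32,0.67,5.46
height,0.23,0.14,0.26,0.10,5.46,0.19,0.59,4.00
volume,9.98e-5,5.91e-5,3.39e-5,2.64e-5,2.17e-3,7.85e-5,0.64,11.83
fl,69.50,533.00,,,17595.30,2037.00,0.02,0.59
fd,0.00,0.03,,,1.41,0.16,NE,NE
fl_fd,0.31,0.46,,,10.03,1.16,0.16,1.26
vl,94.03,277.50,,,7771.29,900.80,0.07,1.48
vd,0.00,17.78,,,644.00,74.50,NE,NE
vl_vd,3.52e-2,2.81e-2,,,0.31,0.03,0.40,4.57
wbd,1.01e-4,7.48e-5,,,7.35e-4,8.56e-5,0.45,2.96
cr,0.16,0.31,,,7.61,0.88,0.11,0.78
"""

# seed-source geography and climate covariates
_LOCATIONS = """\
code,latitude,longitude,altitude,annual_mean_temp,min_temp,max_temp,frostless_period,annual_precipitation
GXLZ,22.36,106.84,269,22.2,0.8,39.9,352,1260
GXFCG,21.77,107.35,235,21.8,1.4,37.8,360,2512
GXNN,22.85,108.40,80,21.7,-2.4,40.4,364,1304.2
GDGZ,23.10,113.21,10,22.1,0.0,39.3,346,1696.5
GDYF,22.10,112.02,346,21.5,-1.0,39.1,345,1670.5
YNBS,25.08,99.16,1670,17.4,-4.2,40.4,283,1710
YNDH,24.08,97.39,780,18.9,-2.9,35.7,299,1544
YNJH,21.02,101.04,552.7,21.0,2.7,41.1,365,1197
YNMS,24.20,98.95,913,19.6,-0.6,36.2,315,1650
YNMN,21.40,101.30,631,21.0,0.5,38.4,331,1540
"""


def _read(text: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(text))


def load_growth_summary() -> pd.DataFrame:
    """Per-provenance descriptives of DBH (cm), height (m), volume (m^3)."""
    return _read(_GROWTH)


def load_wood_summary() -> pd.DataFrame:
    """Per-provenance descriptives of the eight wood properties."""
    return _read(_WOOD)


def load_variance_components() -> pd.DataFrame:
    """Published REML variance components, heritabilities and CV_G.

    ``v_pb`` is NaN for wood traits (no interaction term in the model);
    ``h2``/``cv_g`` are the string "NE" where the provenance variance hit
    the zero boundary.
    """
    return _read(_VARCOMP)


def load_provenance_locations() -> pd.DataFrame:
    """Seed-source coordinates (decimal degrees), altitude (m) and
    climate covariates."""
    return _read(_LOCATIONS)


def provenance_means(traits=None) -> pd.DataFrame:
    """Provenance-by-trait matrix of published means (selection input)."""
    long = pd.concat([load_growth_summary(), load_wood_summary()])
    wide = long.pivot(index="provenance", columns="trait", values="mean")
    if traits is not None:
        wide = wide[list(traits)]
    return wide
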