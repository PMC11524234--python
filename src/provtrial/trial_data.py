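"""Domain types and delimited-table I/O for provenance-trial data.

A provenance trial is a common-garden experiment: seed lots from several
geographic origins (provenances) are planted together in a randomized
complete block design so that among-provenance differences can be read as
genetic.  Three tables describe a trial:

``growth``
    one row per planted tree (provenance, block, tree, alive flag, DBH in
    cm, height in m, optionally stem volume in m^3).  Dead trees keep their
    provenance/block identity but carry missing measurements, so survival
    counts remain computable from the same table.
``wood``
    one row per cored tree (fiber/vessel dimensions in um, slenderness
    ratios, wood basic density in g/cm^3, crystallinity in %, optional raw
    lab quantities).
``provenance``
    one row per seed origin (code, latitude/longitude in decimal degrees,
    altitude in m, optional climate covariates).

Files are comma-separated with a header row; tabs are accepted on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProvenanceInfo",
    "TreeRecord",
    "WoodSample",
    "TrialDesign",
    "SchemaError",
    "RowError",
    "ReferentialError",
    "read_trial_table",
    "write_trial_table",
    "records_to_frame",
    "frame_to_records",
    "validate_trial",
]

CLIMATE_COLUMNS = (
    "annual_mean_temp",
    "min_temp",
    "max_temp",
    "frostless_period",
    "annual_precipitation",
)


class SchemaError(ValueError):
    """A table is missing a mandatory column or has an unknown schema."""


class RowError(ValueError):
    """A row holds an unparseable or invalid value; carries the line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class ReferentialError(ValueError):
    """A trait table references a provenance code absent from the
    provenance table."""


@dataclass(frozen=True)
class ProvenanceInfo:
    """A seed-source population and where it was collected."""

    code: str
    latitude: float
    longitude: float
    altitude: float | None = None
    climate: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass(frozen=True)
class TreeRecord:
    """One planted tree inside a provenance x block plot.

    ``dbh`` (cm), ``height`` (m) and the derived ``volume`` (m^3) are
    present only for living trees.
    """

    provenance: str
    block: int
    tree: int
    alive: bool
    dbh: float | None = None
    height: float | None = None
    volume: float | None = None

    def __post_init__(self):
        if self.alive:
            if self.dbh is None and self.height is None:
                raise ValueError(
                    f"alive tree {self.provenance}/b{self.block}/t{self.tree} "
                    "must carry at least one measurement"
                )
            for name in ("dbh", "height"):
                v = getattr(self, name)
                if v is not None and v <= 0:
                    raise ValueError(f"{name} must be positive for a live tree")
        else:
            if self.dbh is not None or self.height is not None:
                raise ValueError("dead trees carry no measurements")
        if self.volume is not None and (self.dbh is None or self.height is None):
            raise ValueError("volume requires dbh and height")


@dataclass(frozen=True)
class WoodSample:
    """Per-tree wood-property measurements from one increment core.

    Lengths/diameters in um, density in g/cm^3, crystallinity in percent.
    ``raw`` may carry the lab quantities behind the derived traits:
    ``w1`` (volume of displaced water, cm^3), ``w2`` (oven-dry weight, g),
    ``iu``/``ia`` (integrated X-ray intensities at the 2-theta = 22 deg
    crystalline peak and 18 deg amorphous trough).
    """

    provenance: str
    tree: int
    fl: float | None = None
    fd: float | None = None
    vl: float | None = None
    vd: float | None = None
    fl_fd: float | None = None
    vl_vd: float | None = None
    wbd: float | None = None
    cr: float | None = None
    raw: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("fl", "fd", "vl", "vd"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.wbd is not None and not 0.0 < self.wbd < 1.5:
            raise ValueError(f"wbd {self.wbd} outside (0, 1.5) g/cm^3")
        if self.cr is not None and not 0.0 <= self.cr <= 100.0:
            raise ValueError(f"cr {self.cr} outside [0, 100] %")
        for ratio, num, den in (("fl_fd", self.fl, self.fd), ("vl_vd", self.vl, self.vd)):
            r = getattr(self, ratio)
            if r is not None and num is not None and den is not None:
                if abs(r - num / den) > 0.005 * abs(num / den):
                    raise ValueError(
                        f"stored {ratio}={r} disagrees with {num}/{den} by >0.5%"
                    )


@dataclass(frozen=True)
class TrialDesign:
    """Design summary of a trial: sizes and the surviving-count table.

    ``n_ij`` maps (block, provenance) -> surviving trees; plots with zero
    survivors are kept (value 0) so callers can decide how to treat them.
    ``singleton_provenances`` lists provenances observed in only one block,
    where the provenance-by-block interaction is confounded with the
    provenance effect.
    """

    p: int
    b: int
    n: int
    n_ij: dict[tuple[int, str], int]
    singleton_provenances: tuple[str, ...] = ()

    @property
    def empty_plots(self) -> list[tuple[int, str]]:
        return [k for k, v in self.n_ij.items() if v == 0]


# ---------------------------------------------------------------------------
# schemas

_GROWTH_REQUIRED = ("provenance", "block", "tree", "alive")
_GROWTH_NUMERIC = ("dbh", "height", "volume")
_WOOD_REQUIRED = ("provenance", "tree")
_WOOD_NUMERIC = ("fl", "fd", "vl", "vd", "fl_fd", "vl_vd", "wbd", "cr",
                 "w1", "w2", "iu", "ia")
_PROV_REQUIRED = ("code", "latitude", "longitude")

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


def _sniff_sep(path: Path) -> str:
    head = path.read_text().splitlines()[0] if path.read_text() else ""
    return "\t" if "\t" in head else ","


def _parse_float(text, col: str, line: int) -> float | None:
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return None
    s = str(text).strip()
    if s == "" or s.lower() in ("na", "nan", "ne"):
        return None
    try:
        return float(s)
    except ValueError:
        raise RowError(f"non-numeric value {s!r} in column '{col}'", line) from None


def _parse_bool(text, line: int) -> bool:
    s = str(text).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise RowError(f"cannot interpret {text!r} as alive flag", line)


def read_trial_table(
    path: str | Path,
    schema: str,
    provenances: Sequence[ProvenanceInfo] | None = None,
) -> list:
    """Read one of the three trial tables into validated records.

    Parameters
    ----------
    path : file path
        CSV (or TSV) file with a header row.  Header matching is
        case-insensitive.
    schema : {"growth", "wood", "provenance"}
        Which record type the table holds.
    provenances : sequence of ProvenanceInfo, optional
        When given for a growth/wood table, every provenance code in the
        table must appear in it (referential check).

    Returns
    -------
    list of TreeRecord, WoodSample or ProvenanceInfo.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema not in ("growth", "wood", "provenance"):
        raise SchemaError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    return _records_from_frame(df, schema, provenances)


def _records_from_frame(
    df: pd.DataFrame,
    schema: str,
    provenances: Sequence[ProvenanceInfo] | None = None,
) -> list:
    df = df.copy()
    df.columns = [str(c).strip().lower() for c in df.columns]

    required = {"growth": _GROWTH_REQUIRED, "wood": _WOOD_REQUIRED,
                "provenance": _PROV_REQUIRED}[schema]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{schema} table missing mandatory column '{col}'")

    known_codes = {p.code for p in provenances} if provenances is not None else None
    out: list = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        if schema == "provenance":
            climate = {c: v for c in CLIMATE_COLUMNS
                       if (v := _parse_float(row.get(c), c, line)) is not None}
            out.append(ProvenanceInfo(
                code=str(row["code"]).strip(),
                latitude=_parse_float(row["latitude"], "latitude", line),
                longitude=_parse_float(row["longitude"], "longitude", line),
                altitude=_parse_float(row.get("altitude"), "altitude", line),
                climate=climate,
            ))
            continue
        code = str(row["provenance"]).strip()
        if known_codes is not None and code not in known_codes:
            raise ReferentialError(
                f"line {line}: provenance code {code!r} not in provenance table"
            )
        if schema == "growth":
            alive = _parse_bool(row["alive"], line)
            vals = {c: _parse_float(row.get(c), c, line) for c in _GROWTH_NUMERIC}
            try:
                out.append(TreeRecord(
                    provenance=code,
                    block=int(_parse_float(row["block"], "block", line)),
                    tree=int(_parse_float(row["tree"], "tree", line)),
                    alive=alive,
                    **vals,
                ))
            except ValueError as exc:
                raise RowError(str(exc), line) from None
        else:
            raw = {c: v for c in ("w1", "w2", "iu", "ia")
                   if (v := _parse_float(row.get(c), c, line)) is not None}
            vals = {c: _parse_float(row.get(c), c, line)
                    for c in _WOOD_NUMERIC if c not in ("w1", "w2", "iu", "ia")}
            try:
                out.append(WoodSample(
                    provenance=code,
                    tree=int(_parse_float(row["tree"], "tree", line)),
                    raw=raw,
                    **vals,
                ))
            except ValueError as exc:
                raise RowError(str(exc), line) from None
    return out


def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Flatten typed records into a DataFrame (raw/climate dicts expanded)."""
    rows = []
    for r in records:
        d = {}
        for f in dc_fields(r):
            v = getattr(r, f.name)
            if f.name in ("raw", "climate"):
                d.update(v)
            else:
                d[f.name] = v
        rows.append(d)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame, schema: str) -> list:
    """Inverse of :func:`records_to_frame` for a given schema."""
    return _records_from_frame(df, schema)


def write_trial_table(records: Iterable, path: str | Path) -> None:
    """Write records as RFC-4180-style CSV (header row, minimal quoting)."""
    df = records_to_frame(list(records))
    df.to_csv(Path(path), index=False)


def validate_trial(records: Sequence[TreeRecord], n_planted: int | None = None) -> TrialDesign:
    """Summarize a growth table into a :class:`TrialDesign`.

    ``n`` (planted trees per plot) defaults to the maximum observed plot
    count; pass ``n_planted`` when the nominal plot size is known.  Empty
    plots (all trees dead) are kept in ``n_ij`` with count 0.  A provenance
    observed in only one block is flagged: its provenance-by-block
    interaction cannot be separated from its main effect.
    """
    records = list(records)
    if not any(r.alive for r in records):
        raise ValueError("no alive records in trial")
    provs = sorted({r.provenance for r in records})
    blocks = sorted({r.block for r in records})
    n_ij = {(b, p): 0 for b in blocks for p in provs
            if any(r.block == b and r.provenance == p for r in records)}
    for r in records:
        if r.alive:
            n_ij[(r.block, r.provenance)] += 1
    singletons = tuple(
        p for p in provs
        if len({b for (b, q) in n_ij if q == p}) < 2
    )
    n = n_planted if n_planted is not None else max(n_ij.values())
    total_alive = sum(1 for r in records if r.alive)
    assert sum(n_ij.values()) == total_alive
    return TrialDesign(p=len(provs), b=len(blocks), n=n, n_ij=n_ij,
                       singleton_provenances=singletons)
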