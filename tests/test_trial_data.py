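"""Trial-table I/O, record validation and design summaries."""

import numpy as np
import pytest

from provtrial.simulate import SimulationConfig, simulate_trial
from provtrial.trial_data import (ProvenanceInfo, ReferentialError, RowError,
                                  SchemaError, TreeRecord, WoodSample,
                                  read_trial_table, validate_trial,
                                  write_trial_table)

GROWTH_CSV = """provenance,block,tree,alive,dbh,height
GXLZ,1,1,1,12.5,11.0
GXLZ,1,2,1,14.0,13.5
GXNN,1,1,0,,
GXNN,1,2,1,11.2,10.8
"""


@pytest.fixture
def growth_file(tmp_path):
    path = tmp_path / "growth.csv"
    path.write_text(GROWTH_CSV)
    return path


def test_growth_fixture_reads_with_dead_tree(growth_file):
    records = read_trial_table(growth_file, "growth")
    assert len(records) == 4
    assert sum(r.alive for r in records) == 3
    dead = [r for r in records if not r.alive][0]
    assert dead.provenance == "GXNN" and dead.dbh is None and dead.height is None


def test_tab_separated_accepted(tmp_path):
    path = tmp_path / "growth.tsv"
    path.write_text(GROWTH_CSV.replace(",", "\t"))
    assert len(read_trial_table(path, "growth")) == 4


@pytest.mark.parametrize("schema,records", [
    ("growth", [
        TreeRecord("GXLZ", 1, 1, True, dbh=12.5, height=11.0, volume=0.0645),
        TreeRecord("GXLZ", 2, 1, False),
    ]),
    ("wood", [
        WoodSample("GXLZ", 1, fl=1500.0, fd=32.0, vl=650.0, vd=160.0,
                   wbd=0.33, cr=51.0, raw={"w1": 2.0, "w2": 0.66}),
        WoodSample("GXNN", 2, fl=1400.0, fd=31.0),
    ]),
    ("provenance", [
        ProvenanceInfo("GXLZ", 22.36, 106.84, 269.0,
                       climate={"annual_mean_temp": 22.2}),
        ProvenanceInfo("YNBS", 25.08, 99.16, 1670.0),
    ]),
])
def test_write_read_round_trip_identity(tmp_path, schema, records):
    path = tmp_path / f"{schema}.csv"
    write_trial_table(records, path)
    assert read_trial_table(path, schema) == records


def test_non_numeric_measurement_cites_line(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("provenance,block,tree,alive,dbh,height\n"
                    "A,1,1,1,10.0,9.0\n"
                    "A,1,2,1,abc,9.0\n")
    with pytest.raises(RowError, match="line 3"):
        read_trial_table(path, "growth")


def test_missing_column_named_in_schema_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("provenance,block,alive,dbh,height\nA,1,1,10,9\n")
    with pytest.raises(SchemaError, match="tree"):
        read_trial_table(path, "growth")


def test_unknown_provenance_code_is_referential_error(growth_file):
    provs = [ProvenanceInfo("GXLZ", 22.36, 106.84)]
    with pytest.raises(ReferentialError, match="GXNN"):
        read_trial_table(growth_file, "growth", provenances=provs)


def test_record_invariants_rejected():
    with pytest.raises(ValueError):
        TreeRecord("A", 1, 1, True)  # alive without measurements
    with pytest.raises(ValueError):
        TreeRecord("A", 1, 1, True, dbh=-1.0)
    with pytest.raises(ValueError):
        WoodSample("A", 1, fl=1500.0, fd=30.0, fl_fd=60.0)  # ratio mismatch
    with pytest.raises(ValueError):
        ProvenanceInfo("A", 95.0, 0.0)


def _balanced_records(n_per_plot=(3, 3, 3, 3)):
    out = []
    i = 0
    for b in (1, 2):
        for p in ("A", "B"):
            for k in range(n_per_plot[i]):
                out.append(TreeRecord(p, b, k + 1, True, dbh=10.0 + k,
                                      height=9.0))
            i += 1
    return out


def test_validate_trial_balanced_counts():
    design = validate_trial(_balanced_records())
    assert (design.p, design.b, design.n) == (2, 2, 3)
    assert set(design.n_ij.values()) == {3}


def test_validate_trial_unbalanced_and_order_invariant():
    records = _balanced_records((3, 3, 3, 2))
    design = validate_trial(records)
    assert sorted(design.n_ij.values()) == [2, 3, 3, 3]
    shuffled = list(reversed(records))
    assert validate_trial(shuffled).n_ij == design.n_ij


def test_mean_plot_count_matches_binomial_expectation():
    """With survival 0.8 and 5-tree plots, plots average ~4 survivors."""
    counts = []
    for seed in range(20):
        cfg = SimulationConfig(p=10, b=10, n=5, traits=("dbh",),
                               grand_mean=(12.5,), g_p=((0.5,),),
                               v_pb=(0.1,), r=((9.0,),), survival=0.8,
                               seed=1000 + seed)
        records, _ = simulate_trial(cfg)
        design = validate_trial(records)
        counts.extend(design.n_ij.values())
    assert np.mean(counts) == pytest.approx(4.0, abs=0.1)
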