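import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import p4valid as p4
from p4valid.core_io import (
    DataFormatError,
    DuplicateKeyError,
    format_measured_cell,
    parse_measured_cell,
    write_replicate_table,
)

from conftest import table_from_cells


PANEL_CSV = """matrix,level_id,spiked,day,replicate,measured
plasma,L1,0.4,1,1,0.55
plasma,L1,0.4,1,2,0.61
plasma,P0,0,2,3,<0.2
plasma,L2,5.0,1,1,5.3
"""


def test_read_replicate_table_parses_values_and_censoring(tmp_path):
    path = tmp_path / "panel.csv"
    path.write_text(PANEL_CSV)
    t = p4.read_replicate_table(path)
    assert t.matrix == "plasma"
    assert t.values("L1", day=1).tolist() == [0.55, 0.61]
    cens = t.level_frame("P0").iloc[0]
    assert cens["censored"] == "below"
    assert cens["limit"] == 0.2
    assert math.isnan(cens["value"])


@pytest.mark.parametrize(
    "cell,value,censored,limit",
    [
        ("0.55", 0.55, "none", None),
        ("<0.2", None, "below", 0.2),
        (">40", None, "above", 40.0),
        (5, 5.0, "none", None),
    ],
)
def test_parse_measured_cell(cell, value, censored, limit):
    m = parse_measured_cell(cell)
    assert m.value == value
    assert m.censored.value == censored
    assert m.limit == limit


def test_duplicate_key_is_hard_error(tmp_path):
    path = tmp_path / "dup.csv"
    path.write_text(
        "matrix,level_id,spiked,day,replicate,measured\n"
        "plasma,L1,1,1,1,0.5\nplasma,L1,1,1,1,0.6\n"
    )
    with pytest.raises(DuplicateKeyError, match="L1"):
        p4.read_replicate_table(path)


def test_bad_cells_report_row_and_matrix_errors(tmp_path):
    bad_val = tmp_path / "bad.csv"
    bad_val.write_text(
        "matrix,level_id,spiked,day,replicate,measured\nplasma,L1,1,1,1,oops\n"
    )
    with pytest.raises(DataFormatError, match="line 2"):
        p4.read_replicate_table(bad_val)
    bad_matrix = tmp_path / "mat.csv"
    bad_matrix.write_text(
        "matrix,level_id,spiked,day,replicate,measured\nurine,L1,1,1,1,0.5\n"
    )
    with pytest.raises(DataFormatError, match="matrix"):
        p4.read_replicate_table(bad_matrix)
    negative = tmp_path / "neg.csv"
    negative.write_text(
        "matrix,level_id,spiked,day,replicate,measured\nplasma,L1,1,1,1,-0.5\n"
    )
    with pytest.raises(DataFormatError):
        p4.read_replicate_table(negative)


@pytest.mark.parametrize(
    "policy,expected",
    [("substitute_limit", 0.2), ("substitute_half_limit", 0.1)],
)
def test_resolve_censored_substitution(tmp_path, policy, expected):
    path = tmp_path / "panel.csv"
    path.write_text(PANEL_CSV)
    t = p4.resolve_censored(p4.read_replicate_table(path), policy)
    assert not t.has_censored
    assert t.values("P0").tolist() == [expected]
    # uncensored values are untouched
    assert t.values("L2").tolist() == [5.3]
    assert t.meta["censor_policy"] == policy


def test_resolve_censored_drop_records_emptied_group(tmp_path):
    path = tmp_path / "panel.csv"
    path.write_text(PANEL_CSV)
    t = p4.resolve_censored(p4.read_replicate_table(path), "drop")
    assert "P0" not in {lv.level_id for lv in t.levels()}
    assert any("P0" in w for w in t.meta["censor_warnings"])


@st.composite
def replicate_tables(draw):
    n_levels = draw(st.integers(1, 3))
    spikes = draw(
        st.lists(
            st.floats(0.1, 30, allow_nan=False), min_size=n_levels,
            max_size=n_levels, unique=True,
        )
    )
    rows = []
    for i, s in enumerate(spikes):
        for day in (1, 2):
            for rep in (1, 2):
                kind = draw(st.sampled_from(["value", "below", "above"]))
                if kind == "value":
                    v = draw(st.floats(0, 40, allow_nan=False))
                    rows.append((f"L{i}", s, day, rep, v, "none", math.nan))
                elif kind == "below":
                    rows.append((f"L{i}", s, day, rep, math.nan, "below", 0.2))
                else:
                    rows.append((f"L{i}", s, day, rep, math.nan, "above", 40.0))
    df = pd.DataFrame(
        rows,
        columns=["level_id", "spiked", "day", "replicate", "value", "censored", "limit"],
    )
    return p4.ReplicateTable(df, matrix="serum", n_days=2, n_reps=2)


@settings(max_examples=50, derandomize=True)
@given(replicate_tables())
def test_write_read_round_trip(tmp_path_factory, table):
    """Writing then reading reproduces values and censoring flags exactly."""
    path = tmp_path_factory.mktemp("rt") / "t.csv"
    write_replicate_table(table, path)
    back = p4.read_replicate_table(path)
    a = table.data.sort_values(["level_id", "day", "replicate"]).reset_index(drop=True)
    b = back.data.sort_values(["level_id", "day", "replicate"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b, check_dtype=False)
    assert back.matrix == table.matrix


def test_round_half_even():
    assert p4.round_half_even(6.25, 1) == 6.2
    assert p4.round_half_even(6.35, 1) == 6.4
    assert p4.round_half_even(-40.85, 1) == -40.8
    assert p4.round_half_even(None) is None


def test_validation_report_partial_and_decimals(tmp_path):
    cells = [("L1", 1.0, d, r, v) for d, vals in {1: (1.0, 1.2), 2: (1.1, 1.3)}.items()
             for r, v in enumerate(vals, 1)]
    cells += [("P0", 0.0, d, r, 0.2) for d in (1, 2) for r in (1, 2)]
    table = table_from_cells(cells)
    prof = p4.precision_profile(table, trend_form=None)
    rec = p4.recovery_table(table)
    path = tmp_path / "report.csv"
    p4.write_validation_report({"precision": prof, "recovery": rec}, path)
    lines = path.read_text().strip().splitlines()
    header = lines[0].split(",")
    row = dict(zip(header, lines[1].split(",")))
    assert row["level_id"] == "L1"
    assert row["rb_pct"] == "" and row["teo_ab"] == ""  # comparison stage absent
    assert row["srb_pct"] != ""
    # decimals=3 leaves three places
    p4.write_validation_report({"precision": prof, "recovery": rec}, path, decimals=3)
    row3 = dict(zip(header, path.read_text().strip().splitlines()[1].split(",")))
    assert len(row3["mean_measured"].split(".")[1]) == 3


def test_report_requires_some_stage(tmp_path):
    with pytest.raises(DataFormatError):
        p4.write_validation_report({}, tmp_path / "r.csv")


def test_measurement_invariants():
    with pytest.raises(DataFormatError):
        p4.Measurement(-1.0)
    with pytest.raises(DataFormatError):
        p4.Measurement(1.0, p4.Censoring.BELOW, 0.2)
    with pytest.raises(DataFormatError):
        p4.Measurement(None, p4.Censoring.BELOW, None)
    m = parse_measured_cell(format_measured_cell(p4.Measurement(None, p4.Censoring.ABOVE, 40.0)))
    assert m.censored == p4.Censoring.ABOVE and m.limit == 40.0
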