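import numpy as np
import pandas as pd
import pytest

import p4valid as p4


def noise_free_model(baseline=0.3, srb_intercept=0.0, srb_slope=0.0, **kw):
    """Degenerate error model: no replicate noise, no day effect."""
    return p4.ErrorModel(
        baseline_mean=baseline,
        baseline_sd=0.0,
        cv_intercept=0.0,
        cv_slope=0.0,
        cv_min=0.0,
        sd_between_day=0.0,
        srb_intercept=srb_intercept,
        srb_slope=srb_slope,
        **kw,
    )


def make_levels(spikes, matrix="plasma"):
    return [
        p4.SpikeLevel("P0" if s == 0 else f"L{i}", float(s), matrix)
        for i, s in enumerate(sorted(spikes))
    ]


def table_from_cells(cells, matrix="plasma", n_days=None, n_reps=None):
    """Build a ReplicateTable from (level_id, spiked, day, rep, value) rows."""
    df = pd.DataFrame(
        [(l, s, d, r, float(v), "none", np.nan) for l, s, d, r, v in cells],
        columns=["level_id", "spiked", "day", "replicate", "value", "censored", "limit"],
    )
    return p4.ReplicateTable(
        df,
        matrix=matrix,
        n_days=n_days or int(df["day"].max()),
        n_reps=n_reps or int(df["replicate"].max()),
    )


def one_level_table(values_by_day, level_id="L1", spiked=1.0):
    cells = [
        (level_id, spiked, day, rep, v)
        for day, vals in values_by_day.items()
        for rep, v in enumerate(vals, start=1)
    ]
    return table_from_cells(cells)


@pytest.fixture(scope="session")
def plasma_panel():
    """Default plasma-model spike panel, censoring resolved."""
    t = p4.simulate_spike_panel(
        p4.default_plasma_levels(), 5, 5, p4.default_plasma_model(), seed=11
    )
    return p4.resolve_censored(t)


@pytest.fixture(scope="session")
def paired_40():
    return p4.simulate_paired_comparison(40, p4.ComparisonModel(), seed=11)
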