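"""Synthetic spike panels, QC panels and two-laboratory comparison sets.

The generator emulates a chemiluminescent immunoassay measuring progesterone
in pooled cattle serum/plasma: a low endogenous baseline, concentration-
dependent proportional imprecision (CV% falling with log concentration),
concentration-dependent recovery loss, a shared multiplicative run (day)
effect, and censored reporting outside the calibrated 0.2-40 ng/mL range.

Every stochastic element is driven by one integer seed, so identical seeds
yield bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    Censoring,
    DataFormatError,
    Measurement,
    PairedComparison,
    QCPanel,
    ReplicateTable,
    SpikeLevel,
    _REPLICATE_COLUMNS,
    _measurement_row,
)

__all__ = [
    "ErrorModel",
    "ComparisonModel",
    "default_plasma_model",
    "default_plasma_levels",
    "simulate_spike_panel",
    "simulate_qc_panel",
    "simulate_paired_comparison",
]


@dataclass(frozen=True)
class ErrorModel:
    """Generative error model for one matrix.

    Within-run imprecision follows ``CV%(c) = cv_intercept + cv_slope *
    log10(c)`` floored at ``cv_min``; recovery loss follows ``SRB%(c) =
    srb_intercept + srb_slope * log10(c)`` so the multiplicative recovery
    factor is ``1 + SRB%(c)/100``.  The defaults are the plasma trendlines
    fitted in the validation study this package reproduces, so synthetic
    panels statistically resemble a real plasma panel.
    """

    baseline_mean: float = 0.30   # endogenous matrix P4, ng/mL
    baseline_sd: float = 0.0      # pool-to-pool spread of the baseline
    cv_intercept: float = 8.9     # CV% at 1 ng/mL
    cv_slope: float = -1.7        # CV% change per decade of concentration
    cv_min: float = 0.5           # floor so CV stays positive at high c
    sd_between_day: float = 0.05  # relative SD of the shared day effect
    srb_intercept: float = -20.7  # spiking-recovery bias % at 1 ng/mL
    srb_slope: float = 3.3        # SRB% change per decade
    lower_report_limit: float = 0.2
    upper_report_limit: float = 40.0

    def cv_within(self, c: float) -> float:
        """Within-run CV% at true concentration ``c`` (ng/mL)."""
        if c <= 0:
            raise DataFormatError(f"cv_within undefined at c={c}")
        return max(self.cv_min, self.cv_intercept + self.cv_slope * math.log10(c))

    def recovery(self, c: float) -> float:
        """Multiplicative recovery factor at true concentration ``c``."""
        if c <= 0:
            raise DataFormatError(f"recovery undefined at c={c}")
        r = 1.0 + (self.srb_intercept + self.srb_slope * math.log10(c)) / 100.0
        if r <= 0:
            raise DataFormatError(f"recovery factor {r:.3f} <= 0 at c={c}")
        return r

    def true_level_concentration(self, spiked: float, baseline: float | None = None) -> float:
        """Recovered true concentration of a level: (baseline + spiked) * recovery.

        A zero-concentration level (blank-like: baseline 0, nothing spiked)
        has true concentration 0 and will be emitted entirely censored.
        """
        b = self.baseline_mean if baseline is None else baseline
        c = b + spiked
        if c == 0:
            return 0.0
        return c * self.recovery(c)


@dataclass(frozen=True)
class ComparisonModel:
    """Generative model for a paired two-laboratory dataset.

    Lab A reports the truth with proportional noise; lab B applies a linear
    systematic transform (slope/intercept of B versus A) before its own
    noise.  ``concentration_law`` gives the distribution of true sample
    concentrations as ``("loguniform" | "uniform", low, high)``.
    """

    slope_b_vs_a: float = 1.09
    intercept_b_vs_a: float = 0.05  # ng/mL
    cv_a: float = 5.0               # analytical CV%, lab A
    cv_b: float = 5.0               # analytical CV%, lab B
    concentration_law: tuple[str, float, float] = ("loguniform", 0.3, 28.0)

    def __post_init__(self) -> None:
        if self.slope_b_vs_a <= 0:
            raise DataFormatError("comparison slope must be > 0")
        if self.cv_a < 0 or self.cv_b < 0:
            raise DataFormatError("lab CVs must be >= 0")
        law, lo, hi = self.concentration_law
        if law not in ("loguniform", "uniform") or not 0 < lo < hi:
            raise DataFormatError(f"bad concentration law {self.concentration_law!r}")


def default_plasma_model() -> ErrorModel:
    """Plasma error model with the study's fitted trendline constants."""
    return ErrorModel(baseline_mean=0.30, baseline_sd=0.03)


def default_plasma_levels() -> list[SpikeLevel]:
    """The plasma spiking design: control plus 0.4-30 ng/mL added P4."""
    spikes = [0.0, 0.4, 0.7, 1.0, 2.0, 5.0, 7.0, 10.0, 15.0, 20.0, 30.0]
    out = []
    for i, s in enumerate(spikes):
        lid = "P0" if s == 0 else f"L{i}"
        out.append(SpikeLevel(lid, s, "plasma"))
    return out


def default_serum_levels() -> list[SpikeLevel]:
    """The serum spiking design: control plus 0.5-40 ng/mL added P4."""
    spikes = [0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0]
    out = []
    for i, s in enumerate(spikes):
        lid = "S0" if s == 0 else f"S{i}"
        out.append(SpikeLevel(lid, s, "serum"))
    return out


def _draw_baseline(model: ErrorModel, rng: np.random.Generator) -> float:
    if model.baseline_sd == 0:
        b = model.baseline_mean
    else:
        b = float(rng.normal(model.baseline_mean, model.baseline_sd))
    if b < 0 or (b == 0 and model.baseline_sd > 0):
        raise DataFormatError(
            f"drawn baseline {b:.3f} <= 0; model misconfiguration "
            f"(baseline_mean={model.baseline_mean}, baseline_sd={model.baseline_sd})"
        )
    return b


def _day_effects(n_days: int, rel_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Mean-one lognormal run effects, one per day, shared across levels."""
    if rel_sd == 0:
        return np.ones(n_days)
    sigma = math.sqrt(math.log1p(rel_sd**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_days))


def _censor(value: float, model: ErrorModel) -> Measurement:
    if value < model.lower_report_limit:
        return Measurement(None, Censoring.BELOW, model.lower_report_limit)
    if value > model.upper_report_limit:
        return Measurement(None, Censoring.ABOVE, model.upper_report_limit)
    return Measurement(float(value))


def simulate_spike_panel(
    levels: Sequence[SpikeLevel],
    n_days: int,
    n_reps: int,
    model: ErrorModel,
    seed: int,
) -> ReplicateTable:
    """Simulate a full spike panel (all levels x days x replicates).

    measured(level, day, rep) = truth * day_effect(day) * (1 + e), with
    truth = (baseline + spiked) * recovery(baseline + spiked), one shared
    day effect per day, and e ~ Normal(0, (CV%(truth)/100)^2).  Values
    outside the reporting range are emitted censored.
    """
    if not levels:
        raise DataFormatError("no spike levels given")
    matrices = {lv.matrix for lv in levels}
    if len(matrices) != 1:
        raise DataFormatError("levels must share one matrix")
    if sum(lv.is_control for lv in levels) != 1:
        raise DataFormatError("panel requires exactly one control (spiked = 0) level")
    if len({lv.spiked for lv in levels}) != len(levels):
        raise DataFormatError("spiked amounts must be unique within a panel")

    rng = np.random.default_rng(seed)
    baseline = _draw_baseline(model, rng)
    day_eff = _day_effects(n_days, model.sd_between_day, rng)

    rows = []
    for lv in sorted(levels, key=lambda l: l.spiked):
        truth = model.true_level_concentration(lv.spiked, baseline)
        if truth < 0:
            raise DataFormatError(f"true concentration < 0 at level {lv.level_id}")
        cv = model.cv_within(truth) if truth > 0 else 0.0
        for day in range(1, n_days + 1):
            noise = rng.normal(0.0, cv / 100.0, size=n_reps)
            for rep in range(1, n_reps + 1):
                value = truth * day_eff[day - 1] * (1.0 + noise[rep - 1])
                m = _censor(value, model)
                rows.append((lv.level_id, lv.spiked, day, rep, *_measurement_row(m)))
    df = pd.DataFrame(rows, columns=_REPLICATE_COLUMNS)
    return ReplicateTable(
        data=df,
        matrix=levels[0].matrix,
        n_days=n_days,
        n_reps=n_reps,
        meta={"seed": seed, "baseline": baseline, "model": model.__dict__.copy()},
    )


def simulate_qc_panel(
    nominals: Sequence[float],
    n_days: int,
    n_reps: int,
    model: ErrorModel,
    seed: int,
    apply_recovery: bool = False,
) -> QCPanel:
    """Simulate replicate runs of commercial QC materials.

    QC materials are artificial assay-matched matrices at stated nominal
    targets, so by default the matrix recovery loss does not apply and bias
    against the nominal arises only from run effects and noise; set
    ``apply_recovery`` to impose the model's recovery profile as well.
    """
    if any(n <= 0 for n in nominals):
        raise DataFormatError("nominal QC targets must be > 0")
    rng = np.random.default_rng(seed)
    day_eff = _day_effects(n_days, model.sd_between_day, rng)
    rows = []
    for k, nominal in enumerate(sorted(nominals), start=1):
        truth = nominal * (model.recovery(nominal) if apply_recovery else 1.0)
        cv = model.cv_within(truth)
        for day in range(1, n_days + 1):
            noise = rng.normal(0.0, cv / 100.0, size=n_reps)
            for rep in range(1, n_reps + 1):
                value = truth * day_eff[day - 1] * (1.0 + noise[rep - 1])
                m = _censor(value, model)
                rows.append((f"QC{k}", nominal, day, rep, *_measurement_row(m)))
    df = pd.DataFrame(
        rows,
        columns=["qc_level_id", "nominal", "day", "replicate", "value", "censored", "limit"],
    )
    return QCPanel(df, n_days=n_days, n_reps=n_reps, meta={"seed": seed})


def _draw_truths(
    law: tuple[str, float, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    kind, lo, hi = law
    if kind == "loguniform":
        return np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    return rng.uniform(lo, hi, size=n)


def simulate_paired_comparison(
    n: int,
    model: ComparisonModel,
    seed: int,
) -> PairedComparison:
    """Simulate ``n`` samples measured by two laboratories.

    value_a = truth * (1 + e_a); value_b = (intercept + slope * truth) *
    (1 + e_b), with e_lab ~ Normal(0, (cv_lab/100)^2).
    """
    if n < 3:
        raise DataFormatError("need n >= 3 paired samples")
    rng = np.random.default_rng(seed)
    truth = _draw_truths(model.concentration_law, n, rng)
    e_a = rng.normal(0.0, model.cv_a / 100.0, size=n)
    e_b = rng.normal(0.0, model.cv_b / 100.0, size=n)
    value_a = truth * (1.0 + e_a)
    value_b = (model.intercept_b_vs_a + model.slope_b_vs_a * truth) * (1.0 + e_b)
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(1, n + 1)],
            "value_a": value_a,
            "value_b": value_b,
        }
    )
    return PairedComparison(df)
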