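"""Precision profiling, spiking recovery, and detection limits.

Conventions (all stated in result metadata):

* within-run CV% of a level = unweighted mean over days of 100*sd/mean of
  that day's replicates (sample SD, n-1 denominator);
* between-run CV% = 100*sd/mean over the daily means;
* overall CVs = unweighted mean of the per-level CVs over spiked levels;
* recovery% = 100*(mean measured - control mean)/spiked, SRB% = recovery - 100;
* LOB = blank mean + 1.65*SD, LOD = control mean + 1.65*SD, LOQ(level) =
  level mean + 2*SD, each over the daily-mean (between-run) series.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import DataFormatError, ReplicateTable, SpikeLevel

__all__ = [
    "AnalysisError",
    "LevelPrecision",
    "TrendlineFit",
    "PrecisionProfile",
    "LevelRecovery",
    "RecoveryResult",
    "LoqEntry",
    "DetectionLimits",
    "within_run_cv",
    "between_run_cv",
    "grand_mean",
    "precision_profile",
    "fit_cv_trendline",
    "recovery_percent",
    "recovery_table",
    "detection_limits",
]


class AnalysisError(ValueError):
    """Raised when a statistic cannot be computed from the data given."""


# ---------------------------------------------------------------------------
# CV primitives


def _cv_pct(values: np.ndarray) -> float:
    mean = values.mean()
    if mean <= 0:
        raise AnalysisError("mean <= 0, CV undefined")
    return 100.0 * values.std(ddof=1) / mean


def within_run_cv(
    table: ReplicateTable, level_id: str, day: int | None = None
) -> float:
    """Within-run (repeatability) CV% of one level.

    Per-day CVs (sample SD over that day's replicates) are averaged over
    all days with at least two uncensored replicates; ``day`` restricts the
    calculation to a single run, reproducing a day-1-only protocol.
    """
    groups = table.day_groups(level_id)
    if day is not None:
        groups = {d: v for d, v in groups.items() if d == day}
    day_cvs = []
    for d, vals in sorted(groups.items()):
        if vals.size < 2:
            continue
        if vals.mean() <= 0:
            _warnings.warn(
                f"level {level_id} day {d}: nonpositive day mean, excluded",
                stacklevel=2,
            )
            continue
        day_cvs.append(_cv_pct(vals))
    if not day_cvs:
        raise AnalysisError(
            f"level {level_id}: no day with >= 2 uncensored replicates and positive mean"
        )
    return float(np.mean(day_cvs))


def between_run_cv(table: ReplicateTable, level_id: str) -> float:
    """Between-run (reproducibility) CV%: CV over the daily means."""
    means = day_means(table, level_id)
    if len(means) < 2:
        raise AnalysisError(f"level {level_id}: need >= 2 days with usable means")
    return float(_cv_pct(np.array(sorted(means.items()))[:, 1]))


def day_means(table: ReplicateTable, level_id: str) -> dict[int, float]:
    """Mean of uncensored replicates per day."""
    return {d: float(v.mean()) for d, v in table.day_groups(level_id).items()}


def grand_mean(table: ReplicateTable, level_id: str) -> float:
    """Mean of all uncensored replicates of a level, pooled over days."""
    v = table.values(level_id)
    if not v.size:
        raise AnalysisError(f"level {level_id}: no uncensored values")
    return float(v.mean())


# ---------------------------------------------------------------------------
# precision profile


@dataclass(frozen=True)
class LevelPrecision:
    level_id: str
    spiked: float
    mean_measured: float
    within_cv_pct: float
    between_cv_pct: float | None


@dataclass(frozen=True)
class TrendlineFit:
    """CV trendline: ``linlog`` CV% = a + b*log10(c); ``quadratic``
    CV% = a + b*c + c2*c^2.  ``coefficients`` in ascending-term order."""

    form: str
    coefficients: tuple[float, ...]
    r_squared: float

    def predict(self, c: float) -> float:
        if self.form == "linlog":
            a, b = self.coefficients
            return a + b * math.log10(c)
        a, b, c2 = self.coefficients
        return a + b * c + c2 * c * c


@dataclass
class PrecisionProfile:
    levels: list[LevelPrecision]
    overall_within_cv_pct: float
    overall_between_cv_pct: float | None
    trendline: TrendlineFit | None = None
    meta: dict = field(default_factory=dict)

    def level(self, level_id: str) -> LevelPrecision:
        for lv in self.levels:
            if lv.level_id == level_id:
                return lv
        raise KeyError(level_id)


def precision_profile(
    table: ReplicateTable,
    day: int | None = None,
    trend_form: str | None = "linlog",
    include_control: bool = False,
) -> PrecisionProfile:
    """Per-level within- and between-run CVs plus the CV trendline.

    Overall CVs are the unweighted means of the per-level CVs over spiked
    levels (the control is excluded unless ``include_control``).  With a
    ``day`` filter the between-run CVs are undefined and omitted.
    """
    rows: list[LevelPrecision] = []
    for lv in table.levels():
        if lv.is_control and not include_control:
            continue
        wcv = within_run_cv(table, lv.level_id, day=day)
        bcv = None
        if day is None:
            try:
                bcv = between_run_cv(table, lv.level_id)
            except AnalysisError:
                bcv = None
        rows.append(
            LevelPrecision(lv.level_id, lv.spiked, grand_mean(table, lv.level_id), wcv, bcv)
        )
    if not rows:
        raise AnalysisError("no spiked levels with computable precision")
    spiked_rows = [r for r in rows if r.spiked > 0]
    overall_w = float(np.mean([r.within_cv_pct for r in spiked_rows]))
    bcvs = [r.between_cv_pct for r in spiked_rows if r.between_cv_pct is not None]
    overall_b = float(np.mean(bcvs)) if bcvs else None
    profile = PrecisionProfile(
        rows,
        overall_w,
        overall_b,
        meta={"day_filter": day, "within_cv": "mean of per-day CVs"},
    )
    if trend_form is not None and len(spiked_rows) >= (3 if trend_form == "quadratic" else 2):
        profile.trendline = fit_cv_trendline(profile, form=trend_form)
    return profile


def fit_cv_trendline(
    profile: PrecisionProfile | Mapping[float, float],
    form: str = "linlog",
    which: str = "within",
) -> TrendlineFit:
    """Least-squares CV-versus-concentration trendline.

    ``profile`` is a :class:`PrecisionProfile` (CVs taken against the
    spiked concentrations, control excluded) or a mapping concentration ->
    CV%.  ``form='linlog'`` regresses CV% on log10(concentration);
    ``form='quadratic'`` on (c, c^2).
    """
    if form not in ("linlog", "quadratic"):
        raise AnalysisError(f"unknown trendline form {form!r}")
    if isinstance(profile, PrecisionProfile):
        pts = {
            r.spiked: (r.within_cv_pct if which == "within" else r.between_cv_pct)
            for r in profile.levels
            if r.spiked > 0
        }
        if any(v is None for v in pts.values()):
            raise AnalysisError("between-run CVs unavailable for trendline")
    else:
        pts = dict(profile)
    conc = np.array(sorted(pts))
    cv = np.array([pts[c] for c in conc], dtype=float)
    min_pts = 3 if form == "quadratic" else 2
    if conc.size < min_pts:
        raise AnalysisError(f"{form} trendline needs >= {min_pts} levels")
    if form == "linlog":
        if (conc <= 0).any():
            raise AnalysisError("linlog trendline needs concentrations > 0")
        X = np.column_stack([np.ones_like(conc), np.log10(conc)])
    else:
        X = np.column_stack([np.ones_like(conc), conc, conc**2])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise AnalysisError("singular design: concentrations do not identify the trendline")
    coef, *_ = np.linalg.lstsq(X, cv, rcond=None)
    fitted = X @ coef
    ss_res = float(((cv - fitted) ** 2).sum())
    ss_tot = float(((cv - cv.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 and ss_res < 1e-24 else (1.0 - ss_res / ss_tot if ss_tot else 0.0)
    return TrendlineFit(form, tuple(float(c) for c in coef), r2)


# ---------------------------------------------------------------------------
# recovery


@dataclass(frozen=True)
class LevelRecovery:
    level_id: str
    spiked: float
    mean_measured: float
    recovery_pct: float
    srb_pct: float  # always recovery_pct - 100


@dataclass
class RecoveryResult:
    control_mean: float
    levels: list[LevelRecovery]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for r in self.levels:
            if abs(r.srb_pct - (r.recovery_pct - 100.0)) > 1e-9:
                raise AnalysisError(f"SRB invariant violated at {r.level_id}")

    def level(self, level_id: str) -> LevelRecovery:
        for r in self.levels:
            if r.level_id == level_id:
                return r
        raise KeyError(level_id)


def recovery_percent(
    table: ReplicateTable, level: SpikeLevel | str, control_mean: float
) -> LevelRecovery:
    """Recovery% of one spiked level against the unspiked matrix control.

    recovery = 100 * (mean measured - control_mean) / spiked;
    SRB = recovery - 100.
    """
    if isinstance(level, str):
        sub = table.level_frame(level)
        level = SpikeLevel(level, float(sub["spiked"].iloc[0]), table.matrix)
    if level.spiked == 0:
        raise AnalysisError("control level (spiked = 0) is not a recovery level")
    mean = grand_mean(table, level.level_id)
    rec = 100.0 * (mean - control_mean) / level.spiked
    return LevelRecovery(level.level_id, level.spiked, mean, rec, rec - 100.0)


def recovery_table(
    table: ReplicateTable, control_mean: float | None = None
) -> RecoveryResult:
    """Recovery/SRB for every spiked level.

    The control mean defaults to the grand mean of the panel's spiked = 0
    level pooled over all days (after censoring resolution).
    """
    if control_mean is None:
        ctrl = table.control_level()
        if ctrl is None:
            raise AnalysisError("no control (spiked = 0) level and no control_mean given")
        control_mean = grand_mean(table, ctrl.level_id)
    rows = [
        recovery_percent(table, lv, control_mean)
        for lv in table.levels()
        if not lv.is_control
    ]
    if not rows:
        raise AnalysisError("no spiked levels to compute recovery for")
    return RecoveryResult(float(control_mean), rows)


# ---------------------------------------------------------------------------
# detection limits


@dataclass(frozen=True)
class LoqEntry:
    level_id: str
    loq: float
    between_cv_pct: float


@dataclass
class DetectionLimits:
    lob: float | None
    lod: float | None
    loq_by_level: dict[str, LoqEntry]
    warnings: list[str] = field(default_factory=list)


def _series_limit(day_values: Mapping[int, Sequence[float]] | Sequence[float], k: float) -> float:
    """mean + k*SD over a daily-mean series (between-run convention)."""
    if isinstance(day_values, Mapping):
        series = np.array([np.mean(v) for _, v in sorted(day_values.items())], dtype=float)
    else:
        series = np.asarray(day_values, dtype=float)
    if series.size < 2:
        raise AnalysisError("need >= 2 daily values for a detection limit")
    return float(series.mean() + k * series.std(ddof=1))


def detection_limits(
    table: ReplicateTable,
    blank: Sequence[float] | Mapping[int, Sequence[float]] | None = None,
    loq_level_ids: Sequence[str] | None = None,
) -> DetectionLimits:
    """Limit of blank / detection / quantification from daily-mean series.

    * LOB = blank mean + 1.65 SD (``blank``: daily means of distilled-water
      replicates, or day -> replicate values; omitted -> LOB is None);
    * LOD = control mean + 1.65 SD over the matrix-control daily means;
    * LOQ(level) = level mean + 2 SD, reported with that level's
      between-run CV%.

    A series with fewer than two usable daily values invalidates only its
    own limit (recorded in ``warnings``).
    """
    warns: list[str] = []

    lob = None
    if blank is not None:
        try:
            lob = _series_limit(blank, 1.65)
        except AnalysisError as exc:
            warns.append(f"LOB: {exc}")

    lod = None
    ctrl = table.control_level()
    if ctrl is None:
        warns.append("LOD: no control (spiked = 0) level in table")
    else:
        try:
            lod = _series_limit(table.day_groups(ctrl.level_id), 1.65)
        except AnalysisError as exc:
            warns.append(f"LOD: {exc}")

    if loq_level_ids is None:
        loq_level_ids = [lv.level_id for lv in table.levels() if not lv.is_control]
    loq: dict[str, LoqEntry] = {}
    for lid in loq_level_ids:
        try:
            value = _series_limit(table.day_groups(lid), 2.0)
            loq[lid] = LoqEntry(lid, value, between_run_cv(table, lid))
        except AnalysisError as exc:
            warns.append(f"LOQ {lid}: {exc}")
    return DetectionLimits(lob, lod, loq, warns)
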