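"""Observed total analytical error (Westgard): TEo% = 2*CV% + |bias%|.

Three variants differ only in the bias source paired with the within-run
CV of each spiking level:

* TEo_SR - spiking-recovery bias of the level itself;
* TEo_RB - range-based bias: the mean interlaboratory percentage
  difference of the concentration bin covering the level;
* TEo_AB - average-based bias: the overall Bland-Altman mean percentage
  difference, identical for every level.

The QC variant pairs the between-run CV of a QC level with its percent
deviation from the nominal target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .comparison import BlandAltmanResult, ConcentrationBin
from .core_io import QCPanel
from .precision import AnalysisError, PrecisionProfile, RecoveryResult, _cv_pct

__all__ = [
    "teo",
    "TotalErrorRow",
    "TotalErrorTable",
    "teo_sr_table",
    "teo_rb_table",
    "teo_ab_table",
    "merge_total_error",
    "QCLevelSummary",
    "qc_summary",
]


def teo(cv_pct: float, bias_pct: float) -> float:
    """Observed total error: 2*CV% + |bias%|."""
    if cv_pct < 0:
        raise AnalysisError(f"negative CV% ({cv_pct})")
    return 2.0 * cv_pct + abs(bias_pct)


@dataclass
class TotalErrorRow:
    level_id: str
    spiked: float
    cv_pct: float
    sr_bias_pct: float | None = None
    rb_bias_pct: float | None = None
    ab_bias_pct: float | None = None
    teo_sr: float | None = None
    teo_rb: float | None = None
    teo_ab: float | None = None


@dataclass
class TotalErrorTable:
    rows: list[TotalErrorRow]
    cv_source: str = "within-run"
    meta: dict = field(default_factory=dict)

    def row(self, level_id: str) -> TotalErrorRow:
        for r in self.rows:
            if r.level_id == level_id:
                return r
        raise KeyError(level_id)

    def mean_teo_sr(self, level_ids: Sequence[str] | None = None) -> float:
        """Unweighted mean TEo_SR, optionally over a level subset."""
        rows = self.rows if level_ids is None else [self.row(l) for l in level_ids]
        vals = [r.teo_sr for r in rows if r.teo_sr is not None]
        if not vals:
            raise AnalysisError("no TEo_SR values to average")
        return float(np.mean(vals))


def _spiked_levels(profile: PrecisionProfile):
    return [r for r in profile.levels if r.spiked > 0]


def teo_sr_table(profile: PrecisionProfile, recovery: RecoveryResult) -> TotalErrorTable:
    """TEo_SR per level: within-run CV paired with that level's SRB."""
    prof = {r.level_id: r for r in _spiked_levels(profile)}
    rec = {r.level_id: r for r in recovery.levels}
    unmatched = sorted(set(prof) ^ set(rec))
    if unmatched:
        raise AnalysisError(f"precision/recovery levels do not align: {unmatched}")
    rows = []
    for lid in sorted(prof, key=lambda l: prof[l].spiked):
        p, r = prof[lid], rec[lid]
        rows.append(
            TotalErrorRow(
                level_id=lid,
                spiked=p.spiked,
                cv_pct=p.within_cv_pct,
                sr_bias_pct=r.srb_pct,
                teo_sr=teo(p.within_cv_pct, r.srb_pct),
            )
        )
    return TotalErrorTable(rows, meta={"bias_source": "spiking-recovery"})


def _assign_bin(spiked: float, bins: Sequence[ConcentrationBin]) -> ConcentrationBin:
    """Bin whose pair-mean range contains the level, else nearest midpoint."""
    for b in bins:
        if b.range[0] <= spiked <= b.range[1]:
            return b
    return min(bins, key=lambda b: abs((b.range[0] + b.range[1]) / 2.0 - spiked))


def teo_rb_table(
    profile: PrecisionProfile, bins: Sequence[ConcentrationBin]
) -> TotalErrorTable:
    """TEo_RB per level: within-run CV paired with the covering bin's bias."""
    if not bins:
        raise AnalysisError("no concentration bins given")
    rows = []
    assignment = {}
    for p in sorted(_spiked_levels(profile), key=lambda r: r.spiked):
        b = _assign_bin(p.spiked, bins)
        assignment[p.level_id] = b.bin_id
        rows.append(
            TotalErrorRow(
                level_id=p.level_id,
                spiked=p.spiked,
                cv_pct=p.within_cv_pct,
                rb_bias_pct=b.bin_bias_pct,
                teo_rb=teo(p.within_cv_pct, b.bin_bias_pct),
            )
        )
    return TotalErrorTable(
        rows, meta={"bias_source": "range-based", "bin_assignment": assignment}
    )


def teo_ab_table(profile: PrecisionProfile, ba: BlandAltmanResult) -> TotalErrorTable:
    """TEo_AB per level: within-run CV paired with the overall mean % bias."""
    if ba.mode != "percent":
        raise AnalysisError("TEo_AB needs a percent-mode Bland-Altman result")
    rows = []
    for p in sorted(_spiked_levels(profile), key=lambda r: r.spiked):
        rows.append(
            TotalErrorRow(
                level_id=p.level_id,
                spiked=p.spiked,
                cv_pct=p.within_cv_pct,
                ab_bias_pct=ba.mean_bias,
                teo_ab=teo(p.within_cv_pct, ba.mean_bias),
            )
        )
    return TotalErrorTable(rows, meta={"bias_source": "average-based"})


def merge_total_error(*tables: TotalErrorTable) -> TotalErrorTable:
    """Combine variant tables (same levels) into one row set."""
    tables = [t for t in tables if t is not None]
    if not tables:
        raise AnalysisError("nothing to merge")
    merged: dict[str, TotalErrorRow] = {}
    meta: dict = {}
    for t in tables:
        meta.update(t.meta)
        for r in t.rows:
            m = merged.setdefault(
                r.level_id, TotalErrorRow(r.level_id, r.spiked, r.cv_pct)
            )
            for f in ("sr_bias_pct", "rb_bias_pct", "ab_bias_pct", "teo_sr", "teo_rb", "teo_ab"):
                v = getattr(r, f)
                if v is not None:
                    setattr(m, f, v)
    rows = sorted(merged.values(), key=lambda r: (r.spiked, r.level_id))
    return TotalErrorTable(rows, meta=meta)


# ---------------------------------------------------------------------------
# QC panels


@dataclass(frozen=True)
class QCLevelSummary:
    qc_level_id: str
    nominal: float
    grand_mean: float
    within_cv_pct: float
    between_cv_pct: float
    bias_pct: float  # 100 * |grand mean - nominal| / nominal
    teo_pct: float  # 2 * between-run CV + bias


def qc_summary(panel: QCPanel) -> list[QCLevelSummary]:
    """Precision, bias against nominal, and TEo for each QC level.

    The grand mean is the mean of the daily means; the TEo convention for
    QC materials uses the between-run CV (day-to-day stability is what QC
    monitors).
    """
    out = []
    for lid in panel.level_ids():
        groups = panel.day_groups(lid)
        if len(groups) < 2:
            raise AnalysisError(f"QC level {lid}: need >= 2 days")
        day_cvs = [_cv_pct(v) for v in groups.values() if v.size >= 2]
        if not day_cvs:
            raise AnalysisError(f"QC level {lid}: need >= 2 replicates in some day")
        within = float(np.mean(day_cvs))
        dmeans = np.array([v.mean() for _, v in sorted(groups.items())])
        between = float(_cv_pct(dmeans))
        gmean = float(dmeans.mean())
        nominal = panel.nominal(lid)
        bias = 100.0 * abs(gmean - nominal) / nominal
        out.append(
            QCLevelSummary(lid, nominal, gmean, within, between, bias, teo(between, bias))
        )
    return out
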