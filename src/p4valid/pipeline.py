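"""End-to-end orchestration of the validation protocol.

``run_validation`` executes the three phases of a full immunoassay
validation on one configuration: the spiking-recovery phase (linearity,
precision, recovery, detection limits), the interlaboratory comparison
phase (Passing-Bablok, Bland-Altman, concentration bins), and the
total-error phase (TEo_SR / TEo_RB / TEo_AB plus the QC summary).  Inputs
come either from CSV files or from the synthetic generator; all randomness
flows from the single configured seed, so two runs with identical config
and seed produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import comparison as cmp
from . import core_io, linearity, precision, synthetic, total_error

log = logging.getLogger("p4valid")

__all__ = ["ValidationConfig", "StageError", "run_validation"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial results were written."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


_DEFAULT_STAGES = {
    "panel": True,
    "linearity": True,
    "precision": True,
    "recovery": True,
    "limits": True,
    "comparison": True,
    "total_error": True,
    "qc": True,
}


@dataclass
class ValidationConfig:
    """Everything one validation run needs.

    File inputs (``panel_csv``/``pairs_csv``/``qc_csv``) take precedence;
    any missing input is simulated from the error model, which requires a
    seed.  The defaults mirror a 5-day x 5-replicate plasma spike panel
    with a 40-sample two-laboratory comparison set and 3 QC levels.
    """

    outdir: str | Path = "p4valid_out"
    seed: int | None = None
    panel_csv: str | None = None
    pairs_csv: str | None = None
    qc_csv: str | None = None
    matrix: str = "plasma"
    n_days: int = 5
    n_reps: int = 5
    n_comparison: int = 40
    spiked_levels: list[float] | None = None
    error_model: dict = field(default_factory=dict)
    comparison_model: dict = field(default_factory=dict)
    qc_nominals: list[float] = field(default_factory=lambda: [0.64, 7.5, 20.9])
    blank_day_means: list[float] | None = None
    stages: dict = field(default_factory=dict)
    censor_policy: str = "substitute_limit"
    day_filter: int | None = None
    linearity_day: int | None = 1
    trend_form: str = "linlog"
    alpha: float = 0.05
    n_bins: int = 5
    decimals: int = 1
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "ValidationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise core_io.DataFormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def stage_enabled(self, name: str) -> bool:
        return {**_DEFAULT_STAGES, **self.stages}.get(name, True)


def _error_model(cfg: ValidationConfig) -> synthetic.ErrorModel:
    base = synthetic.default_plasma_model()
    return dataclasses.replace(base, **cfg.error_model)


def _levels(cfg: ValidationConfig) -> list[synthetic.SpikeLevel]:
    if cfg.spiked_levels is not None:
        out = []
        for i, s in enumerate(sorted(cfg.spiked_levels)):
            lid = ("P0" if cfg.matrix == "plasma" else "S0") if s == 0 else f"L{i}"
            out.append(synthetic.SpikeLevel(lid, float(s), cfg.matrix))
        return out
    if cfg.matrix == "serum":
        return synthetic.default_serum_levels()
    return synthetic.default_plasma_levels()


def _acquire_panel(cfg: ValidationConfig) -> core_io.ReplicateTable:
    if cfg.panel_csv:
        log.info("reading spike panel from %s", cfg.panel_csv)
        return core_io.read_replicate_table(cfg.panel_csv)
    if cfg.seed is None:
        raise core_io.DataFormatError("seed is mandatory when simulating the panel")
    log.info("simulating spike panel (seed %d)", cfg.seed)
    return synthetic.simulate_spike_panel(
        _levels(cfg), cfg.n_days, cfg.n_reps, _error_model(cfg), cfg.seed
    )


def _acquire_pairs(cfg: ValidationConfig) -> core_io.PairedComparison:
    if cfg.pairs_csv:
        log.info("reading paired comparison from %s", cfg.pairs_csv)
        return core_io.read_paired_comparison(cfg.pairs_csv)
    if cfg.seed is None:
        raise core_io.DataFormatError("seed is mandatory when simulating comparison data")
    model = synthetic.ComparisonModel(**cfg.comparison_model)
    return synthetic.simulate_paired_comparison(cfg.n_comparison, model, cfg.seed + 1)


def _acquire_qc(cfg: ValidationConfig) -> core_io.QCPanel:
    if cfg.qc_csv:
        log.info("reading QC panel from %s", cfg.qc_csv)
        return core_io.read_qc_panel(cfg.qc_csv)
    if cfg.seed is None:
        raise core_io.DataFormatError("seed is mandatory when simulating the QC panel")
    return synthetic.simulate_qc_panel(
        cfg.qc_nominals, cfg.n_days, cfg.n_reps, _error_model(cfg), cfg.seed + 2
    )


def _write_outputs(results: dict, cfg: ValidationConfig, outdir: Path) -> dict[str, Path]:
    paths: dict[str, Path] = {}
    reportable = {k: results.get(k) for k in ("precision", "recovery", "total_error")}
    if any(v is not None for v in reportable.values()):
        paths["report_csv"] = core_io.write_validation_report(
            reportable, outdir / "report.csv", decimals=cfg.decimals
        )
    if results:
        paths["results_json"] = core_io.write_results_json(
            results, outdir / "results.json"
        )
    return paths


def run_validation(config: ValidationConfig) -> dict:
    """Run all enabled stages; return results plus written file paths.

    A failing stage raises :class:`StageError` naming the stage after the
    results of every completed stage have been written to ``outdir``.
    """
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(cfg).items()
        }
    }

    def run_stage(name: str, fn):
        if not cfg.stage_enabled(name):
            log.info("stage %s disabled", name)
            return None
        log.info("running stage %s", name)
        try:
            return fn()
        except Exception as exc:
            _write_outputs(results, cfg, outdir)
            raise StageError(name, exc) from exc

    panel = run_stage("panel", lambda: _acquire_panel(cfg))
    if panel is not None:
        resolved = core_io.resolve_censored(panel, cfg.censor_policy)
        results["panel_meta"] = dict(resolved.meta)

        def _linearity():
            means = {
                lv.spiked: resolved.values(lv.level_id, day=cfg.linearity_day).mean()
                for lv in resolved.levels()
                if not lv.is_control
            }
            return linearity.fit_linearity(means, alpha=cfg.alpha)

        results["linearity"] = run_stage("linearity", _linearity)
        results["precision"] = run_stage(
            "precision",
            lambda: precision.precision_profile(
                resolved, day=cfg.day_filter, trend_form=cfg.trend_form
            ),
        )
        results["recovery"] = run_stage("recovery", lambda: precision.recovery_table(resolved))
        results["limits"] = run_stage(
            "limits",
            lambda: precision.detection_limits(resolved, blank=cfg.blank_day_means),
        )

    pairs = ba = bins = None
    if cfg.stage_enabled("comparison"):
        def _comparison():
            nonlocal pairs, ba, bins
            pairs = _acquire_pairs(cfg)
            pb = cmp.passing_bablok(pairs, alpha=cfg.alpha)
            ba = cmp.bland_altman(pairs, mode="percent")
            ba_abs = cmp.bland_altman(pairs, mode="absolute")
            bins = cmp.bin_by_concentration(pairs, n_bins=cfg.n_bins)
            return {
                "passing_bablok": pb,
                "bland_altman_percent": ba,
                "bland_altman_absolute": ba_abs,
                "bins": bins,
            }

        results["comparison"] = run_stage("comparison", _comparison)

    def _total_error():
        profile, recov = results.get("precision"), results.get("recovery")
        if profile is None or recov is None:
            raise precision.AnalysisError("total error needs the precision and recovery stages")
        tables = [total_error.teo_sr_table(profile, recov)]
        if bins is not None:
            tables.append(total_error.teo_rb_table(profile, bins))
        if ba is not None:
            tables.append(total_error.teo_ab_table(profile, ba))
        return total_error.merge_total_error(*tables)

    if panel is not None:
        results["total_error"] = run_stage("total_error", _total_error)

    def _qc():
        return total_error.qc_summary(_acquire_qc(cfg))

    results["qc"] = run_stage("qc", _qc)

    paths = _write_outputs(results, cfg, outdir)
    if cfg.plots:
        paths.update(_make_plots(results, pairs, outdir))
    results["paths"] = paths
    log.info("wrote %s", ", ".join(str(p) for p in paths.values()))
    return results


def _make_plots(results: Mapping, pairs, outdir: Path) -> dict[str, Path]:
    from . import plots

    out: dict[str, Path] = {}
    prof = results.get("precision")
    if prof is not None:
        out["cv_plot"] = plots.plot_cv_profile(prof, outdir / "cv_profile.png")
    fit = results.get("linearity")
    if fit is not None and prof is not None:
        spiked = [r.spiked for r in prof.levels if r.spiked > 0]
        measured = [r.mean_measured for r in prof.levels if r.spiked > 0]
        out["linearity_plot"] = plots.plot_linearity(
            spiked, measured, fit, outdir / "linearity.png"
        )
    comp = results.get("comparison")
    if comp is not None and pairs is not None:
        out["pb_plot"] = plots.plot_passing_bablok(
            pairs, comp["passing_bablok"], outdir / "passing_bablok.png"
        )
        out["ba_plot"] = plots.plot_bland_altman(
            pairs, comp["bland_altman_percent"], outdir / "bland_altman.png"
        )
    return out
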