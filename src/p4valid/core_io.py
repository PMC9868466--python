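"""Domain types and file formats shared by every validation stage.

The central container is :class:`ReplicateTable`: a long-format table of
replicate measurements keyed by ``(level_id, day, replicate)``, carrying the
spiked analyte amount per level and per-cell censoring state.  Analyzers
report concentrations outside their calibrated range only as ``"<limit"`` or
``">limit"``; those cells are kept as censored markers until a resolution
policy is applied with :func:`resolve_censored`.

All concentrations are ng/mL.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_EVEN
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Censoring",
    "CensorPolicy",
    "Measurement",
    "SpikeLevel",
    "ReplicateTable",
    "PairedComparison",
    "QCPanel",
    "DataFormatError",
    "DuplicateKeyError",
    "parse_measured_cell",
    "format_measured_cell",
    "read_replicate_table",
    "write_replicate_table",
    "read_paired_comparison",
    "write_paired_comparison",
    "read_qc_panel",
    "resolve_censored",
    "round_half_even",
    "write_validation_report",
    "write_results_json",
]

MATRICES = ("serum", "plasma")


class DataFormatError(ValueError):
    """Raised for malformed or invalid input tables."""


class DuplicateKeyError(DataFormatError):
    """Raised when a replicate key occurs more than once."""


class Censoring(str, Enum):
    NONE = "none"
    BELOW = "below"
    ABOVE = "above"


class CensorPolicy(str, Enum):
    """How to turn censored cells into point values (or remove them)."""

    SUBSTITUTE_LIMIT = "substitute_limit"
    SUBSTITUTE_HALF_LIMIT = "substitute_half_limit"
    DROP = "drop"


@dataclass(frozen=True)
class Measurement:
    """A single reported concentration, possibly censored at a limit.

    Exactly one semantics is active: either ``value`` holds an uncensored
    nonnegative concentration (``censored == NONE``, ``limit is None``), or
    the cell is censored and ``limit`` holds the reporting limit while
    ``value`` is ``None``.
    """

    value: float | None
    censored: Censoring = Censoring.NONE
    limit: float | None = None

    def __post_init__(self) -> None:
        if self.censored == Censoring.NONE:
            if self.value is None or self.limit is not None:
                raise DataFormatError(
                    "uncensored measurement must carry a value and no limit"
                )
            if self.value < 0:
                raise DataFormatError(f"negative concentration {self.value!r}")
        else:
            if self.value is not None or self.limit is None:
                raise DataFormatError(
                    "censored measurement carries only a reporting limit"
                )
            if self.limit <= 0:
                raise DataFormatError(f"nonpositive censoring limit {self.limit!r}")

    @property
    def is_censored(self) -> bool:
        return self.censored != Censoring.NONE


@dataclass(frozen=True)
class SpikeLevel:
    """One spiking level of a panel: a label, the added amount, the matrix."""

    level_id: str
    spiked: float
    matrix: str = "plasma"

    def __post_init__(self) -> None:
        if self.spiked < 0:
            raise DataFormatError(f"negative spiked amount for {self.level_id}")
        if self.matrix not in MATRICES:
            raise DataFormatError(f"unknown matrix {self.matrix!r}")

    @property
    def is_control(self) -> bool:
        return self.spiked == 0


_REPLICATE_COLUMNS = ["level_id", "spiked", "day", "replicate", "value", "censored", "limit"]


@dataclass
class ReplicateTable:
    """Long-format replicate measurements of a spike panel.

    ``data`` columns: level_id (str), spiked (float), day (int >= 1),
    replicate (int >= 1), value (float, NaN when censored), censored
    ({none, below, above}), limit (float, NaN when uncensored).
    """

    data: pd.DataFrame
    matrix: str
    n_days: int
    n_reps: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _REPLICATE_COLUMNS if c not in df.columns]
        if missing:
            raise DataFormatError(f"replicate table missing columns {missing}")
        if self.matrix not in MATRICES:
            raise DataFormatError(f"unknown matrix {self.matrix!r}")
        keys = df[["level_id", "day", "replicate"]]
        dup = keys[keys.duplicated()]
        if len(dup):
            first = tuple(dup.iloc[0])
            raise DuplicateKeyError(f"duplicate replicate key {first}")
        if (df["day"] < 1).any() or (df["day"] > self.n_days).any():
            raise DataFormatError(f"day outside 1..{self.n_days}")
        if (df["replicate"] < 1).any() or (df["replicate"] > self.n_reps).any():
            raise DataFormatError(f"replicate outside 1..{self.n_reps}")
        spiked_per_level = df.groupby("level_id")["spiked"].nunique()
        if (spiked_per_level > 1).any():
            bad = spiked_per_level[spiked_per_level > 1].index[0]
            raise DataFormatError(f"level {bad!r} has inconsistent spiked amounts")
        level_per_spike = df.groupby("spiked")["level_id"].nunique()
        if (level_per_spike > 1).any():
            bad = level_per_spike[level_per_spike > 1].index[0]
            raise DataFormatError(f"spiked amount {bad!r} used by multiple levels")
        n_controls = df.loc[df["spiked"] == 0, "level_id"].nunique()
        if n_controls > 1:
            raise DataFormatError("more than one control (spiked = 0) level")
        uncens = df["censored"] == Censoring.NONE.value
        if (df.loc[uncens, "value"] < 0).any():
            raise DataFormatError("negative uncensored value")

    # -- accessors ---------------------------------------------------------

    def levels(self) -> list[SpikeLevel]:
        """Spike levels in ascending spiked order."""
        g = self.data.groupby("level_id")["spiked"].first().reset_index()
        g = g.sort_values(["spiked", "level_id"])
        return [
            SpikeLevel(r.level_id, float(r.spiked), self.matrix)
            for r in g.itertuples()
        ]

    def control_level(self) -> SpikeLevel | None:
        for lv in self.levels():
            if lv.is_control:
                return lv
        return None

    def level_frame(self, level_id: str) -> pd.DataFrame:
        sub = self.data[self.data["level_id"] == level_id]
        if sub.empty:
            raise KeyError(f"no level {level_id!r} in table")
        return sub

    def values(self, level_id: str, day: int | None = None) -> np.ndarray:
        """Uncensored values for a level, optionally restricted to one day."""
        sub = self.level_frame(level_id)
        if day is not None:
            sub = sub[sub["day"] == day]
        sub = sub[sub["censored"] == Censoring.NONE.value]
        return sub["value"].to_numpy(dtype=float)

    def day_groups(self, level_id: str) -> dict[int, np.ndarray]:
        """Uncensored values per day (days with no usable value omitted)."""
        out: dict[int, np.ndarray] = {}
        for day in sorted(self.level_frame(level_id)["day"].unique()):
            v = self.values(level_id, day=int(day))
            if v.size:
                out[int(day)] = v
        return out

    def missing_cells(self) -> list[tuple[str, int, int]]:
        """Keys of the full (level, day, replicate) grid absent from the data."""
        have = set(
            map(tuple, self.data[["level_id", "day", "replicate"]].itertuples(index=False))
        )
        out = []
        for lv in self.levels():
            for day in range(1, self.n_days + 1):
                for rep in range(1, self.n_reps + 1):
                    if (lv.level_id, day, rep) not in have:
                        out.append((lv.level_id, day, rep))
        return out

    @property
    def has_censored(self) -> bool:
        return bool((self.data["censored"] != Censoring.NONE.value).any())


@dataclass
class PairedComparison:
    """Paired measurements of the same samples by two laboratories."""

    data: pd.DataFrame  # columns: sample_id, value_a, value_b
    label_a: str = "lab A"
    label_b: str = "lab B"

    def __post_init__(self) -> None:
        for c in ("sample_id", "value_a", "value_b"):
            if c not in self.data.columns:
                raise DataFormatError(f"paired table missing column {c!r}")
        if self.data["sample_id"].duplicated().any():
            raise DuplicateKeyError("duplicate sample_id in paired table")
        vals = self.data[["value_a", "value_b"]]
        if vals.isna().any().any():
            raise DataFormatError("paired values must be uncensored point values")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def a(self) -> np.ndarray:
        return self.data["value_a"].to_numpy(dtype=float)

    @property
    def b(self) -> np.ndarray:
        return self.data["value_b"].to_numpy(dtype=float)


@dataclass
class QCPanel:
    """Replicates of commercial QC materials with nominal target values.

    ``data`` columns: qc_level_id, nominal, day, replicate, value, censored,
    limit — same keying rules as :class:`ReplicateTable`.
    """

    data: pd.DataFrame
    n_days: int
    n_reps: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = ["qc_level_id", "nominal", "day", "replicate", "value", "censored", "limit"]
        missing = [c for c in need if c not in self.data.columns]
        if missing:
            raise DataFormatError(f"QC panel missing columns {missing}")
        if (self.data["nominal"] <= 0).any():
            raise DataFormatError("nominal QC target must be > 0")
        keys = self.data[["qc_level_id", "day", "replicate"]]
        if keys.duplicated().any():
            raise DuplicateKeyError("duplicate (qc_level_id, day, replicate) key")

    def level_ids(self) -> list[str]:
        g = self.data.groupby("qc_level_id")["nominal"].first().sort_values()
        return list(g.index)

    def nominal(self, qc_level_id: str) -> float:
        sub = self.data[self.data["qc_level_id"] == qc_level_id]
        if sub.empty:
            raise KeyError(f"no QC level {qc_level_id!r}")
        return float(sub["nominal"].iloc[0])

    def day_groups(self, qc_level_id: str) -> dict[int, np.ndarray]:
        sub = self.data[self.data["qc_level_id"] == qc_level_id]
        out: dict[int, np.ndarray] = {}
        for day in sorted(sub["day"].unique()):
            d = sub[(sub["day"] == day) & (sub["censored"] == Censoring.NONE.value)]
            v = d["value"].to_numpy(dtype=float)
            if v.size:
                out[int(day)] = v
        return out


# ---------------------------------------------------------------------------
# cell parsing / formatting


def parse_measured_cell(
    cell: str | float,
    below_prefix: str = "<",
    above_prefix: str = ">",
) -> Measurement:
    """Parse a measured-value cell, honouring ``"<0.2"``-style censoring."""
    if isinstance(cell, (int, float)) and not isinstance(cell, bool):
        return Measurement(float(cell))
    text = str(cell).strip()
    if text.startswith(below_prefix):
        return Measurement(None, Censoring.BELOW, float(text[len(below_prefix):]))
    if text.startswith(above_prefix):
        return Measurement(None, Censoring.ABOVE, float(text[len(above_prefix):]))
    return Measurement(float(text))


def format_measured_cell(m: Measurement) -> str:
    if m.censored == Censoring.BELOW:
        return f"<{m.limit!r}"
    if m.censored == Censoring.ABOVE:
        return f">{m.limit!r}"
    return repr(float(m.value))


def _measurement_row(m: Measurement) -> tuple[float, str, float]:
    return (
        math.nan if m.value is None else float(m.value),
        m.censored.value,
        math.nan if m.limit is None else float(m.limit),
    )


# ---------------------------------------------------------------------------
# readers / writers


def read_replicate_table(
    path: str | Path,
    below_prefix: str = "<",
    above_prefix: str = ">",
) -> ReplicateTable:
    """Read a long-format spike-panel CSV.

    Expected header: ``matrix,level_id,spiked,day,replicate,measured``.
    Censored cells are written as e.g. ``<0.2`` or ``>40``.
    """
    raw = pd.read_csv(path, dtype=str).rename(columns=str.strip)
    need = ["matrix", "level_id", "spiked", "day", "replicate", "measured"]
    missing = [c for c in need if c not in raw.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}")
    matrices = set(raw["matrix"].str.strip())
    if len(matrices) != 1:
        raise DataFormatError(f"{path}: expected a single matrix, got {sorted(matrices)}")
    matrix = matrices.pop()
    if matrix not in MATRICES:
        raise DataFormatError(f"{path}: unknown matrix label {matrix!r}")

    rows = []
    for idx, r in enumerate(raw.itertuples(index=False), start=2):  # header = line 1
        try:
            m = parse_measured_cell(r.measured, below_prefix, above_prefix)
        except (ValueError, DataFormatError) as exc:
            raise DataFormatError(
                f"{path}: line {idx}: bad measured cell {r.measured!r} ({exc})"
            ) from None
        try:
            rows.append(
                (
                    str(r.level_id).strip(),
                    float(r.spiked),
                    int(r.day),
                    int(r.replicate),
                    *_measurement_row(m),
                )
            )
        except ValueError as exc:
            raise DataFormatError(f"{path}: line {idx}: {exc}") from None
    df = pd.DataFrame(rows, columns=_REPLICATE_COLUMNS)
    return ReplicateTable(
        data=df,
        matrix=matrix,
        n_days=int(df["day"].max()),
        n_reps=int(df["replicate"].max()),
        meta={"source": str(path)},
    )


def write_replicate_table(table: ReplicateTable, path: str | Path) -> Path:
    """Write a :class:`ReplicateTable` in the long CSV dialect (round-trips)."""
    path = Path(path)
    lines = ["matrix,level_id,spiked,day,replicate,measured"]
    for r in table.data.itertuples(index=False):
        if r.censored == Censoring.NONE.value:
            m = Measurement(float(r.value))
        else:
            m = Measurement(None, Censoring(r.censored), float(r.limit))
        lines.append(
            f"{table.matrix},{r.level_id},{r.spiked!r},{int(r.day)},"
            f"{int(r.replicate)},{format_measured_cell(m)}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_paired_comparison(
    path: str | Path, label_a: str = "lab A", label_b: str = "lab B"
) -> PairedComparison:
    """Read a paired two-laboratory CSV with header ``sample_id,value_a,value_b``."""
    df = pd.read_csv(path).rename(columns=str.strip)
    need = ["sample_id", "value_a", "value_b"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}")
    df = df[need].copy()
    df["sample_id"] = df["sample_id"].astype(str)
    return PairedComparison(df, label_a=label_a, label_b=label_b)


def write_paired_comparison(pairs: PairedComparison, path: str | Path) -> Path:
    path = Path(path)
    lines = ["sample_id,value_a,value_b"]
    for r in pairs.data.itertuples(index=False):
        lines.append(f"{r.sample_id},{float(r.value_a)!r},{float(r.value_b)!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_qc_panel(
    path: str | Path,
    below_prefix: str = "<",
    above_prefix: str = ">",
) -> QCPanel:
    """Read a QC-panel CSV with header ``qc_level_id,nominal,day,replicate,measured``."""
    raw = pd.read_csv(path, dtype=str).rename(columns=str.strip)
    need = ["qc_level_id", "nominal", "day", "replicate", "measured"]
    missing = [c for c in need if c not in raw.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns {missing}")
    rows = []
    for idx, r in enumerate(raw.itertuples(index=False), start=2):
        try:
            m = parse_measured_cell(r.measured, below_prefix, above_prefix)
            rows.append(
                (
                    str(r.qc_level_id).strip(),
                    float(r.nominal),
                    int(r.day),
                    int(r.replicate),
                    *_measurement_row(m),
                )
            )
        except (ValueError, DataFormatError) as exc:
            raise DataFormatError(f"{path}: line {idx}: {exc}") from None
    df = pd.DataFrame(
        rows,
        columns=["qc_level_id", "nominal", "day", "replicate", "value", "censored", "limit"],
    )
    return QCPanel(df, n_days=int(df["day"].max()), n_reps=int(df["replicate"].max()))


# ---------------------------------------------------------------------------
# censoring resolution


def resolve_censored(
    table: ReplicateTable,
    policy: CensorPolicy | str = CensorPolicy.SUBSTITUTE_LIMIT,
) -> ReplicateTable:
    """Replace censored cells by point values according to ``policy``.

    ``substitute_limit`` uses the reporting limit itself (conservative for
    below-limit cells), ``substitute_half_limit`` uses half the limit, and
    ``drop`` removes the cells.  The applied policy and any (level, day)
    group emptied by ``drop`` are recorded in ``meta``.
    """
    policy = CensorPolicy(policy)
    df = table.data.copy()
    cens = df["censored"] != Censoring.NONE.value
    warnings: list[str] = []
    if policy == CensorPolicy.DROP:
        kept = df[~cens]
        for (lvl, day), grp in df[cens].groupby(["level_id", "day"]):
            rest = kept[(kept["level_id"] == lvl) & (kept["day"] == day)]
            if rest.empty:
                warnings.append(
                    f"drop policy removed every replicate of ({lvl}, day {int(day)})"
                )
        df = kept.reset_index(drop=True)
    else:
        factor = 1.0 if policy == CensorPolicy.SUBSTITUTE_LIMIT else 0.5
        df.loc[cens, "value"] = df.loc[cens, "limit"] * factor
        df.loc[cens, "censored"] = Censoring.NONE.value
        df.loc[cens, "limit"] = math.nan
    meta = dict(table.meta)
    meta["censor_policy"] = policy.value
    if warnings:
        meta["censor_warnings"] = warnings
    return ReplicateTable(df, table.matrix, table.n_days, table.n_reps, meta)


# ---------------------------------------------------------------------------
# report output


def round_half_even(x: float | None, decimals: int = 1) -> float | None:
    """Round half to even at ``decimals`` places (banker's rounding)."""
    if x is None:
        return None
    x = float(x)
    if math.isnan(x):
        return None
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


def _fmt(x: float | None, decimals: int) -> str:
    r = round_half_even(x, decimals)
    return "" if r is None else f"{r:.{decimals}f}"


def write_validation_report(
    results: Mapping,
    path: str | Path,
    decimals: int = 1,
) -> Path:
    """Write the per-level summary table (CSV) combining all stage outputs.

    ``results`` may contain ``precision`` (PrecisionProfile), ``recovery``
    (RecoveryResult) and ``total_error`` (TotalErrorTable); absent stages
    leave their columns blank.  One row per spiked level, columns: level_id,
    spiked, mean_measured, within_cv_pct, srb_pct, rb_pct, ab_pct, teo_sr,
    teo_rb, teo_ab.  Values are rounded half-to-even to ``decimals``.
    """
    profile = results.get("precision")
    recovery = results.get("recovery")
    te = results.get("total_error")
    if profile is None and recovery is None and te is None:
        raise DataFormatError("no stage results to report")

    level_ids: list[str] = []
    spiked: dict[str, float] = {}
    for src in (profile, recovery, te):
        if src is None:
            continue
        for row in src.levels if hasattr(src, "levels") else src.rows:
            lid = row.level_id
            if lid not in spiked:
                level_ids.append(lid)
                spiked[lid] = row.spiked
    level_ids.sort(key=lambda lid: (spiked[lid], lid))

    def stage_map(src, attr):
        if src is None:
            return {}
        rows = src.levels if hasattr(src, "levels") else src.rows
        return {r.level_id: getattr(r, attr, None) for r in rows}

    mean_m = stage_map(profile, "mean_measured")
    wcv = stage_map(profile, "within_cv_pct")
    srb = stage_map(recovery, "srb_pct")
    rb = stage_map(te, "rb_bias_pct")
    ab = stage_map(te, "ab_bias_pct")
    tsr = stage_map(te, "teo_sr")
    trb = stage_map(te, "teo_rb")
    tab = stage_map(te, "teo_ab")

    path = Path(path)
    lines = [
        "level_id,spiked,mean_measured,within_cv_pct,srb_pct,rb_pct,ab_pct,"
        "teo_sr,teo_rb,teo_ab"
    ]
    for lid in level_ids:
        cells = [
            lid,
            _fmt(spiked[lid], decimals),
            _fmt(mean_m.get(lid), decimals),
            _fmt(wcv.get(lid), decimals),
            _fmt(srb.get(lid), decimals),
            _fmt(rb.get(lid), decimals),
            _fmt(ab.get(lid), decimals),
            _fmt(tsr.get(lid), decimals),
            _fmt(trb.get(lid), decimals),
            _fmt(tab.get(lid), decimals),
        ]
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path


def _jsonable(obj):
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj


def write_results_json(results: Mapping, path: str | Path) -> Path:
    """Dump every fitted stage object to one JSON document."""
    path = Path(path)
    path.write_text(json.dumps(_jsonable(results), indent=2, allow_nan=False) + "\n")
    return path
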