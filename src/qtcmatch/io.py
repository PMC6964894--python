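"""Readers and writers for trajectory CSV files, result TSVs and run configs.

Input dialect: long (tidy) delimited text with header
``timestamp,object_id,x,y`` — UTF-8, '.' decimal separator, seconds and
metres.  Timestamps must be uniform and complete per object; the sample
interval is inferred from consecutive rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .matching import MatchResult
from .trajectory import StaticPoint, Trajectory

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "write_results",
    "write_annotations",
    "field_corner_statics",
    "parse_statics_spec",
    "RunConfig",
    "load_config",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("timestamp", "object_id", "x", "y")

#: Absolute tolerance (seconds) for uniform-timestamp validation.
TIME_TOLERANCE = 1e-9


def read_trajectories(
    source: Union[str, Path, TextIO], dialect: str = ","
) -> dict[str, Trajectory]:
    """Parse a long-format trajectory file into one Trajectory per object.

    ``dialect`` is the column delimiter.  Validation errors name the
    offending file row (1-based, header = row 1).
    """
    df = pd.read_csv(source, sep=dialect, dtype={"object_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {missing}")
    if df.empty:
        return {}

    for col in ("timestamp", "x", "y"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.index[values.isna() & df[col].notna()]
        if len(bad) or values.isna().any():
            row = int((bad if len(bad) else values.index[values.isna()])[0]) + 2
            raise ValidationError(f"non-numeric {col!r} value at row {row}")
        df[col] = values.astype(float)

    dup = df.duplicated(subset=["timestamp", "object_id"], keep="first")
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ValidationError(f"duplicate (timestamp, object_id) at row {row}")

    out: dict[str, Trajectory] = {}
    for oid, grp in df.groupby("object_id", sort=True):
        grp = grp.sort_values("timestamp")
        t = grp["timestamp"].to_numpy()
        if len(t) < 2:
            row = int(grp.index[0]) + 2
            raise ValidationError(
                f"object {oid!r} has a single sample (row {row}); "
                "cannot infer the sample interval"
            )
        dt = np.diff(t)
        if np.any(np.abs(dt - dt[0]) > TIME_TOLERANCE):
            bad_pos = int(np.argmax(np.abs(dt - dt[0]) > TIME_TOLERANCE))
            row = int(grp.index[bad_pos + 1]) + 2
            raise ValidationError(
                f"object {oid!r}: non-uniform timestamps near row {row} "
                f"(expected spacing {dt[0]}, found {dt[bad_pos]})"
            )
        if dt[0] <= 0:
            raise ValidationError(f"object {oid!r}: non-increasing timestamps")
        out[str(oid)] = Trajectory(
            str(oid), grp[["x", "y"]].to_numpy(), float(dt[0])
        )
    return out


def write_trajectories(
    recording: Mapping[str, Trajectory],
    sink: Union[str, Path, TextIO],
) -> None:
    """Write a recording in the long CSV dialect (deterministic ordering)."""
    frames = []
    for oid in sorted(recording):
        tr = recording[oid]
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": np.arange(tr.n_samples) * tr.sample_interval,
                    "object_id": oid,
                    "x": tr.positions[:, 0],
                    "y": tr.positions[:, 1],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(REQUIRED_COLUMNS)
    )
    df.to_csv(sink, index=False, float_format="%.6f")


RESULT_COLUMNS = (
    "rank",
    "start_index",
    "end_index",
    "start_seconds",
    "raw_cost",
    "normalized_distance",
    "permutation",
)


def _format_permutation(perm: Optional[dict[str, str]]) -> str:
    if not perm:
        return "-"
    return ";".join(f"{k}->{v}" for k, v in sorted(perm.items()))


def write_results(
    results: Sequence[MatchResult], sink: Union[str, Path, TextIO]
) -> None:
    """Write ranked match results as TSV (normalized distance to 6 decimals)."""
    lines = ["\t".join(RESULT_COLUMNS)]
    for r in results:
        raw = r.raw_cost
        raw_str = str(int(raw)) if float(raw) == int(raw) else f"{raw:.6f}"
        lines.append(
            "\t".join(
                [
                    str(r.rank),
                    str(r.start_index),
                    str(r.end_index),
                    f"{r.start_seconds:.3f}",
                    raw_str,
                    f"{r.normalized:.6f}",
                    _format_permutation(r.permutation_used),
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text, encoding="utf-8")


def write_annotations(annotations, sink: Union[str, Path, TextIO]) -> None:
    """Side-car TSV naming each planted motif window of a synthetic scene."""
    lines = ["\t".join(("motif_id", "start_index", "end_index", "transform"))]
    for a in annotations:
        lines.append(
            "\t".join(
                [str(a.motif_id), str(a.start_index), str(a.end_index), a.transform]
            )
        )
    text = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text, encoding="utf-8")


#: Standard association-football pitch dimensions, metres.
DEFAULT_FIELD = (105.0, 68.0)


def field_corner_statics(
    length: float = DEFAULT_FIELD[0], width: float = DEFAULT_FIELD[1]
) -> tuple[StaticPoint, ...]:
    """Four static anchor points at the corners of a pitch with origin (0, 0)."""
    if length <= 0 or width <= 0:
        raise ValidationError("field dimensions must be positive")
    return (
        StaticPoint("corner_SW", (0.0, 0.0)),
        StaticPoint("corner_SE", (length, 0.0)),
        StaticPoint("corner_NW", (0.0, width)),
        StaticPoint("corner_NE", (length, width)),
    )


def parse_statics_spec(
    spec: str,
    field_length: float = DEFAULT_FIELD[0],
    field_width: float = DEFAULT_FIELD[1],
) -> tuple[StaticPoint, ...]:
    """Parse a static-point specification string.

    ``"none"`` → no statics; ``"field-corners"`` → the four pitch corners;
    otherwise ``id:x:y`` entries separated by ';'.
    """
    spec = spec.strip()
    if spec in ("", "none"):
        return ()
    if spec == "field-corners":
        return field_corner_statics(field_length, field_width)
    points = []
    for entry in spec.split(";"):
        parts = entry.split(":")
        if len(parts) != 3:
            raise ValidationError(
                f"bad static point entry {entry!r}; expected id:x:y"
            )
        try:
            points.append(StaticPoint(parts[0], (float(parts[1]), float(parts[2]))))
        except ValueError as exc:
            raise ValidationError(f"bad static point entry {entry!r}: {exc}") from exc
    return tuple(points)


@dataclass
class RunConfig:
    """Flat configuration mirroring the CLI flags of the ``match`` command."""

    input: str = ""
    players: tuple[str, ...] = ()
    ref_start: int = 0
    ref_len: int = 500
    window: Optional[int] = None
    stride: int = 10
    downsample: int = 10
    epsilon: float = 0.0
    top_k: int = 9
    statics: str = "none"
    field_length: float = DEFAULT_FIELD[0]
    field_width: float = DEFAULT_FIELD[1]
    char_costs: Optional[str] = None  # "d01,d02,d12" override of -/0, -/+, 0/+
    permute: tuple[str, ...] = ()
    seed: int = 0
    output: str = "results.tsv"

    def __post_init__(self) -> None:
        self.players = tuple(self.players)
        self.permute = tuple(self.permute)
        for name in ("ref_len", "stride", "downsample", "top_k"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.ref_start < 0:
            raise ValidationError("ref_start must be >= 0")
        if self.field_length <= 0 or self.field_width <= 0:
            raise ValidationError("field dimensions must be positive")


_LIST_KEYS = {"players", "permute"}


def load_config(path: Union[str, Path]) -> dict:
    """Read a flat key-value config file (YAML mapping of flag names)."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValidationError(f"config {path} must be a flat key-value mapping")
    valid = set(RunConfig.__dataclass_fields__)
    out = {}
    for key, value in data.items():
        key = str(key).replace("-", "_")
        if key not in valid:
            raise ValidationError(f"unknown config key {key!r}")
        if key in _LIST_KEYS and isinstance(value, str):
            value = tuple(v.strip() for v in value.split(",") if v.strip())
        elif key in _LIST_KEYS and isinstance(value, (list, tuple)):
            value = tuple(str(v) for v in value)
        out[key] = value
    return out
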