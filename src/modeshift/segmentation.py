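"""Cutting speed profiles into sequences at zero speed.

A *sequence* is a maximal run of consecutive 1 Hz observations whose
speed exceeds the zero threshold (default: exactly 0 km/h, matching
receivers that log literal zeros when stationary).  Zero-speed points
are pure delimiters and are discarded.  A mode change inside a run also
cuts, so that every sequence carries a single true mode label.

Sequences are binned into four duration strata (<=15 s, 16-30 s,
31-60 s, >60 s) used to stratify classification performance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import ConfigError, DataError, SchemaError
from .trace_io import Trace

#: Duration strata partitioning the positive integers:
#: [1,15], [16,30], [31,60], [61, inf).
STRATUM_LABELS = ("<=15s", "16-30s", "31-60s", ">60s")


def assign_stratum(duration: int) -> str:
    """Duration stratum for a sequence of ``duration`` seconds.

    Boundaries are inclusive as printed: 15 -> first bin, 16 -> second,
    60 -> third, 61 -> fourth.
    """
    if duration < 1:
        raise DataError(f"duration must be >= 1, got {duration}")
    if duration <= 15:
        return STRATUM_LABELS[0]
    if duration <= 30:
        return STRATUM_LABELS[1]
    if duration <= 60:
        return STRATUM_LABELS[2]
    return STRATUM_LABELS[3]


@dataclass
class Sequence:
    """One maximal nonzero-speed run: the unit of classification."""

    person_id: str
    commute_id: str
    mode: str
    speeds: np.ndarray
    start_index: int | None = None  # position in the (filtered) source trace

    def __post_init__(self) -> None:
        self.speeds = np.asarray(self.speeds, dtype=float)
        if self.speeds.size < 1:
            raise DataError("a sequence must contain at least one speed value")

    @property
    def duration(self) -> int:
        """Observation count at 1 Hz (== seconds)."""
        return int(self.speeds.size)

    @property
    def stratum(self) -> str:
        return assign_stratum(self.duration)


def segment_trace(trace: Trace, zero_threshold: float = 0.0) -> list[Sequence]:
    """Cut one trace into sequences wherever speed drops to the threshold.

    Returns the maximal runs of consecutive points with
    ``speed > zero_threshold``; delimiter points are discarded.  A mode
    change inside a run also starts a new sequence.  An all-zero trace
    yields an empty list.
    """
    if zero_threshold < 0:
        raise ConfigError(f"zero_threshold must be >= 0, got {zero_threshold}")
    speeds = trace.speeds
    modes = trace.modes
    active = speeds > zero_threshold
    sequences: list[Sequence] = []
    start = None
    for i in range(len(speeds) + 1):
        boundary = (
            i == len(speeds)
            or not active[i]
            or (start is not None and modes[i] != modes[start])
        )
        if start is not None and boundary:
            sequences.append(
                Sequence(
                    trace.person_id,
                    trace.commute_id,
                    str(modes[start]),
                    speeds[start:i],
                    start_index=start,
                )
            )
            start = None
        if i < len(speeds) and active[i] and start is None:
            start = i
    return sequences


def segment_traces(
    traces: Iterable[Trace], zero_threshold: float = 0.0
) -> list[Sequence]:
    """Segment many traces, concatenating the per-trace sequence lists."""
    out: list[Sequence] = []
    for tr in traces:
        out.extend(segment_trace(tr, zero_threshold))
    return out


# ---------------------------------------------------------------------------
# Sequence table CSV (two dialects)

_BASE_COLS = ("person_id", "commute_id", "mode", "duration_s", "stratum")


def write_sequences_csv(
    sequences: Iterable[Sequence], path: str | Path, dialect: str = "inline"
) -> None:
    """Write the sequence table.

    ``inline`` serialises the speed list into a semicolon-joined column
    (floats via ``repr``, so the round trip is bit exact).  ``pointer``
    stores a (person, commute, start_index) reference into the source
    trace instead.
    """
    if dialect not in ("inline", "pointer"):
        raise ConfigError(f"unknown sequence-table dialect {dialect!r}")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if dialect == "inline":
            writer.writerow(_BASE_COLS + ("speeds",))
            for s in sequences:
                writer.writerow(
                    [s.person_id, s.commute_id, s.mode, s.duration, s.stratum]
                    + [";".join(repr(float(v)) for v in s.speeds)]
                )
        else:
            writer.writerow(_BASE_COLS + ("start_index",))
            for s in sequences:
                if s.start_index is None:
                    raise DataError(
                        "pointer dialect requires sequences with a start_index"
                    )
                writer.writerow(
                    [s.person_id, s.commute_id, s.mode, s.duration, s.stratum]
                    + [s.start_index]
                )


def read_sequences_csv(
    path: str | Path,
    traces: Mapping[tuple[str, str], Trace] | None = None,
) -> list[Sequence]:
    """Read a sequence table written by :func:`write_sequences_csv`.

    The pointer dialect needs ``traces`` keyed by (person_id, commute_id)
    to resolve speed values.
    """
    out: list[Sequence] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        cols = reader.fieldnames or []
        for col in _BASE_COLS:
            if col not in cols:
                raise SchemaError(f"required column {col!r} missing from {path}")
        inline = "speeds" in cols
        if not inline and "start_index" not in cols:
            raise SchemaError(f"{path}: need either a 'speeds' or 'start_index' column")
        for row in reader:
            n = int(row["duration_s"])
            if inline:
                speeds = np.array(
                    [float(v) for v in row["speeds"].split(";")], dtype=float
                )
                start: int | None = None
            else:
                if traces is None:
                    raise DataError(
                        "pointer-dialect sequence table needs the source traces"
                    )
                key = (row["person_id"], row["commute_id"])
                if key not in traces:
                    raise DataError(f"no source trace for sequence key {key}")
                start = int(row["start_index"])
                speeds = traces[key].speeds[start : start + n]
            if len(speeds) != n:
                raise DataError(
                    f"sequence {row['person_id']}/{row['commute_id']}: "
                    f"duration_s={n} but {len(speeds)} speed values"
                )
            out.append(
                Sequence(row["person_id"], row["commute_id"], row["mode"], speeds, start)
            )
    return out
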