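"""Reading, writing and cleaning of 1 Hz GPS speed traces.

A *trace* is one person-commute's ordered track points, each carrying a
speed in km/h (as logged by the receiver or derived from coordinates),
an indoor flag and an annotated true transport mode.  The canonical
interchange format is a UTF-8 CSV with header

    person_id, commute_id, timestamp, speed_kmh, lat, lon, indoor, mode

where ``lat``/``lon`` may be empty, ``indoor`` is 0/1 and ``mode`` is one
of walk, bike, train, bus, car, unknown.  GPX 1.1 is supported as a
convenience reader; speeds are taken from a per-trackpoint ``speed``
extension when present and otherwise derived from consecutive
coordinates via the haversine great-circle distance.
"""

from __future__ import annotations

import csv
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TySequence

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    DuplicateRecordError,
    InvalidIntervalError,
    InvalidRecordError,
    SchemaError,
)

#: Recognised transport-mode labels (``motorized`` appears only after the
#: three-class collapse and never in raw input).
MODES = ("walk", "bike", "train", "bus", "car", "unknown")

#: Mean Earth radius in km (IUGG), used for great-circle distances.
EARTH_RADIUS_KM = 6371.0088

CSV_COLUMNS = (
    "person_id",
    "commute_id",
    "timestamp",
    "speed_kmh",
    "lat",
    "lon",
    "indoor",
    "mode",
)


@dataclass
class TrackPoint:
    """A single 1 Hz GPS observation.

    ``timestamp`` is seconds since trace start.  ``speed`` is km/h and
    must be finite and non-negative; latitude/longitude are optional
    decimal degrees (WGS84).
    """

    timestamp: float
    speed: float
    lat: float | None = None
    lon: float | None = None
    indoor: bool = False
    mode: str = "unknown"

    def __post_init__(self) -> None:
        if not math.isfinite(self.speed) or self.speed < 0:
            raise InvalidRecordError(
                f"speed must be finite and non-negative, got {self.speed!r}"
            )
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise InvalidRecordError(f"latitude out of range: {self.lat!r}")
        if self.lon is not None and not -180.0 <= self.lon <= 180.0:
            raise InvalidRecordError(f"longitude out of range: {self.lon!r}")


@dataclass
class Trace:
    """Ordered track points of one person-commute."""

    person_id: str
    commute_id: str
    points: list[TrackPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        ts = self.timestamps
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise DataError(
                f"timestamps not strictly increasing in trace "
                f"({self.person_id}, {self.commute_id})"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([p.timestamp for p in self.points], dtype=float)

    @property
    def speeds(self) -> np.ndarray:
        return np.array([p.speed for p in self.points], dtype=float)

    @property
    def modes(self) -> np.ndarray:
        return np.array([p.mode for p in self.points], dtype=object)


def _haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a sphere of mean Earth radius."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def derive_speed(p_prev: TrackPoint, p_cur: TrackPoint) -> float:
    """Speed in km/h between two positioned track points.

    Uses the haversine great-circle distance divided by elapsed time.
    The result is unsigned (swapping the points gives the same value).
    """
    for p in (p_prev, p_cur):
        if p.lat is None or p.lon is None:
            raise InvalidRecordError("derive_speed requires lat/lon on both points")
    dt = abs(p_cur.timestamp - p_prev.timestamp)
    if dt == 0:
        raise InvalidIntervalError("cannot derive speed over a zero-length interval")
    dist = _haversine_km(p_prev.lat, p_prev.lon, p_cur.lat, p_cur.lon)
    return dist / (dt / 3600.0)


def read_trace_csv(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[Trace]:
    """Read traces from the canonical CSV format.

    Parameters
    ----------
    path:
        CSV file with at least person_id, commute_id, timestamp and
        speed_kmh columns; ``indoor`` and ``mode`` default to
        false/unknown when absent.
    dialect:
        Optional mapping from canonical column names to the names used
        in the file, e.g. ``{"speed_kmh": "speed"}``.

    Returns one :class:`Trace` per distinct (person_id, commute_id),
    points sorted by timestamp.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    for col in ("person_id", "commute_id", "timestamp", "speed_kmh"):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} missing from {path}")
    if "indoor" not in df.columns:
        df["indoor"] = 0
    if "mode" not in df.columns:
        df["mode"] = "unknown"
    for col in ("lat", "lon"):
        if col not in df.columns:
            df[col] = np.nan

    speeds = pd.to_numeric(df["speed_kmh"], errors="coerce")
    bad = ~np.isfinite(speeds) | (speeds < 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise InvalidRecordError(
            f"row {row}: speed_kmh={df['speed_kmh'].iloc[row]!r} is not a "
            "finite non-negative number"
        )
    df["speed_kmh"] = speeds

    keys = df[["person_id", "commute_id", "timestamp"]].astype(str)
    dup = keys.duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise DuplicateRecordError(
            f"row {row}: duplicate (person_id, commute_id, timestamp) = "
            f"{tuple(keys.iloc[row])}"
        )

    unknown_modes = set(df["mode"].astype(str)) - set(MODES)
    if unknown_modes:
        raise InvalidRecordError(f"unknown mode labels: {sorted(unknown_modes)}")

    traces = []
    for (pid, cid), group in df.groupby(
        ["person_id", "commute_id"], sort=True, dropna=False
    ):
        group = group.sort_values("timestamp")
        points = [
            TrackPoint(
                timestamp=float(r.timestamp),
                speed=float(r.speed_kmh),
                lat=None if pd.isna(r.lat) else float(r.lat),
                lon=None if pd.isna(r.lon) else float(r.lon),
                indoor=bool(int(r.indoor)),
                mode=str(r.mode),
            )
            for r in group.itertuples()
        ]
        traces.append(Trace(str(pid), str(cid), points))
    return traces


def write_trace_csv(traces: Iterable[Trace], path: str | Path) -> None:
    """Write traces in the canonical CSV format.

    Floats are written with ``repr`` (shortest round-tripping form) so a
    read-back reproduces every field bit for bit.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for tr in traces:
            for p in tr.points:
                writer.writerow(
                    [
                        tr.person_id,
                        tr.commute_id,
                        repr(float(p.timestamp)),
                        repr(float(p.speed)),
                        "" if p.lat is None else repr(float(p.lat)),
                        "" if p.lon is None else repr(float(p.lon)),
                        int(p.indoor),
                        p.mode,
                    ]
                )


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _gpx_time_seconds(text: str) -> float:
    # ISO 8601, e.g. 2010-06-01T08:00:05Z
    from datetime import datetime

    text = text.strip().replace("Z", "+00:00")
    return datetime.fromisoformat(text).timestamp()


def read_gpx(path: str | Path) -> list[Trace]:
    """Read GPX 1.1 tracks; each track segment becomes one trace.

    Speeds come from a per-trackpoint ``speed`` extension when present
    (passed through unchanged, assumed km/h) and are otherwise derived
    from consecutive coordinates, which requires ``<time>`` elements.
    Timestamps are re-based to seconds from segment start.
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise DataError(f"malformed GPX file {path}: {exc}") from exc

    traces: list[Trace] = []
    root = tree.getroot()
    tracks = [el for el in root.iter() if _local(el.tag) == "trk"]
    for ti, trk in enumerate(tracks):
        name = next(
            (el.text for el in trk if _local(el.tag) == "name" and el.text), f"track{ti}"
        )
        segs = [el for el in trk.iter() if _local(el.tag) == "trkseg"]
        for si, seg in enumerate(segs):
            raw: list[dict] = []
            for tp in seg:
                if _local(tp.tag) != "trkpt":
                    continue
                rec: dict = {
                    "lat": float(tp.attrib["lat"]),
                    "lon": float(tp.attrib["lon"]),
                    "time": None,
                    "speed": None,
                }
                for child in tp.iter():
                    lt = _local(child.tag)
                    if lt == "time" and child.text:
                        rec["time"] = _gpx_time_seconds(child.text)
                    elif lt == "speed" and child.text is not None:
                        rec["speed"] = float(child.text)
                raw.append(rec)
            if not raw:
                continue
            need_derive = any(r["speed"] is None for r in raw)
            if need_derive and any(r["time"] is None for r in raw):
                raise DataError(
                    f"GPX segment {si} of track {name!r}: trackpoint without "
                    "time but speed must be derived"
                )
            if all(r["time"] is not None for r in raw):
                t0 = raw[0]["time"]
                times = [r["time"] - t0 for r in raw]
            else:
                times = list(range(len(raw)))
            points = [
                TrackPoint(
                    timestamp=times[i],
                    speed=0.0,
                    lat=r["lat"],
                    lon=r["lon"],
                )
                for i, r in enumerate(raw)
            ]
            speeds: list[float] = []
            for i, r in enumerate(raw):
                if r["speed"] is not None:
                    speeds.append(float(r["speed"]))
                elif i > 0:
                    speeds.append(derive_speed(points[i - 1], points[i]))
                else:
                    speeds.append(math.nan)  # patched below
            if speeds and math.isnan(speeds[0]):
                speeds[0] = speeds[1] if len(speeds) > 1 else 0.0
            for p, s in zip(points, speeds):
                p.speed = s
            traces.append(Trace(name, f"seg{si}", points))
    return traces


def filter_indoor(trace: Trace) -> list[Trace]:
    """Drop indoor points and split the trace at the removed runs.

    Each maximal run of surviving points with contiguous (1 s spaced)
    timestamps becomes its own trace, so later segmentation can never
    bridge an indoor gap.  Timestamp gaps larger than one second split
    the trace in exactly the same way, whatever their cause.
    """
    outdoor = [p for p in trace.points if not p.indoor]
    pieces: list[Trace] = []
    run: list[TrackPoint] = []
    for p in outdoor:
        if run and p.timestamp - run[-1].timestamp > 1:
            pieces.append(Trace(trace.person_id, trace.commute_id, run))
            run = []
        run.append(p)
    if run:
        pieces.append(Trace(trace.person_id, trace.commute_id, run))
    return pieces


def trace_from_arrays(
    person_id: str,
    commute_id: str,
    speeds: TySequence[float] | np.ndarray,
    modes: TySequence[str] | np.ndarray,
) -> Trace:
    """Build a gap-free 1 Hz trace from parallel speed/mode arrays."""
    if len(speeds) != len(modes):
        raise DataError("speeds and modes must have the same length")
    points = [
        TrackPoint(timestamp=float(i), speed=float(s), mode=str(m))
        for i, (s, m) in enumerate(zip(speeds, modes))
    ]
    return Trace(person_id, commute_id, points)
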