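"""Per-sequence speed metrics.

Seven metrics summarise each sequence's speed profile S_1..S_N (km/h):

* ``mean``  - arithmetic mean speed.
* ``p95``   - 95th percentile of speed.
* ``sd``    - sample standard deviation (denominator N-1).
* ``rcm``   - rate-of-change metric: the mean absolute successive
  difference (1/(N-1)) * sum |S_n - S_{n-1}|, in km/h per second.
* ``rcm_std`` - rcm divided by sd (dimensionless; 0 when sd == 0).
* ``accel`` - 95th percentile of the consecutive differences
  d_n = S_n - S_{n-1} (high-acceleration proxy).
* ``decel`` - 5th percentile of the differences (braking proxy).

All percentiles use linear interpolation between order statistics at
rank 1 + q*(N-1) ("type 7"), the one convention pinned repo-wide.
Sequences need N >= 2 observations; shorter ones are dropped upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence as TySequence

import numpy as np
import pandas as pd

from .errors import DataError, MetricsError
from .segmentation import Sequence

METRIC_NAMES = ("mean", "p95", "sd", "rcm", "rcm_std", "accel", "decel")


def percentile(values: TySequence[float] | np.ndarray, q: float) -> float:
    """Type-7 percentile: linear interpolation at rank 1 + q*(N-1).

    ``q`` is a fraction in [0, 1]; q=0 gives the minimum, q=1 the
    maximum.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise DataError("percentile of an empty list is undefined")
    if not 0.0 <= q <= 1.0:
        raise DataError(f"q must lie in [0, 1], got {q}")
    return float(np.quantile(arr, q, method="linear"))


@dataclass(frozen=True)
class MetricVector:
    """The seven per-sequence speed metrics (the feature space)."""

    mean: float
    p95: float
    sd: float
    rcm: float
    rcm_std: float
    accel: float
    decel: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def compute_metrics(seq: Sequence | TySequence[float] | np.ndarray) -> MetricVector:
    """Compute the seven speed metrics for one sequence.

    Accepts a :class:`~modeshift.segmentation.Sequence` or a bare speed
    array.  Raises :class:`MetricsError` for fewer than two
    observations (differences and sd are undefined there).
    """
    speeds = seq.speeds if isinstance(seq, Sequence) else np.asarray(seq, dtype=float)
    n = speeds.size
    if n < 2:
        raise MetricsError(f"metrics undefined for a sequence of {n} observation(s)")
    diffs = np.diff(speeds)
    sd = float(np.std(speeds, ddof=1))
    rcm = float(np.mean(np.abs(diffs)))
    return MetricVector(
        mean=float(np.mean(speeds)),
        p95=percentile(speeds, 0.95),
        sd=sd,
        rcm=rcm,
        rcm_std=rcm / sd if sd > 0 else 0.0,
        accel=percentile(diffs, 0.95),
        decel=percentile(diffs, 0.05),
    )


def feature_table(sequences: Iterable[Sequence]) -> pd.DataFrame:
    """Feature table: one row per sequence of duration >= 2.

    Columns: person_id, commute_id, mode, duration_s, stratum and the
    seven metrics.  Sequences too short to featurise are dropped; their
    count is recorded in ``df.attrs["n_dropped_short"]``.
    """
    rows = []
    dropped = 0
    for s in sequences:
        if s.duration < 2:
            dropped += 1
            continue
        row = {
            "person_id": s.person_id,
            "commute_id": s.commute_id,
            "mode": s.mode,
            "duration_s": s.duration,
            "stratum": s.stratum,
        }
        row.update(compute_metrics(s).as_dict())
        rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=["person_id", "commute_id", "mode", "duration_s", "stratum"]
        + list(METRIC_NAMES),
    )
    df.attrs["n_dropped_short"] = dropped
    return df
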