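"""Seeded generator of labelled 1 Hz commute speed traces.

The generator emulates a small commuting cohort (default: 12 persons,
two back-and-forth commutes each) whose per-mode sequence-speed
distributions match published reference statistics for walking,
cycling, train, bus and car travel.  Each commute is a chain of
transport-mode *legs* (a train commuter may cycle to the station); each
leg consists of a few long "main" movement bouts plus a realistic
majority of short stop-go fragments, all separated by runs of exact
zero speed so that zero-speed segmentation recovers the generated bouts
exactly.

Within a bout the speed profile ramps up from standstill at a
mode-specific rate, fluctuates around a cruise level as an AR(1)
process, and ramps back down to standstill.  Per-bout cruise levels are
log-normal (positive support, right skew) with a person-level random
effect, calibrated so that, per mode, the median of per-sequence mean
speed over sequences longer than one minute lands on the reference
median, with the reference IQR:

    walk 4.1 (3.6-4.7), bike 14.9 (13.1-16.4), train 88.3 (75.1-104.0),
    bus 31.1 (24.1-33.7), car 41.7 (35.6-53.9) km/h.

Generation is reproducible bit for bit: a single global seed drives a
counter-based per-person/per-commute substream, so regenerating any
person is order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .segmentation import segment_traces
from .trace_io import Trace, trace_from_arrays

#: Converts an interquartile range ratio to a log-normal sigma:
#: for X log-normal, log(q75/q25) = 2 * 0.6745 * sigma.
_IQR_Z = 2.0 * 0.674489750196082


def _lognormal_sigma(lo: float, hi: float) -> float:
    return math.log(hi / lo) / _IQR_Z


@dataclass(frozen=True)
class ModeProfile:
    """Generator parameters for one transport mode.

    Speeds are km/h, durations seconds, ramp rates km/h per second.
    ``cruise_median``/``cruise_iqr`` calibrate the per-sequence mean
    speed of long (main) bouts; ``bout_duration_*`` their length.
    ``n_bouts_range`` is the short-bout count per leg (inclusive), and
    the ``short_*`` fields the short-bout duration/speed distributions.
    ``ar_coefficient`` and ``noise_sd`` shape the within-bout AR(1)
    speed fluctuation; the innovation scale drives how hard the mode
    accelerates and brakes second to second.
    """

    mode: str
    cruise_median: float
    cruise_iqr: tuple[float, float]
    ar_coefficient: float
    noise_sd: float
    bout_duration_median: float
    bout_duration_iqr: tuple[float, float]
    stop_duration_mean: float
    ramp_rate: float
    n_bouts_range: tuple[int, int]
    n_main_bouts: int
    short_duration_median: float
    short_duration_iqr: tuple[float, float]
    short_speed_median: float
    short_speed_iqr: tuple[float, float]
    person_sigma_frac: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.cruise_iqr
        if not lo < self.cruise_median < hi:
            raise ConfigError(
                f"{self.mode}: cruise_median must lie inside cruise_iqr"
            )
        if min(self.ramp_rate, self.noise_sd, self.stop_duration_mean) <= 0:
            raise ConfigError(f"{self.mode}: rates and durations must be > 0")
        if not 0 <= self.ar_coefficient < 1:
            raise ConfigError(f"{self.mode}: ar_coefficient must lie in [0, 1)")


def default_profiles() -> dict[str, ModeProfile]:
    """Calibrated default profiles for the five transport modes.

    Long-bout speed and duration medians/IQRs follow the reference
    cohort statistics; ramp rates, AR coefficients and innovation SDs
    are plausibility choices (a train accelerates smoothly at about
    0.7 m/s^2; a bus brakes hard and often; walking barely fluctuates).
    """
    return {
        "walk": ModeProfile(
            mode="walk",
            cruise_median=4.1,
            cruise_iqr=(3.6, 4.7),
            ar_coefficient=0.5,
            noise_sd=0.6,
            bout_duration_median=94,
            bout_duration_iqr=(70, 112),
            stop_duration_mean=20,
            ramp_rate=1.0,
            n_bouts_range=(4, 8),
            n_main_bouts=2,
            short_duration_median=3,
            short_duration_iqr=(2, 12),
            short_speed_median=2.0,
            short_speed_iqr=(1.3, 3.4),
        ),
        "bike": ModeProfile(
            mode="bike",
            cruise_median=14.9,
            cruise_iqr=(13.1, 16.4),
            ar_coefficient=0.6,
            noise_sd=1.2,
            bout_duration_median=139,
            bout_duration_iqr=(87, 264),
            stop_duration_mean=15,
            ramp_rate=2.0,
            n_bouts_range=(5, 12),
            n_main_bouts=3,
            short_duration_median=7,
            short_duration_iqr=(2, 30),
            short_speed_median=6.0,
            short_speed_iqr=(2.0, 12.1),
        ),
        "train": ModeProfile(
            mode="train",
            cruise_median=88.3,
            cruise_iqr=(75.1, 104.0),
            ar_coefficient=0.98,
            noise_sd=1.5,
            bout_duration_median=471,
            bout_duration_iqr=(205, 705),
            stop_duration_mean=45,
            ramp_rate=2.5,
            n_bouts_range=(2, 6),
            n_main_bouts=1,
            short_duration_median=6,
            short_duration_iqr=(2, 40),
            short_speed_median=2.6,
            short_speed_iqr=(1.5, 20.0),
        ),
        "bus": ModeProfile(
            mode="bus",
            cruise_median=31.1,
            cruise_iqr=(24.1, 33.7),
            ar_coefficient=0.9,
            noise_sd=4.0,
            bout_duration_median=79,
            bout_duration_iqr=(69, 101),
            stop_duration_mean=25,
            ramp_rate=3.0,
            n_bouts_range=(4, 9),
            n_main_bouts=3,
            short_duration_median=20,
            short_duration_iqr=(5, 45),
            short_speed_median=18.9,
            short_speed_iqr=(6.0, 28.5),
        ),
        "car": ModeProfile(
            mode="car",
            cruise_median=41.7,
            cruise_iqr=(35.6, 53.9),
            ar_coefficient=0.92,
            noise_sd=3.0,
            bout_duration_median=219,
            bout_duration_iqr=(109, 387),
            stop_duration_mean=20,
            ramp_rate=3.0,
            n_bouts_range=(2, 6),
            n_main_bouts=2,
            short_duration_median=30,
            short_duration_iqr=(12, 50),
            short_speed_median=32.9,
            short_speed_iqr=(11.0, 42.0),
        ),
    }


def default_assignment() -> dict[str, tuple[str, ...]]:
    """One plausible person -> commute-leg-chain completion of the
    cohort's mode incidences (walk 2, bike 9, train 5, bus 3, car 3
    persons over 12; multi-mode persons chain legs).

    The true person-mode incidence matrix of the reference cohort is
    unpublished; this synthetic assignment merely reproduces the
    per-mode person counts.
    """
    return {
        "p01": ("walk",),
        "p02": ("walk", "train"),
        "p03": ("bike", "train"),
        "p04": ("bike", "train"),
        "p05": ("bike", "train"),
        "p06": ("bike", "train"),
        "p07": ("bike", "bus"),
        "p08": ("bike", "bus"),
        "p09": ("bike", "bus"),
        "p10": ("bike", "car"),
        "p11": ("bike", "car"),
        "p12": ("car",),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Cohort shape: persons, their commute leg chains, and the seed."""

    n_persons: int = 12
    person_mode_assignment: Mapping[str, tuple[str, ...]] = field(
        default_factory=default_assignment
    )
    commutes_per_person: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.person_mode_assignment) != self.n_persons:
            raise ConfigError(
                f"assignment covers {len(self.person_mode_assignment)} persons, "
                f"n_persons={self.n_persons}"
            )
        modes = set()
        for chain in self.person_mode_assignment.values():
            if not chain:
                raise ConfigError("every person needs at least one commute leg")
            modes.update(chain)
        if not modes:
            raise ConfigError("assignment contains no modes")


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * math.exp(sigma * rng.standard_normal()))


def _bout_speeds(
    rng: np.random.Generator, target_mean: float, duration: int, profile: ModeProfile
) -> np.ndarray:
    """One bout's speed profile: ramp up, AR(1) cruise, ramp down.

    The cruise level is chosen so the bout's mean speed approximates
    ``target_mean`` after accounting for the ramps; when the bout is too
    short to reach any cruise at the mode's ramp rate, the profile
    degenerates to a triangle (its mean is then ramp-limited).
    """
    r = profile.ramp_rate
    n = int(duration)
    feasible = 4.0 * target_mean <= r * n
    if not feasible:
        up = n // 2
        down = n - up
        ramp_up = r * np.arange(1, up + 1)
        ramp_down = r * np.arange(down, 0, -1)
        return np.concatenate([ramp_up, ramp_down])
    v = (r * n / 2.0) * (1.0 - math.sqrt(1.0 - 4.0 * target_mean / (r * n)))
    t_up = max(1, math.ceil(v / r))
    t_down = t_up
    plateau_len = n - t_up - t_down
    if plateau_len < 0:  # numerical corner: fall back to triangle
        up = n // 2
        down = n - up
        return np.concatenate(
            [np.minimum(r * np.arange(1, up + 1), v), np.minimum(r * np.arange(down, 0, -1), v)]
        )
    ramp_up = np.minimum(r * np.arange(1, t_up + 1), v)
    ramp_down = ramp_up[::-1]
    phi = profile.ar_coefficient
    sd_x = profile.noise_sd / math.sqrt(1.0 - phi * phi)
    x = rng.standard_normal() * sd_x
    plateau = np.empty(plateau_len)
    innov = rng.standard_normal(plateau_len) * profile.noise_sd
    for i in range(plateau_len):
        x = phi * x + innov[i]
        plateau[i] = x
    plateau = np.clip(v + plateau, 0.1, None)
    profile_speeds = np.concatenate([ramp_up, plateau, ramp_down])
    # Condition the realised bout mean on the drawn target: the AR(1)
    # fluctuation shapes second-to-second dynamics but must not blur the
    # calibrated sequence-mean distribution.
    if plateau_len > 0:
        for _ in range(2):
            deficit = target_mean * n - profile_speeds.sum()
            lo, hi = t_up, t_up + plateau_len
            profile_speeds[lo:hi] = np.clip(
                profile_speeds[lo:hi] + deficit / plateau_len, 0.1, None
            )
    return profile_speeds


def _person_effects(
    seed: int, person_index: int, modes: list[str]
) -> dict[str, float]:
    """Raw standard-normal person effects, one draw per mode."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, person_index]))
    return {mode: float(rng.standard_normal()) for mode in modes}


def _person_factor_table(
    seed: int,
    persons: list[str],
    assignment: Mapping[str, tuple[str, ...]],
    profiles: Mapping[str, ModeProfile],
) -> dict[str, dict[str, float]]:
    """Per-person multiplicative speed effects, centred within mode.

    With only two or three persons per mode, uncentred random effects
    would shift a mode's cohort-level median speed by the luck of a
    couple of draws; centring the log effects across each mode's users
    keeps the calibration anchored while persons still differ.
    """
    modes = sorted(profiles)
    raw = {p: _person_effects(seed, pi, modes) for pi, p in enumerate(persons)}
    factors: dict[str, dict[str, float]] = {p: {} for p in persons}
    for mode in modes:
        users = [p for p in persons if mode in assignment.get(p, ())]
        if not users:
            continue
        zbar = sum(raw[p][mode] for p in users) / len(users)
        sigma = _lognormal_sigma(*profiles[mode].cruise_iqr)
        for p in users:
            factors[p][mode] = math.exp(
                profiles[mode].person_sigma_frac * sigma * (raw[p][mode] - zbar)
            )
    return factors


def _leg(
    rng: np.random.Generator, profile: ModeProfile, person_factor: float
) -> tuple[list[np.ndarray], list[int]]:
    """Bouts and stop lengths for one commute leg of one mode."""
    sigma = _lognormal_sigma(*profile.cruise_iqr)
    sigma_bout = sigma * math.sqrt(max(0.0, 1.0 - profile.person_sigma_frac**2))
    dur_sigma = _lognormal_sigma(*profile.bout_duration_iqr)
    s_dur_sigma = _lognormal_sigma(*profile.short_duration_iqr)
    s_spd_sigma = _lognormal_sigma(*profile.short_speed_iqr)

    mains: list[np.ndarray] = []
    for _ in range(profile.n_main_bouts):
        dur = max(2, round(_lognormal(rng, profile.bout_duration_median, dur_sigma)))
        target = profile.cruise_median * person_factor * math.exp(
            sigma_bout * rng.standard_normal()
        )
        mains.append(_bout_speeds(rng, target, dur, profile))

    lo, hi = profile.n_bouts_range
    n_short = int(rng.integers(lo, hi + 1))
    shorts: list[np.ndarray] = []
    for _ in range(n_short):
        dur = int(
            np.clip(round(_lognormal(rng, profile.short_duration_median, s_dur_sigma)), 2, 59)
        )
        target = float(
            np.clip(
                profile.short_speed_median
                * person_factor
                * math.exp(s_spd_sigma * rng.standard_normal()),
                0.3,
                160.0,
            )
        )
        shorts.append(_bout_speeds(rng, target, dur, profile))

    # a couple of fragments before the main bouts, the rest after
    k = len(shorts) // 2
    bouts = shorts[:k] + mains + shorts[k:]
    stops = [
        max(1, int(rng.poisson(profile.stop_duration_mean))) for _ in bouts
    ]
    return bouts, stops


def simulate_cohort(
    config: CohortConfig | None = None,
    profiles: Mapping[str, ModeProfile] | None = None,
) -> list[Trace]:
    """Generate the labelled synthetic cohort, one trace per commute.

    Each commute runs the person's leg chain out and reversed back,
    with zero-speed stops between bouts and legs.  All points carry the
    generating mode and indoor=False.
    """
    config = config or CohortConfig()
    profiles = dict(profiles or default_profiles())
    for chain in config.person_mode_assignment.values():
        for mode in chain:
            if mode not in profiles:
                raise ConfigError(f"no profile for mode {mode!r} in assignment")

    traces: list[Trace] = []
    persons = sorted(config.person_mode_assignment)
    factor_table = _person_factor_table(
        config.seed, persons, config.person_mode_assignment, profiles
    )
    for pi, person in enumerate(persons):
        chain = tuple(config.person_mode_assignment[person])
        factors = factor_table[person]
        for ci in range(config.commutes_per_person):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, pi, ci + 1])
            )
            legs = chain + tuple(reversed(chain))  # out and back
            speeds_parts: list[np.ndarray] = []
            modes_parts: list[np.ndarray] = []
            for li, mode in enumerate(legs):
                profile = profiles[mode]
                bouts, stops = _leg(rng, profile, factors[mode])
                for bout, stop in zip(bouts, stops):
                    speeds_parts.append(bout)
                    modes_parts.append(np.full(bout.size, mode, dtype=object))
                    speeds_parts.append(np.zeros(stop))
                    modes_parts.append(np.full(stop, mode, dtype=object))
                if li == len(chain) - 1:  # turn-around stop at the destination
                    pause = 60 + int(rng.poisson(30))
                    speeds_parts.append(np.zeros(pause))
                    modes_parts.append(np.full(pause, mode, dtype=object))
            speeds = np.concatenate(speeds_parts)
            modes = np.concatenate(modes_parts)
            traces.append(
                trace_from_arrays(person, f"c{ci + 1}", speeds, modes)
            )
    return traces


def calibration_report(
    traces: list[Trace], zero_threshold: float = 0.0
) -> pd.DataFrame:
    """Per-mode sequence counts and duration/speed medians with IQRs.

    Mirrors the reference cohort summary layout: one row per mode, with
    an all-sequences block and a >=60 s block ("speed per sequence" is
    the per-sequence mean speed).  Modes absent from the cohort simply
    do not appear.
    """
    sequences = segment_traces(traces, zero_threshold)
    if not sequences:
        raise DataError("no sequences to report on")
    rows = []
    modes = sorted({s.mode for s in sequences})
    for mode in modes:
        seqs = [s for s in sequences if s.mode == mode]
        durs = np.array([s.duration for s in seqs], dtype=float)
        spds = np.array([float(np.mean(s.speeds)) for s in seqs])
        long_mask = durs >= 60
        row = {
            "mode": mode,
            "n_sequences": len(seqs),
            "duration_median": float(np.median(durs)),
            "duration_q25": float(np.quantile(durs, 0.25)),
            "duration_q75": float(np.quantile(durs, 0.75)),
            "speed_median": float(np.median(spds)),
            "speed_q25": float(np.quantile(spds, 0.25)),
            "speed_q75": float(np.quantile(spds, 0.75)),
            "n_sequences_60s": int(long_mask.sum()),
        }
        if long_mask.any():
            row.update(
                duration_median_60s=float(np.median(durs[long_mask])),
                speed_median_60s=float(np.median(spds[long_mask])),
                speed_q25_60s=float(np.quantile(spds[long_mask], 0.25)),
                speed_q75_60s=float(np.quantile(spds[long_mask], 0.75)),
            )
        else:
            row.update(
                duration_median_60s=np.nan,
                speed_median_60s=np.nan,
                speed_q25_60s=np.nan,
                speed_q75_60s=np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("mode")


def profiles_to_dict(profiles: Mapping[str, ModeProfile]) -> dict:
    """Plain-dict form of a profile set (for YAML/JSON echoing)."""
    return {mode: asdict(p) for mode, p in sorted(profiles.items())}


def profiles_from_dict(doc: Mapping[str, Mapping]) -> dict[str, ModeProfile]:
    """Inverse of :func:`profiles_to_dict`, with tuple fields restored."""
    out = {}
    for mode, fields_ in doc.items():
        kw = dict(fields_)
        for key in (
            "cruise_iqr",
            "bout_duration_iqr",
            "n_bouts_range",
            "short_duration_iqr",
            "short_speed_iqr",
        ):
            if key in kw:
                kw[key] = tuple(kw[key])
        out[mode] = ModeProfile(**kw)
    return out
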