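"""Ground-truth simulator for reed-switch running-wheel data.

Generates dark-phase-dominant, bouted wheel running under a 12:12 light/dark
cycle, then renders it into raw switch-edge streams — optionally corrupted by
contact bounce and wheel faults — so the whole decoding/analysis pipeline can
be tested against a known truth without any animal data.

Model
-----
Each simulated day (a "session", 1440 min starting at the daily logger reset,
by default at lights-off) draws a Poisson number of running bouts.  Every bout
is independently assigned to the dark phase with probability
``dark_activity_fraction``, starts uniformly within its phase, and has an
exponentially distributed duration clipped at the phase boundary.  Bouts may
overlap; their per-minute rotation intensities add, and each minute's rotation
count is Poisson with that summed intensity.  Because both phases span 12 h,
clipping losses are symmetric and the expected share of rotations falling in
the dark phase equals ``dark_activity_fraction`` exactly.

Rotation times within a minute are evenly spaced.  This keeps every
inter-rotation gap far above the debounce lockout, so with bounce and faults
disabled the decoder recovers the simulated per-minute counts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, time, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, ParameterError
from .events import MS_PER_MIN, Edge, SwitchEvent

MIN_PER_DAY = 1440


@dataclass(frozen=True)
class BehaviorParams:
    """Generative parameters for one animal's running behavior.

    Defaults emulate an adult mouse acquiring wheel running: ~30 bouts/day of
    ~10 min at ~60 rotations/min (≈ 7 km/day on a 127 mm wheel), 90% of
    activity in the dark phase, and a mild day-on-day escalation.  The bout
    statistics are order-of-magnitude choices; see docs/methods.md.
    """

    n_days: int = 13
    lights_off: time = time(10, 20)
    photoperiod_h: float = 12.0          # hours of darkness per day
    dark_activity_fraction: float = 0.9  # expected share of rotations in the dark
    bout_rate_per_h: float = 2.5         # bout starts per dark hour (daily total scale)
    bout_duration_min: float = 10.0      # mean bout length (exponential)
    rot_per_min: float = 60.0            # mean within-bout rotation rate
    ramp: float = 1.02                   # per-day multiplier on rot_per_min
    session_start: time | None = None    # daily reset clock time; default = lights_off
    max_rot_per_min: int = 500           # physical cap; keeps rotation gaps > lockout

    def __post_init__(self):
        if not 0.0 <= self.dark_activity_fraction <= 1.0:
            raise ParameterError(
                f"dark_activity_fraction must be in [0, 1], got {self.dark_activity_fraction}"
            )
        for name in ("bout_rate_per_h", "bout_duration_min", "rot_per_min", "ramp"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_days < 1:
            raise ParameterError(f"n_days must be >= 1, got {self.n_days}")
        if not 0 < self.photoperiod_h < 24:
            raise ParameterError(f"photoperiod_h must be in (0, 24), got {self.photoperiod_h}")

    @property
    def start_clock(self) -> time:
        return self.session_start if self.session_start is not None else self.lights_off


@dataclass(frozen=True)
class BounceParams:
    """Contact-bounce model: spurious edge pairs right after a closure.

    The burst window defaults to 3 ms — an order of magnitude shorter than the
    30 ms lockout — so a correctly configured decoder suppresses it entirely.
    """

    p_bounce: float = 0.3
    burst_window_ms: float = 3.0
    max_burst_pairs: int = 3  # pairs per burst drawn uniformly from 1..max

    def __post_init__(self):
        if not 0.0 <= self.p_bounce <= 1.0:
            raise ParameterError(f"p_bounce must be in [0, 1], got {self.p_bounce}")
        if self.burst_window_ms <= 0:
            raise ParameterError("burst_window_ms must be > 0")


@dataclass(frozen=True)
class FaultSpec:
    """Wheel faults: offline windows (dead reed switch) and rotation drag.

    ``offline_intervals`` are (day, start_minute, end_minute) windows in which
    the switch emits nothing.  ``drag_factor`` < 1 thins emitted rotations
    (waste build-up slowing the wheel); ground truth is kept pre-fault.
    """

    offline_intervals: tuple[tuple[int, int, int], ...] = ()
    drag_factor: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.drag_factor <= 1.0:
            raise ParameterError(f"drag_factor must be in [0, 1], got {self.drag_factor}")
        for day, lo, hi in self.offline_intervals:
            if not (0 <= lo < hi <= MIN_PER_DAY):
                raise ParameterError(f"bad offline interval minutes ({lo}, {hi})")


@dataclass
class GroundTruth:
    """What the simulator actually generated, before bounce/faults.

    ``rotations[d]`` is the sorted array of rotation times (ms since that
    session's reset); ``minute_counts[d]`` the 1440-length per-minute counts;
    ``daily`` a table of per-session truth metrics computed with the same
    wheel geometry the analysis layer uses.
    """

    rotations: list[np.ndarray]
    minute_counts: list[np.ndarray]
    daily: pd.DataFrame
    dark_mask: np.ndarray  # per-minute bool, True = dark phase (same for all days)


def _phase_windows(params: BehaviorParams) -> tuple[np.ndarray, float]:
    """Per-minute dark mask over one session and the session->clock offset (min)."""
    start = params.start_clock
    start_min = start.hour * 60 + start.minute
    off_min = params.lights_off.hour * 60 + params.lights_off.minute
    offset = (off_min - start_min) % MIN_PER_DAY  # session minute at which dark begins
    dark_len = int(round(params.photoperiod_h * 60))
    idx = (np.arange(MIN_PER_DAY) - offset) % MIN_PER_DAY
    return idx < dark_len, float(offset)


def simulate_behavior(
    params: BehaviorParams,
    seed: int | np.random.Generator,
    circumference_m: float | None = None,
    active_threshold: int = 30,
) -> GroundTruth:
    """Draw one animal's rotation times for ``params.n_days`` sessions.

    All randomness flows from ``seed``; passing the same seed reproduces the
    run bit-for-bit.  Truth metrics (distance, active minutes, active speed)
    are computed from the true minute counts using ``circumference_m``
    (default π × 0.127 m) and a fixed active-minute threshold.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if circumference_m is None:
        circumference_m = float(np.pi * 0.127)

    dark_mask, offset = _phase_windows(params)
    dark_len = int(dark_mask.sum())
    light_len = MIN_PER_DAY - dark_len
    # Dark phase runs [offset, offset+dark_len) mod 1440 in session minutes.
    dark_start, dark_end = offset, offset + dark_len

    n_bouts_mean = params.bout_rate_per_h * params.photoperiod_h
    f = params.dark_activity_fraction

    rotations: list[np.ndarray] = []
    minute_counts: list[np.ndarray] = []
    rows = []
    for d in range(params.n_days):
        rate = params.rot_per_min * params.ramp**d
        intensity = np.zeros(MIN_PER_DAY)
        n_bouts = rng.poisson(n_bouts_mean) if n_bouts_mean > 0 else 0
        for _ in range(n_bouts):
            in_dark = rng.random() < f
            if in_dark:
                lo, hi = dark_start, dark_end
            else:
                # light phase is the complement; as a single contiguous block it
                # runs [dark_end, dark_end + light_len)
                lo, hi = dark_end, dark_end + light_len
            start = rng.uniform(lo, hi)
            dur = rng.exponential(params.bout_duration_min) if params.bout_duration_min > 0 else 0.0
            end = min(start + dur, hi)  # bouts terminate at the phase boundary
            _add_coverage(intensity, start % MIN_PER_DAY, end - start, rate)
        counts = rng.poisson(intensity)
        np.minimum(counts, params.max_rot_per_min, out=counts)
        times = _counts_to_times(counts)
        rotations.append(times)
        minute_counts.append(counts)
        active = counts > active_threshold
        n_active = int(active.sum())
        dist_km = counts.sum() * circumference_m / 1000.0
        speed = (
            counts[active].sum() * circumference_m / 1000.0 / (n_active / 60.0)
            if n_active
            else np.nan
        )
        rows.append(
            dict(
                day=d,
                rotations=int(counts.sum()),
                distance_km=dist_km,
                active_min=n_active,
                active_speed_kmh=speed,
                dark_rotations=int(counts[dark_mask].sum()),
            )
        )
    daily = pd.DataFrame(rows)
    return GroundTruth(rotations, minute_counts, daily, dark_mask)


def _add_coverage(intensity: np.ndarray, start_min: float, dur_min: float, rate: float) -> None:
    """Add ``rate`` × (fractional minute coverage) of a bout to the intensity array.

    Coverage extending past the session end wraps to the session start: phase
    windows are defined on the 24-h clock, so when the reset is offset from
    lights-off a phase straddles the session boundary and its tail belongs to
    the same clock phase at the top of the session.
    """
    if dur_min <= 0:
        return
    end_min = start_min + dur_min
    if end_min > MIN_PER_DAY:
        _add_coverage(intensity, start_min, MIN_PER_DAY - start_min, rate)
        _add_coverage(intensity, 0.0, end_min - MIN_PER_DAY, rate)
        return
    k0 = int(start_min)
    k1 = min(int(np.ceil(end_min)), MIN_PER_DAY)
    for k in range(k0, k1):
        lo = max(start_min, k)
        hi = min(end_min, k + 1)
        if hi > lo:
            intensity[k] += rate * (hi - lo)


def _counts_to_times(counts: np.ndarray) -> np.ndarray:
    """Evenly spaced rotation times per minute (ms since session start)."""
    parts = []
    for k in np.nonzero(counts)[0]:
        c = int(counts[k])
        parts.append(k * MS_PER_MIN + (np.arange(c) + 0.5) * (MS_PER_MIN / c))
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


def emit_switch_events(
    rotation_times_ms: np.ndarray | Sequence[float],
    bounce: BounceParams | None = None,
    fault: FaultSpec | None = None,
    seed: int | np.random.Generator = 0,
    channel: int = 0,
    day: int = 0,
    dwell_ms: float = 15.0,
) -> list[SwitchEvent]:
    """Render one session's rotation times as a raw switch-edge stream.

    Each surviving rotation emits CLOSED at its time and OPEN after a short
    dwell (kept below half the gap to the next rotation).  With ``bounce``,
    some closures are followed by a burst of spurious OPEN/CLOSED pairs inside
    ``burst_window_ms``.  Offline fault windows for ``day`` suppress all edges;
    ``drag_factor`` < 1 thins rotations before emission.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.asarray(rotation_times_ms, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ParameterError("rotation times must be sorted")

    if fault is not None and fault.drag_factor < 1.0:
        t = t[rng.random(t.size) < fault.drag_factor]

    offline: list[tuple[float, float]] = []
    if fault is not None:
        offline = [
            (lo * MS_PER_MIN, hi * MS_PER_MIN)
            for (fday, lo, hi) in fault.offline_intervals
            if fday == day
        ]

    def is_offline(x: float) -> bool:
        return any(lo <= x < hi for lo, hi in offline)

    events: list[SwitchEvent] = []
    n = t.size
    for i in range(n):
        ti = float(t[i])
        gap = float(t[i + 1] - ti) if i + 1 < n else np.inf
        dwell = min(dwell_ms, 0.45 * gap)
        burst_times: list[tuple[float, Edge]] = [(ti, Edge.CLOSED)]
        if bounce is not None and bounce.p_bounce > 0 and rng.random() < bounce.p_bounce:
            window = min(bounce.burst_window_ms, 0.8 * dwell)
            n_pairs = int(rng.integers(1, bounce.max_burst_pairs + 1))
            jitter = np.sort(rng.uniform(0, window, size=2 * n_pairs))
            for j in range(n_pairs):
                burst_times.append((ti + jitter[2 * j], Edge.OPEN))
                burst_times.append((ti + jitter[2 * j + 1], Edge.CLOSED))
            burst_times.sort(key=lambda p: p[0])
        burst_times.append((ti + dwell, Edge.OPEN))
        for tt, edge in burst_times:
            if not is_offline(tt):
                events.append(SwitchEvent(channel, tt, edge))
    return events


@dataclass(frozen=True)
class CohortGroup:
    """One experimental group: how many animals and their behavior parameters."""

    n: int
    sex: str
    genotype: str
    params: BehaviorParams


@dataclass
class SimulatedAnimal:
    mouse_id: str
    logger_id: int
    channel: int
    sex: str
    genotype: str
    truth: GroundTruth
    events: list[list[SwitchEvent]]  # one edge stream per session/day


@dataclass
class Cohort:
    animals: list[SimulatedAnimal]
    manifest: pd.DataFrame
    start_date: date
    params_by_group: dict[tuple[str, str], BehaviorParams]

    @property
    def truth_daily(self) -> pd.DataFrame:
        frames = []
        for a in self.animals:
            df = a.truth.daily.copy()
            df.insert(0, "mouse_id", a.mouse_id)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def make_cohort(
    groups: Sequence[CohortGroup],
    seed: int,
    n_loggers: int = 3,
    channels_per_logger: int = 13,
    bounce: BounceParams | None = None,
    fault: FaultSpec | None = None,
    start_date: date = date(2024, 3, 4),
    circumference_m: float | None = None,
) -> Cohort:
    """Simulate a multi-animal cohort across one or more loggers.

    Animals are assigned sequentially to logger channels; mouse ids follow the
    ``"<logger>_<channel>"`` convention.  Raises :class:`CapacityError` if the
    cohort exceeds ``n_loggers × channels_per_logger`` channels.
    """
    n_total = sum(g.n for g in groups)
    if n_total > n_loggers * channels_per_logger:
        raise CapacityError(
            f"{n_total} animals requested but only "
            f"{n_loggers * channels_per_logger} channels available"
        )
    rng = np.random.default_rng(seed)
    animals: list[SimulatedAnimal] = []
    rows = []
    idx = 0
    for g in groups:
        for _ in range(g.n):
            logger_id = 1 + idx // channels_per_logger
            channel = idx % channels_per_logger
            mouse_id = f"{logger_id}_{channel}"
            truth = simulate_behavior(g.params, rng, circumference_m=circumference_m)
            ev = [
                emit_switch_events(
                    truth.rotations[d], bounce=bounce, fault=fault,
                    seed=rng, channel=channel, day=d,
                )
                for d in range(g.params.n_days)
            ]
            animals.append(
                SimulatedAnimal(mouse_id, logger_id, channel, g.sex, g.genotype, truth, ev)
            )
            rows.append(dict(mouse_id=mouse_id, sex=g.sex, genotype=g.genotype, cohort=1))
            idx += 1
    manifest = pd.DataFrame(rows, columns=["mouse_id", "sex", "genotype", "cohort"])
    params_by_group = {(g.sex, g.genotype): g.params for g in groups}
    return Cohort(animals, manifest, start_date, params_by_group)


def write_cohort(
    cohort: Cohort,
    outdir,
    lockout_ms: float = 30.0,
    reset_jitter_s: float = 0.0,
    seed: int = 0,
    missing_reset_days: Sequence[int] = (),
) -> dict:
    """Decode a simulated cohort and write it out as a logger dataset.

    Produces, under ``outdir``: one minute-record CSV per logger per day,
    ``manifest.csv``, ``reset_log.csv`` (session start clock times, optionally
    jittered around the nominal reset and with chosen days left blank), and
    ``ground_truth.csv`` (per animal-day truth metrics).  Returns the paths.
    """
    from pathlib import Path

    from .events import LoggerConfig, decode_stream
    from . import logio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n_days = max(len(a.events) for a in cohort.animals)
    start_clock = next(iter(cohort.params_by_group.values())).start_clock

    reset_entries: list[tuple[date, time | None]] = []
    starts: list[pd.Timestamp] = []
    for d in range(n_days):
        day_label = cohort.start_date + timedelta(days=d)
        base = pd.Timestamp.combine(pd.Timestamp(day_label), start_clock)
        jitter = rng.uniform(-reset_jitter_s, reset_jitter_s) if reset_jitter_s else 0.0
        start = (base + pd.Timedelta(seconds=float(jitter))).floor("s")
        starts.append(start)
        recorded = None if d in missing_reset_days else start.time()
        reset_entries.append((start.date(), recorded))

    loggers = sorted({a.logger_id for a in cohort.animals})
    max_ch = max(a.channel for a in cohort.animals) + 1
    cfg = LoggerConfig(n_channels=max_ch, lockout_ms=lockout_ms)
    log_paths = []
    for d in range(n_days):
        day_label = reset_entries[d][0]
        # a session ends at the next reset; truncate so sessions never overlap
        n_min = MIN_PER_DAY
        if d + 1 < n_days:
            gap_min = int((starts[d + 1] - starts[d]).total_seconds() // 60)
            n_min = min(MIN_PER_DAY, gap_min)
        for lg in loggers:
            stream: list[SwitchEvent] = []
            for a in cohort.animals:
                if a.logger_id == lg and d < len(a.events):
                    stream.extend(a.events[d])
            stream.sort(key=lambda e: e.t_ms)
            decoded = decode_stream(stream, cfg, n_minutes=n_min)
            records = [r for ch in sorted(decoded) for r in decoded[ch]]
            path = outdir / logio.log_filename(lg, day_label)
            logio.write_log(records, path)
            log_paths.append(path)

    manifest_path = outdir / "manifest.csv"
    cohort.manifest.to_csv(manifest_path, index=False)
    reset_path = logio.write_reset_log(reset_entries, outdir / "reset_log.csv")
    truth_path = outdir / "ground_truth.csv"
    cohort.truth_daily.to_csv(truth_path, index=False)
    return dict(
        logs=log_paths, manifest=manifest_path, reset_log=reset_path, truth=truth_path
    )

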