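"""Reed-switch event decoding: edge streams -> debounced rotations -> minute records.

This is a software port of the wheel logger's acquisition logic.  A magnet on the
wheel closes a reed switch once per revolution; the logger watches each channel's
switch, and every open->closed transition that falls outside a short lockout
(debounce) window after the previously *detected* rotation is counted as one
rotation.  Once per minute the logger writes, per channel: how many open and
closed edges it saw, how long the switch dwelt in each state, and how many
rotations it inferred.

The lockout is non-retriggerable: ignored (bouncing) edges do not restart the
timer, so a burst of contact bounce shorter than the lockout can never mask a
genuine rotation that follows it.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, SortOrderError

MS_PER_MIN = 60_000


class Edge(enum.Enum):
    OPEN = "OPEN"
    CLOSED = "CLOSED"


@dataclass(frozen=True, slots=True)
class SwitchEvent:
    """One reed-switch edge on one channel, timed in ms since logger reset."""

    channel: int
    t_ms: float
    edge: Edge

    def __post_init__(self):
        if self.t_ms < 0:
            raise ValueError(f"event time must be >= 0, got {self.t_ms}")


@dataclass(frozen=True, slots=True)
class RotationEvent:
    """A debounced wheel rotation."""

    channel: int
    t_ms: float


@dataclass(frozen=True, slots=True)
class MinuteRecord:
    """The logger's one-minute summary row for one channel.

    Dwell durations are integer milliseconds and sum to exactly 60 000 for
    every complete minute (the CSV dialect rounds the open dwell and assigns
    the complement to the closed dwell).
    """

    channel: int
    minute_index: int
    open_events: int
    close_events: int
    open_dur_ms: int
    closed_dur_ms: int
    rotations: int


@dataclass(frozen=True)
class LoggerConfig:
    """Acquisition settings: channel count, debounce lockout, bin width."""

    n_channels: int = 13
    lockout_ms: float = 30.0
    bin_s: float = 60.0

    def __post_init__(self):
        if not 1 <= self.n_channels <= 13:
            raise ConfigError(f"n_channels must be in 1..13, got {self.n_channels}")
        if self.lockout_ms <= 0:
            raise ConfigError(f"lockout_ms must be > 0, got {self.lockout_ms}")
        if self.bin_s <= 0:
            raise ConfigError(f"bin_s must be > 0, got {self.bin_s}")

    @property
    def bin_ms(self) -> float:
        return self.bin_s * 1000.0


def _check_sorted(events: Sequence[SwitchEvent]) -> None:
    for prev, cur in zip(events, events[1:]):
        if cur.t_ms < prev.t_ms:
            raise SortOrderError(
                f"events out of order: t={cur.t_ms} ms follows t={prev.t_ms} ms"
            )


def detect_rotations(
    events: Sequence[SwitchEvent], lockout_ms: float = 30.0
) -> list[RotationEvent]:
    """Debounce a single channel's edge stream into rotations.

    A rotation is an OPEN->CLOSED transition at least ``lockout_ms`` after the
    previously detected rotation; the first CLOSED transition always detects.
    The switch state before the first edge is taken to be the opposite of that
    edge, so an initial CLOSED edge is a transition.  Duplicate same-state
    edges (glitches) are tolerated: only the first changes state.

    Raises
    ------
    SortOrderError
        If the stream is not sorted by ``t_ms``.
    """
    if lockout_ms <= 0:
        raise ConfigError(f"lockout_ms must be > 0, got {lockout_ms}")
    _check_sorted(events)
    rotations: list[RotationEvent] = []
    state: Edge | None = None
    last_detected = -math.inf
    for ev in events:
        if state is None:
            state = Edge.OPEN if ev.edge is Edge.CLOSED else Edge.CLOSED
        if ev.edge is Edge.CLOSED:
            if state is Edge.OPEN:
                state = Edge.CLOSED
                if ev.t_ms - last_detected >= lockout_ms:
                    rotations.append(RotationEvent(ev.channel, ev.t_ms))
                    last_detected = ev.t_ms
        else:
            if state is Edge.CLOSED:
                state = Edge.OPEN
    return rotations


def summarize_minutes(
    events: Sequence[SwitchEvent],
    rotations: Sequence[RotationEvent],
    config: LoggerConfig | None = None,
    n_minutes: int | None = None,
    channel: int | None = None,
) -> list[MinuteRecord]:
    """Bin one channel's edges and rotations into the logger's minute records.

    Minute ``k`` covers ``[k*60000, (k+1)*60000)`` ms (left-closed, right-open,
    anchored at logger reset).  Switch state is carried across bin boundaries
    and persists after the last edge, so every returned minute is complete and
    its dwell durations sum to exactly one minute.  With no edges at all the
    switch is assumed to rest OPEN.
    """
    config = config or LoggerConfig()
    bin_ms = config.bin_ms
    _check_sorted(events)
    if channel is None:
        channel = events[0].channel if events else (rotations[0].channel if rotations else 0)
    if n_minutes is None:
        t_last = max(
            [ev.t_ms for ev in events] + [r.t_ms for r in rotations], default=0.0
        )
        n_minutes = int(t_last // bin_ms) + 1

    open_events = np.zeros(n_minutes, dtype=np.int64)
    close_events = np.zeros(n_minutes, dtype=np.int64)
    rot_counts = np.zeros(n_minutes, dtype=np.int64)
    closed_dur = np.zeros(n_minutes, dtype=np.float64)

    for ev in events:
        k = int(ev.t_ms // bin_ms)
        if k >= n_minutes:
            continue
        if ev.edge is Edge.OPEN:
            open_events[k] += 1
        else:
            close_events[k] += 1
    for r in rotations:
        k = int(r.t_ms // bin_ms)
        if k < n_minutes:
            rot_counts[k] += 1

    # Reconstruct the state step-function and spread CLOSED dwell over bins.
    horizon = n_minutes * bin_ms
    state = Edge.OPEN
    if events:
        state = Edge.OPEN if events[0].edge is Edge.CLOSED else Edge.CLOSED
    seg_start = 0.0
    for ev in events:
        t = min(ev.t_ms, horizon)
        if ev.edge is not state:  # genuine transition; duplicate edges keep state
            if state is Edge.CLOSED:
                _accrue(closed_dur, seg_start, t, bin_ms)
            seg_start = t
            state = ev.edge
    if state is Edge.CLOSED:
        _accrue(closed_dur, seg_start, horizon, bin_ms)

    records = []
    for k in range(n_minutes):
        closed_ms = int(round(closed_dur[k]))
        closed_ms = min(max(closed_ms, 0), int(bin_ms))
        records.append(
            MinuteRecord(
                channel=channel,
                minute_index=k,
                open_events=int(open_events[k]),
                close_events=int(close_events[k]),
                open_dur_ms=int(bin_ms) - closed_ms,
                closed_dur_ms=closed_ms,
                rotations=int(rot_counts[k]),
            )
        )
    return records


def _accrue(acc: np.ndarray, t0: float, t1: float, bin_ms: float) -> None:
    """Add the overlap of [t0, t1) with each minute bin to ``acc``."""
    if t1 <= t0:
        return
    k0 = int(t0 // bin_ms)
    k1 = int((t1 - 1e-9) // bin_ms)
    k1 = min(k1, len(acc) - 1)
    for k in range(k0, k1 + 1):
        lo = max(t0, k * bin_ms)
        hi = min(t1, (k + 1) * bin_ms)
        if hi > lo:
            acc[k] += hi - lo


def decode_stream(
    events: Iterable[SwitchEvent],
    config: LoggerConfig | None = None,
    n_minutes: int | None = None,
) -> dict[int, list[MinuteRecord]]:
    """Demultiplex a multi-channel stream and decode every channel.

    Returns one minute-record list per configured channel (0..n_channels-1);
    channels with no events yield all-zero, all-OPEN records.  Equivalent to
    running :func:`detect_rotations` + :func:`summarize_minutes` per channel.

    Raises
    ------
    ConfigError
        If an event's channel id is >= ``config.n_channels``.
    """
    config = config or LoggerConfig()
    per_channel: dict[int, list[SwitchEvent]] = {c: [] for c in range(config.n_channels)}
    t_max = 0.0
    for ev in events:
        if ev.channel >= config.n_channels or ev.channel < 0:
            raise ConfigError(
                f"channel {ev.channel} outside configured range 0..{config.n_channels - 1}"
            )
        per_channel[ev.channel].append(ev)
        t_max = max(t_max, ev.t_ms)
    if n_minutes is None:
        n_minutes = int(t_max // config.bin_ms) + 1
    out: dict[int, list[MinuteRecord]] = {}
    for ch in range(config.n_channels):
        evs = per_channel[ch]
        rots = detect_rotations(evs, config.lockout_ms)
        out[ch] = summarize_minutes(evs, rots, config, n_minutes=n_minutes, channel=ch)
    return out


def max_recordable_speed(circumference_m: float, lockout_ms: float) -> float:
    """Fastest wheel speed (km/h) the debounce lockout can still resolve.

    One rotation per lockout interval: ``circumference_m / (lockout_ms/1000) * 3.6``.
    """
    if circumference_m <= 0 or lockout_ms <= 0:
        raise ConfigError("circumference_m and lockout_ms must both be > 0")
    return circumference_m / (lockout_ms / 1000.0) * 3.6
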