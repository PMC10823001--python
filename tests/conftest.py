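"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from wheelrun.events import Edge, SwitchEvent
from wheelrun import simulate as sim


def closed_stream(times, channel=0, dwell_frac=0.5):
    """Build an alternating edge stream with OPEN->CLOSED transitions at ``times``.

    An OPEN edge is inserted midway between consecutive closures so each CLOSED
    edge is a genuine transition.
    """
    times = list(times)
    events = []
    for i, t in enumerate(times):
        events.append(SwitchEvent(channel, t, Edge.CLOSED))
        if i + 1 < len(times):
            gap = times[i + 1] - t
            events.append(SwitchEvent(channel, t + dwell_frac * gap, Edge.OPEN))
    return events


def naive_transitions(events):
    """Oracle: OPEN->CLOSED transition times via an explicit state machine."""
    state = None
    out = []
    for ev in events:
        if state is None:
            state = Edge.OPEN if ev.edge is Edge.CLOSED else Edge.CLOSED
        if ev.edge is Edge.CLOSED and state is Edge.OPEN:
            out.append(ev.t_ms)
            state = Edge.CLOSED
        elif ev.edge is Edge.OPEN and state is Edge.CLOSED:
            state = Edge.OPEN
    return out


def naive_lockout(transition_times, lockout_ms):
    """Oracle: O(n^2) replay of the non-retriggerable lockout rule.

    A transition is detected iff no *detected* rotation lies within
    ``lockout_ms`` before it; the first always detects.
    """
    detected = []
    for t in transition_times:
        if all(not (0 <= t - d < lockout_ms) for d in detected):
            detected.append(t)
    return detected


def random_stream(rng, n_events=80, channel=0, t_scale=50.0, p_glitch=0.2):
    """Random edge stream: mostly alternating, with occasional duplicate edges."""
    t = 0.0
    state = Edge.OPEN
    events = []
    for _ in range(n_events):
        t += rng.exponential(t_scale)
        if rng.random() < p_glitch:
            edge = state  # duplicate (glitch) edge
        else:
            edge = Edge.CLOSED if state is Edge.OPEN else Edge.OPEN
            state = edge
        events.append(SwitchEvent(channel, t, edge))
    return events


@pytest.fixture(scope="session")
def small_cohort():
    """Two groups x two animals, 3 days, clean signal (no bounce/faults)."""
    params = sim.BehaviorParams(n_days=3)
    groups = [
        sim.CohortGroup(2, "F", "lineA", params),
        sim.CohortGroup(2, "M", "lineB", params),
    ]
    return sim.make_cohort(groups, seed=11)


@pytest.fixture(scope="session")
def stitched_cohort(small_cohort, tmp_path_factory):
    """The small cohort written to disk, read back, and stitched."""
    import pandas as pd
    from wheelrun import logio

    outdir = tmp_path_factory.mktemp("cohortdata")
    paths = sim.write_cohort(small_cohort, outdir, seed=5)
    logs = logio.read_log_dir(outdir)
    timemap = logio.build_timemap(logio.read_reset_log(paths["reset_log"]))
    manifest = pd.read_csv(paths["manifest"])
    series = logio.stitch_sessions(logs, timemap, manifest)
    return small_cohort, series, manifest
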