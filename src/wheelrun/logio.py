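"""Logger CSV dialect, reset-time reconstruction, and session stitching.

The logger writes one CSV per logger per day with one row per (minute, channel):

    minute,channel,open_events,close_events,open_dur_ms,closed_dur_ms,rotations

Minute indices count from the daily logger reset.  Because the loggers in the
reference protocol had no working real-time clock, absolute time is
reconstructed from a manually kept reset log (date -> clock time of reset).
Days whose reset time went unrecorded are imputed as the previous session's
start plus the mean inter-reset interval over all recorded consecutive pairs
(or a user-supplied constant), and flagged as such.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    ConsistencyError,
    InsufficientDataError,
    LogDialectError,
    LogParseError,
)
from .events import MinuteRecord

LOG_COLUMNS = (
    "minute",
    "channel",
    "open_events",
    "close_events",
    "open_dur_ms",
    "closed_dur_ms",
    "rotations",
)

_LOG_NAME_RE = re.compile(r"logger(\d+)_(\d{4}-\d{2}-\d{2})\.csv$")


@dataclass
class LogFile:
    """One logger-day of minute records (all channels)."""

    logger_id: int | None
    day_label: date | None
    records: list[MinuteRecord]

    @property
    def n_minutes(self) -> int:
        return max((r.minute_index for r in self.records), default=-1) + 1

    @property
    def channels(self) -> list[int]:
        return sorted({r.channel for r in self.records})


def log_filename(logger_id: int, day_label: date) -> str:
    return f"logger{logger_id}_{day_label.isoformat()}.csv"


def write_log(records: Iterable[MinuteRecord], path: str | Path) -> Path:
    """Write minute records in the reference dialect (UNIX newlines, no quoting)."""
    path = Path(path)
    rows = sorted(records, key=lambda r: (r.minute_index, r.channel))
    with open(path, "w", newline="\n") as fh:
        fh.write(",".join(LOG_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.minute_index},{r.channel},{r.open_events},{r.close_events},"
                f"{r.open_dur_ms},{r.closed_dur_ms},{r.rotations}\n"
            )
    return path


def read_log(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> LogFile:
    """Parse one logger CSV; the inverse of :func:`write_log`.

    ``column_map`` maps legacy header names onto the reference columns for
    files written by other tooling.  Logger id and day label are taken from a
    filename of the form ``logger<ID>_<YYYY-MM-DD>.csv`` when it matches.

    Raises
    ------
    LogDialectError
        On an unknown or missing column.
    LogParseError
        On a malformed row, naming its 1-based line number.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise LogDialectError(f"{path}: empty file, no header")
        header = [column_map.get(h, h) if column_map else h for h in header]
        unknown = [h for h in header if h not in LOG_COLUMNS]
        if unknown:
            raise LogDialectError(f"{path}: unknown column(s) {unknown}")
        missing = [c for c in LOG_COLUMNS if c not in header]
        if missing:
            raise LogDialectError(f"{path}: missing column(s) {missing}")
        col = {name: header.index(name) for name in LOG_COLUMNS}
        records = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise LogParseError(
                    f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}",
                    line=lineno,
                )
            try:
                records.append(
                    MinuteRecord(
                        minute_index=int(row[col["minute"]]),
                        channel=int(row[col["channel"]]),
                        open_events=int(row[col["open_events"]]),
                        close_events=int(row[col["close_events"]]),
                        open_dur_ms=int(row[col["open_dur_ms"]]),
                        closed_dur_ms=int(row[col["closed_dur_ms"]]),
                        rotations=int(row[col["rotations"]]),
                    )
                )
            except ValueError as exc:
                raise LogParseError(
                    f"{path}: line {lineno}: {exc}", line=lineno
                ) from exc
    m = _LOG_NAME_RE.search(path.name)
    logger_id = int(m.group(1)) if m else None
    day_label = date.fromisoformat(m.group(2)) if m else None
    return LogFile(logger_id=logger_id, day_label=day_label, records=records)


def read_log_dir(directory: str | Path) -> list[LogFile]:
    """Read every ``logger*_*.csv`` in a directory, sorted by (logger, day)."""
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if _LOG_NAME_RE.search(p.name))
    logs = [read_log(p) for p in files]
    logs.sort(key=lambda lf: (lf.logger_id, lf.day_label))
    return logs


# --------------------------------------------------------------------------
# Reset log -> absolute time
# --------------------------------------------------------------------------

MISSING = None  # sentinel for an unrecorded reset time

Provenance = str  # "RECORDED" | "IMPUTED"


@dataclass(frozen=True)
class TimeMapEntry:
    start: datetime
    provenance: Provenance  # RECORDED or IMPUTED


def read_reset_log(path: str | Path) -> list[tuple[date, time | None]]:
    """Read a two-column reset log CSV: date,time (time may be empty = missing)."""
    entries: list[tuple[date, time | None]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if [h.strip().lower() for h in header[:2]] != ["date", "time"]:
            raise LogDialectError(f"{path}: expected header 'date,time'")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                d = date.fromisoformat(row[0].strip())
            except ValueError as exc:
                raise LogParseError(f"{path}: line {lineno}: {exc}", line=lineno) from exc
            tstr = row[1].strip() if len(row) > 1 else ""
            t = time.fromisoformat(tstr) if tstr else MISSING
            entries.append((d, t))
    return entries


def write_reset_log(entries: Sequence[tuple[date, time | None]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write("date,time\n")
        for d, t in entries:
            fh.write(f"{d.isoformat()},{t.isoformat() if t is not None else ''}\n")
    return path


def build_timemap(
    reset_log: Sequence[tuple[date, time | None]],
    fallback_interval_s: float | str = "auto",
) -> dict[date, TimeMapEntry]:
    """Reconstruct absolute session starts from a (possibly gappy) reset log.

    Recorded entries use their own clock time.  A missing entry is imputed as
    the previous session's start plus the mean inter-reset interval — the
    arithmetic mean, per day of separation, over all consecutive recorded
    pairs (``fallback_interval_s="auto"``) or a supplied constant in seconds —
    and flagged ``IMPUTED``.

    Raises
    ------
    InsufficientDataError
        With AUTO and fewer than two recorded entries (no interval to average),
        or when the first entry is missing (nothing to impute forward from).
    ConsistencyError
        If day labels are not strictly increasing or starts go non-monotonic.
    """
    if not reset_log:
        raise InsufficientDataError("empty reset log")
    days = [d for d, _ in reset_log]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ConsistencyError("reset-log day labels must be strictly increasing")

    recorded = [(d, t) for d, t in reset_log if t is not None]
    has_missing = len(recorded) < len(reset_log)
    if isinstance(fallback_interval_s, str):
        if fallback_interval_s.lower() != "auto":
            raise ValueError(f"fallback_interval_s must be a number or 'auto'")
        if has_missing:
            if len(recorded) < 2:
                raise InsufficientDataError(
                    "AUTO imputation needs at least two recorded reset times"
                )
            gaps = []
            for (d0, t0), (d1, t1) in zip(reset_log, reset_log[1:]):
                if t0 is None or t1 is None:
                    continue
                delta = datetime.combine(d1, t1) - datetime.combine(d0, t0)
                span = (d1 - d0).days
                gaps.append(delta.total_seconds() / span)
            if not gaps:
                raise InsufficientDataError(
                    "AUTO imputation needs at least one consecutive recorded pair"
                )
            interval_s = sum(gaps) / len(gaps)
        else:
            interval_s = 86_400.0  # unused; no missing entries
    else:
        interval_s = float(fallback_interval_s)

    if reset_log[0][1] is None:
        raise InsufficientDataError("first reset entry is missing; cannot anchor the map")

    out: dict[date, TimeMapEntry] = {}
    prev_day, prev_start = None, None
    for d, t in reset_log:
        if t is not None:
            start = datetime.combine(d, t)
            prov = "RECORDED"
        else:
            span = (d - prev_day).days
            start = prev_start + timedelta(seconds=interval_s * span)
            prov = "IMPUTED"
        if prev_start is not None and start <= prev_start:
            raise ConsistencyError(
                f"session starts not strictly increasing at {d.isoformat()}"
            )
        out[d] = TimeMapEntry(start=start, provenance=prov)
        prev_day, prev_start = d, start
    return out


# --------------------------------------------------------------------------
# Stitching sessions into per-animal series
# --------------------------------------------------------------------------

SERIES_COLUMNS = [
    "timestamp",
    "session",
    "minute",
    "open_events",
    "close_events",
    "open_dur_ms",
    "closed_dur_ms",
    "rotations",
]


def stitch_sessions(
    log_files: Sequence[LogFile],
    timemap: Mapping[date, TimeMapEntry] | Mapping[tuple[int, date], TimeMapEntry],
    manifest: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Join logger-days into absolute-time per-animal minute series.

    Each record's timestamp is its session start plus ``minute`` minutes —
    sessions are never resampled onto a fixed grid, so late resets simply
    shift that day's timestamps.  Series are keyed by mouse id
    ``"<logger>_<channel>"``; manifest animals with no data yield empty
    frames with a warning, and channels absent from the manifest are dropped
    with a warning.  Overlapping sessions on one logger are rejected.
    """
    known = set(manifest["mouse_id"].astype(str))
    series_rows: dict[str, list[pd.DataFrame]] = {m: [] for m in known}
    warned_channels: set[str] = set()

    # overlap check per logger
    per_logger: dict[int, list[tuple[datetime, datetime, date]]] = {}
    for lf in log_files:
        if lf.logger_id is None or lf.day_label is None:
            raise ConsistencyError("log file lacks logger id / day label; cannot stitch")
        entry = _timemap_lookup(timemap, lf.logger_id, lf.day_label)
        start = entry.start
        end = start + timedelta(minutes=lf.n_minutes)
        per_logger.setdefault(lf.logger_id, []).append((start, end, lf.day_label))

        df = pd.DataFrame(
            [
                (
                    r.minute_index,
                    r.channel,
                    r.open_events,
                    r.close_events,
                    r.open_dur_ms,
                    r.closed_dur_ms,
                    r.rotations,
                )
                for r in lf.records
            ],
            columns=[
                "minute",
                "channel",
                "open_events",
                "close_events",
                "open_dur_ms",
                "closed_dur_ms",
                "rotations",
            ],
        )
        df["timestamp"] = pd.Timestamp(start) + pd.to_timedelta(df["minute"], unit="min")
        df["session"] = lf.day_label
        for ch, sub in df.groupby("channel"):
            mouse_id = f"{lf.logger_id}_{ch}"
            if mouse_id not in known:
                if mouse_id not in warned_channels:
                    warnings.warn(
                        f"channel {ch} on logger {lf.logger_id} has no manifest entry; dropped",
                        stacklevel=2,
                    )
                    warned_channels.add(mouse_id)
                continue
            series_rows[mouse_id].append(sub[SERIES_COLUMNS])

    for sessions in per_logger.values():
        sessions.sort()
        for (s0, e0, d0), (s1, e1, d1) in zip(sessions, sessions[1:]):
            if s1 < e0:
                raise ConsistencyError(
                    f"sessions {d0.isoformat()} and {d1.isoformat()} overlap "
                    f"({e0.isoformat()} > {s1.isoformat()})"
                )

    out: dict[str, pd.DataFrame] = {}
    for mouse_id in sorted(known, key=_mouse_sort_key):
        frames = series_rows[mouse_id]
        if frames:
            df = pd.concat(frames, ignore_index=True).sort_values("timestamp")
            out[mouse_id] = df.reset_index(drop=True)
        else:
            warnings.warn(f"manifest animal {mouse_id} has no logged data", stacklevel=2)
            out[mouse_id] = pd.DataFrame(columns=SERIES_COLUMNS)
    return out


def _timemap_lookup(timemap, logger_id: int, day: date) -> TimeMapEntry:
    if (logger_id, day) in timemap:
        return timemap[(logger_id, day)]
    if day in timemap:
        return timemap[day]
    raise ConsistencyError(
        f"no timemap entry for logger {logger_id}, day {day.isoformat()}"
    )


def _mouse_sort_key(mouse_id: str) -> tuple:
    parts = mouse_id.split("_")
    try:
        return tuple(int(p) for p in parts)
    except ValueError:
        return (float("inf"), mouse_id)


def write_series(series: Mapping[str, pd.DataFrame], path: str | Path) -> Path:
    """Write stitched series as one long CSV with a mouse_id column."""
    frames = []
    for mouse_id, df in series.items():
        if df.empty:
            continue
        d = df.copy()
        d.insert(0, "mouse_id", mouse_id)
        frames.append(d)
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["mouse_id"] + SERIES_COLUMNS)
    )
    out.to_csv(path, index=False)
    return Path(path)


def read_series(path: str | Path) -> dict[str, pd.DataFrame]:
    """Inverse of :func:`write_series`."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    df["session"] = pd.to_datetime(df["session"]).dt.date
    return {
        str(mouse_id): sub.drop(columns="mouse_id").reset_index(drop=True)
        for mouse_id, sub in df.groupby("mouse_id", sort=False)
    }
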