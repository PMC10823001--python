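"""Wheel-running metrics: distance, duration, speed, exclusions, summaries.

Definitions
-----------
distance (km/day)
    Σ rotations × wheel circumference over *all* minutes of a session.
active minute
    A 1-min bin whose rotation count exceeds a threshold — a fixed count
    (default 30, strict ``>``) or, in "quartile" mode, the lower quartile of
    nonzero per-minute counts pooled across the cohort.
active speed (km/h)
    Total distance accumulated in active minutes divided by active time.
    Speed over *all* minutes would be dragged toward zero by rest, so only
    minutes of genuine running enter the ratio.

Exclusion rules annotate, never delete: a day with fewer than
``min_active_min_per_day`` active minutes (broken/offline wheels rarely clear
it) or an implausible active speed (absolute cap, or a robust per-animal
median + k·MAD rule) is flagged and skipped by the statistical summaries, but
remains in the table for audit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import time
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError

MIN_PER_DAY = 1440


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis settings: wheel geometry, thresholds, exclusion rules, binning."""

    wheel_diameter_m: float = 0.127
    circumference_m: float | None = None  # default π × diameter
    active_threshold: int | str = 30      # fixed count, or "quartile"
    strict_inequality: bool = True        # active iff rotations > threshold
    min_active_min_per_day: int = 20
    speed_cap_kmh: float = 20.0
    mad_k: float = 5.0
    quantile_method: str = "nearest_rank"
    quartile_exclude_zeros: bool = True
    hourly_bin_min: int = 60
    actogram_bin_min: int = 10
    lights_off: time = time(10, 20)
    photoperiod_h: float = 12.0

    def __post_init__(self):
        if self.wheel_diameter_m <= 0:
            raise ConfigError("wheel_diameter_m must be > 0")
        if self.circumference_m is not None and self.circumference_m <= 0:
            raise ConfigError("circumference_m must be > 0")
        if isinstance(self.active_threshold, str) and self.active_threshold != "quartile":
            raise ConfigError("active_threshold must be an integer or 'quartile'")

    @property
    def circ_m(self) -> float:
        return (
            self.circumference_m
            if self.circumference_m is not None
            else math.pi * self.wheel_diameter_m
        )


@dataclass(frozen=True)
class DailySummary:
    """Distance / duration / speed and exclusion state for one animal-day."""

    mouse_id: str
    day: object  # session label (date)
    distance_km: float
    active_min: int
    active_speed_kmh: float  # NaN when active_min == 0
    rotations: int
    excluded: bool = False
    exclusion_reason: str = "NONE"  # NONE | TOO_FEW_ACTIVE_MIN | SPEED_OUTLIER | OFFLINE


def derive_active_threshold(
    minute_counts: Iterable[int],
    exclude_zeros: bool = True,
    method: str = "nearest_rank",
) -> int:
    """Lower quartile of per-minute rotation counts, as an integer threshold.

    The pool should span the whole cohort.  Zero-rotation minutes dominate
    real recordings (most of the day is rest), so with ``exclude_zeros`` the
    quartile is taken over active minutes only — a zero-inclusive Q1 would
    collapse to 0.  ``method`` is ``"nearest_rank"`` (default) or
    ``"linear"`` (numpy interpolation), rounded to the nearest integer.
    """
    counts = np.asarray(list(minute_counts))
    if exclude_zeros:
        counts = counts[counts > 0]
    if counts.size == 0:
        raise DegenerateInputError("no nonzero minute counts to derive a threshold from")
    if method == "nearest_rank":
        srt = np.sort(counts)
        rank = max(1, math.ceil(0.25 * srt.size))  # 1-based nearest rank
        q1 = srt[rank - 1]
    elif method == "linear":
        q1 = np.quantile(counts, 0.25)
    else:
        raise ConfigError(f"unknown quantile method {method!r}")
    return int(round(float(q1)))


def classify_active(rotations: int, threshold: int, strict: bool = True) -> bool:
    """Is this minute an active minute?"""
    if threshold < 0:
        raise ConfigError("threshold must be >= 0")
    return rotations > threshold if strict else rotations >= threshold


def resolve_threshold(
    config: AnalysisConfig, pooled_minute_counts: Iterable[int] | None = None
) -> int:
    """Fixed threshold from config, or derive it from the pooled cohort counts."""
    if config.active_threshold == "quartile":
        if pooled_minute_counts is None:
            raise ConfigError("quartile threshold requires pooled minute counts")
        return derive_active_threshold(
            pooled_minute_counts,
            exclude_zeros=config.quartile_exclude_zeros,
            method=config.quantile_method,
        )
    return int(config.active_threshold)


def daily_summary(
    session_df: pd.DataFrame,
    config: AnalysisConfig,
    threshold: int,
    mouse_id: str = "",
    day=None,
) -> DailySummary:
    """Distance, active minutes, and active-only speed for one session."""
    rot = session_df["rotations"].to_numpy()
    circ = config.circ_m
    distance_km = float(rot.sum()) * circ / 1000.0
    active = np.array(
        [classify_active(int(r), threshold, config.strict_inequality) for r in rot]
    )
    n_active = int(active.sum())
    if n_active:
        active_dist_km = float(rot[active].sum()) * circ / 1000.0
        speed = active_dist_km / (n_active / 60.0)
    else:
        speed = float("nan")
    if day is None and "session" in session_df and len(session_df):
        day = session_df["session"].iloc[0]
    return DailySummary(
        mouse_id=mouse_id,
        day=day,
        distance_km=distance_km,
        active_min=n_active,
        active_speed_kmh=speed,
        rotations=int(rot.sum()),
    )


def summarize_days(
    series: Mapping[str, pd.DataFrame],
    config: AnalysisConfig | None = None,
    threshold: int | None = None,
) -> pd.DataFrame:
    """Per animal-day summary table for a whole cohort.

    With ``config.active_threshold == "quartile"`` and no explicit
    ``threshold``, the threshold is derived from minute counts pooled over the
    entire cohort first (the chronic-study rule).
    """
    config = config or AnalysisConfig()
    if threshold is None:
        pooled = None
        if config.active_threshold == "quartile":
            pooled = np.concatenate(
                [df["rotations"].to_numpy() for df in series.values() if len(df)]
            )
        threshold = resolve_threshold(config, pooled)
    rows = []
    for mouse_id, df in series.items():
        if df.empty:
            continue
        for day, sub in df.groupby("session", sort=True):
            s = daily_summary(sub, config, threshold, mouse_id=mouse_id, day=day)
            rows.append(s.__dict__)
    out = pd.DataFrame(
        rows,
        columns=[
            "mouse_id",
            "day",
            "distance_km",
            "active_min",
            "active_speed_kmh",
            "rotations",
            "excluded",
            "exclusion_reason",
        ],
    )
    return out


def apply_exclusions(summaries: pd.DataFrame, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Flag animal-days failing the inclusion rules; rows are kept, not dropped.

    Rules, in precedence order per day:
      OFFLINE             zero rotations the whole day (dead wheel)
      TOO_FEW_ACTIVE_MIN  fewer than ``min_active_min_per_day`` active minutes
      SPEED_OUTLIER       active speed above the absolute cap, or above
                          median + k·MAD of the animal's *other* days
    """
    config = config or AnalysisConfig()
    df = summaries.copy()
    reasons = []
    for idx, row in df.iterrows():
        if row["rotations"] == 0:
            reasons.append("OFFLINE")
            continue
        if row["active_min"] < config.min_active_min_per_day:
            reasons.append("TOO_FEW_ACTIVE_MIN")
            continue
        speed = row["active_speed_kmh"]
        if np.isfinite(speed):
            if speed > config.speed_cap_kmh:
                reasons.append("SPEED_OUTLIER")
                continue
            others = df[
                (df["mouse_id"] == row["mouse_id"]) & (df.index != idx)
            ]["active_speed_kmh"].dropna()
            if len(others) >= 3:
                med = float(np.median(others))
                mad = float(np.median(np.abs(others - med)))
                if mad > 0 and speed > med + config.mad_k * mad:
                    reasons.append("SPEED_OUTLIER")
                    continue
        reasons.append("NONE")
    df["exclusion_reason"] = reasons
    df["excluded"] = df["exclusion_reason"] != "NONE"
    return df


def weekly_group_summary(
    summaries: pd.DataFrame,
    manifest: pd.DataFrame,
    metrics: Sequence[str] = ("distance_km", "active_min", "active_speed_kmh"),
    week_length: int = 7,
) -> pd.DataFrame:
    """Group mean ± SEM per (sex × genotype × week), animal as the unit.

    Weeks are consecutive ``week_length``-session blocks in each animal's own
    session order (a trailing short week is kept).  Excluded days never enter
    an animal's weekly mean; the SEM is the sample SD over animal means
    divided by √n, reported as NaN at n = 1.  Empty group-weeks are omitted
    with a warning.
    """
    df = summaries.merge(manifest[["mouse_id", "sex", "genotype"]], on="mouse_id")
    df = df.sort_values(["mouse_id", "day"])
    df["week"] = df.groupby("mouse_id").cumcount() // week_length + 1
    usable = df[~df["excluded"]]

    rows = []
    all_weeks = sorted(df["week"].unique())
    groups = df[["sex", "genotype"]].drop_duplicates().itertuples(index=False)
    for sex, genotype in groups:
        for week in all_weeks:
            block = usable[
                (usable["sex"] == sex)
                & (usable["genotype"] == genotype)
                & (usable["week"] == week)
            ]
            if block.empty:
                warnings.warn(
                    f"no usable data for {sex}/{genotype} week {week}; omitted",
                    stacklevel=2,
                )
                continue
            per_animal = block.groupby("mouse_id")[list(metrics)].mean()
            for metric in metrics:
                vals = per_animal[metric].dropna()
                n = len(vals)
                mean = float(vals.mean()) if n else float("nan")
                sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
                rows.append(
                    dict(sex=sex, genotype=genotype, week=week, metric=metric,
                         mean=mean, sem=sem, n=n)
                )
    return pd.DataFrame(rows, columns=["sex", "genotype", "week", "metric", "mean", "sem", "n"])


# --------------------------------------------------------------------------
# Time-of-day profiles
# --------------------------------------------------------------------------


def _zt_minutes(timestamps: pd.Series, lights_off: time, photoperiod_h: float) -> np.ndarray:
    """Zeitgeber minute-of-cycle for each timestamp (ZT0 = lights on)."""
    lights_on_min = (
        lights_off.hour * 60 + lights_off.minute + int(round(photoperiod_h * 60))
    ) % MIN_PER_DAY
    mod = timestamps.dt.hour * 60 + timestamps.dt.minute
    return ((mod - lights_on_min) % MIN_PER_DAY).to_numpy()


def hourly_profile(
    series: Mapping[str, pd.DataFrame],
    config: AnalysisConfig | None = None,
    week: int | None = None,
    week_length: int = 7,
    anchor: str = "clock",
) -> pd.DataFrame:
    """Mean running distance per hour of day (km/h) per animal, plus group stats.

    With ``anchor="clock"`` (default) bins are the 24 clock hours, labelled by
    their zeitgeber offset — shifting ``lights_off`` relabels but does not
    rebin.  With ``anchor="zt"`` bins start at lights-on, so bins 12..23 are
    exactly the dark phase.  ``week`` restricts to that 7-session block of
    each animal's sessions.

    Returns a long frame: mouse_id, hour_bin, zt_hour, km_per_h.
    """
    config = config or AnalysisConfig()
    if anchor not in ("clock", "zt"):
        raise ConfigError("anchor must be 'clock' or 'zt'")
    circ = config.circ_m
    rows = []
    for mouse_id, df in series.items():
        if df.empty:
            continue
        d = df
        if week is not None:
            sessions = sorted(d["session"].unique())
            keep = sessions[(week - 1) * week_length : week * week_length]
            d = d[d["session"].isin(keep)]
            if d.empty:
                continue
        n_days = d["session"].nunique()
        ts = pd.to_datetime(d["timestamp"])
        if anchor == "clock":
            hour_bin = ts.dt.hour.to_numpy()
        else:
            hour_bin = _zt_minutes(ts, config.lights_off, config.photoperiod_h) // 60
        dist = d["rotations"].to_numpy() * circ / 1000.0
        km = np.bincount(hour_bin, weights=dist, minlength=24)[:24]
        lights_on_min = (
            config.lights_off.hour * 60
            + config.lights_off.minute
            + int(round(config.photoperiod_h * 60))
        ) % MIN_PER_DAY
        for h in range(24):
            if anchor == "clock":
                zt = ((h * 60 - lights_on_min) % MIN_PER_DAY) / 60.0
            else:
                zt = float(h)
            rows.append(
                dict(mouse_id=mouse_id, hour_bin=h, zt_hour=zt, km_per_h=km[h] / n_days)
            )
    return pd.DataFrame(rows, columns=["mouse_id", "hour_bin", "zt_hour", "km_per_h"])


def estimate_dark_fraction(
    series: Mapping[str, pd.DataFrame],
    config: AnalysisConfig | None = None,
) -> float:
    """Fraction of all rotations falling in the dark phase (ZT12–24)."""
    config = config or AnalysisConfig()
    dark = 0.0
    total = 0.0
    for df in series.values():
        if df.empty:
            continue
        zt_min = _zt_minutes(pd.to_datetime(df["timestamp"]), config.lights_off, config.photoperiod_h)
        rot = df["rotations"].to_numpy()
        dark += rot[zt_min >= 720].sum()
        total += rot.sum()
    if total == 0:
        raise DegenerateInputError("no rotations in dataset")
    return dark / total


# --------------------------------------------------------------------------
# Distribution views
# --------------------------------------------------------------------------


def quartile_partition(totals: pd.Series) -> pd.Series:
    """Label animals High / Average / Low by total distance quartile.

    The top ``n//4`` animals are High, the bottom ``n//4`` Low, the middle
    two quartiles Average.  Ties break by stable (input) order, so with all
    totals equal the first ``n//4`` animals land in Low and the last in High.
    Fewer than 4 animals is degenerate: everything is Average, with a warning.
    """
    n = len(totals)
    labels = pd.Series("Average", index=totals.index, dtype=object)
    if n < 4:
        warnings.warn("fewer than 4 animals; quartile partition is degenerate", stacklevel=2)
        return labels
    k = n // 4
    order = np.argsort(totals.to_numpy(), kind="stable")
    labels.iloc[order[:k]] = "Low"
    labels.iloc[order[-k:]] = "High"
    return labels


@dataclass
class DensityData:
    """Minute-count distribution for density plots: values, mean, median."""

    values: np.ndarray
    mean: float
    median: float


def density_data(minute_counts: Iterable[int], exclude_zeros: bool = True) -> DensityData:
    """Distribution of per-minute rotation counts, zero minutes excluded by default.

    Most minutes of a day are rest; the distribution of interest is over
    minutes in which the animal actually ran.  No day-level exclusion filter
    is applied here.
    """
    vals = np.asarray(list(minute_counts), dtype=float)
    if exclude_zeros:
        vals = vals[vals > 0]
    if vals.size == 0:
        return DensityData(vals, float("nan"), float("nan"))
    return DensityData(vals, float(vals.mean()), float(np.median(vals)))


def zero_minute_fraction(series: Mapping[str, pd.DataFrame] | pd.DataFrame) -> float:
    """Fraction of recorded minutes with zero rotations across the dataset."""
    if isinstance(series, pd.DataFrame):
        frames = [series]
    else:
        frames = [df for df in series.values() if len(df)]
    if not frames:
        raise DegenerateInputError("no minutes in dataset")
    total = sum(len(df) for df in frames)
    zeros = sum(int((df["rotations"] == 0).sum()) for df in frames)
    return zeros / total
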