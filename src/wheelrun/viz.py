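"""Actogram and heatmap matrices, and their rendering.

Correctness lives in the matrices — rotations per 10-min bin, with validity
masks separating "no data" from "zero running" — so tests never touch pixels.
Rendering is a thin matplotlib layer: classic double-plotted actograms with
the light phase shaded, a cohort heatmap over the study clock, density plots
with mean/median markers, and hourly activity waveforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, time, timedelta
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import ConfigError
from .metrics import MIN_PER_DAY, AnalysisConfig, DensityData


@dataclass
class ActogramMatrix:
    """One animal's activity raster: days × (double-plotted) time-of-day bins.

    Columns are anchored at clock midnight.  With ``double_plot`` the right
    half of row *d* repeats the left half of row *d+1* (the classic layout for
    eyeballing phase drift), so ``values[d, n_bins:] == values[d+1, :n_bins]``
    wherever both days exist.  ``valid`` is False where no data was recorded —
    a gap, not a zero.  ``light_mask`` is True in columns where lights are on.
    """

    days: list[date]
    values: np.ndarray   # (n_days, n_cols)
    valid: np.ndarray    # bool, same shape
    light_mask: np.ndarray  # bool, (n_cols,)
    bin_min: int
    double_plot: bool

    @property
    def n_bins_per_day(self) -> int:
        return MIN_PER_DAY // self.bin_min


@dataclass
class HeatmapMatrix:
    """Cohort heatmap: animals × consecutive time bins over the whole study."""

    mouse_ids: list[str]
    values: np.ndarray  # (n_animals, n_bins)
    valid: np.ndarray
    t0: pd.Timestamp    # start of bin 0
    bin_min: int


def _light_mask_for_day(bin_min: int, lights_off: time, photoperiod_h: float) -> np.ndarray:
    """True where lights are ON, per bin of a clock-midnight-anchored day."""
    n_bins = MIN_PER_DAY // bin_min
    off_min = lights_off.hour * 60 + lights_off.minute
    dark_len = int(round(photoperiod_h * 60))
    starts = np.arange(n_bins) * bin_min
    dark = ((starts - off_min) % MIN_PER_DAY) < dark_len
    return ~dark


def actogram_matrix(
    series_df: pd.DataFrame,
    bin_min: int = 10,
    double_plot: bool = True,
    config: AnalysisConfig | None = None,
) -> ActogramMatrix:
    """Bin one animal's minute series into an actogram matrix.

    Minutes are assigned to the clock-time bin containing their start, so the
    sum over bins equals the sum over minutes.  Missing minutes leave their
    bins invalid (masked), never imputed to zero.
    """
    config = config or AnalysisConfig()
    if MIN_PER_DAY % bin_min != 0:
        raise ConfigError(f"bin_min must divide 1440, got {bin_min}")
    n_bins = MIN_PER_DAY // bin_min
    ts = pd.to_datetime(series_df["timestamp"])
    dates = ts.dt.date
    d0, d1 = dates.min(), dates.max()
    days = [d0 + timedelta(days=i) for i in range((d1 - d0).days + 1)]
    day_index = {d: i for i, d in enumerate(days)}

    base = np.zeros((len(days), n_bins))
    valid = np.zeros((len(days), n_bins), dtype=bool)
    row = dates.map(day_index).to_numpy()
    col = ((ts.dt.hour * 60 + ts.dt.minute) // bin_min).to_numpy()
    rot = series_df["rotations"].to_numpy()
    np.add.at(base, (row, col), rot)
    valid[row, col] = True

    light_day = _light_mask_for_day(bin_min, config.lights_off, config.photoperiod_h)
    if not double_plot:
        return ActogramMatrix(days, base, valid, light_day, bin_min, False)

    vals = np.zeros((len(days), 2 * n_bins))
    vmask = np.zeros((len(days), 2 * n_bins), dtype=bool)
    vals[:, :n_bins] = base
    vmask[:, :n_bins] = valid
    vals[:-1, n_bins:] = base[1:]
    vmask[:-1, n_bins:] = valid[1:]
    light = np.concatenate([light_day, light_day])
    return ActogramMatrix(days, vals, vmask, light, bin_min, True)


def heatmap_matrix(
    series: Mapping[str, pd.DataFrame],
    bin_min: int = 10,
) -> HeatmapMatrix:
    """Bin every animal onto one common study clock.

    Bin 0 starts at the first recorded minute (floored to a bin boundary of
    the first calendar day).  Row sums conserve each animal's total rotations.
    """
    if MIN_PER_DAY % bin_min != 0:
        raise ConfigError(f"bin_min must divide 1440, got {bin_min}")
    nonempty = {m: df for m, df in series.items() if len(df)}
    if not nonempty:
        raise ConfigError("no data to bin")
    t_min = min(pd.to_datetime(df["timestamp"]).min() for df in nonempty.values())
    t_max = max(pd.to_datetime(df["timestamp"]).max() for df in nonempty.values())
    anchor = t_min.normalize()
    t0 = anchor + pd.Timedelta(
        minutes=int((t_min - anchor).total_seconds() // 60 // bin_min) * bin_min
    )
    n_bins = int((t_max - t0).total_seconds() // 60 // bin_min) + 1

    mouse_ids = sorted(series.keys(), key=_id_key)
    values = np.zeros((len(mouse_ids), n_bins))
    valid = np.zeros((len(mouse_ids), n_bins), dtype=bool)
    for i, m in enumerate(mouse_ids):
        df = series[m]
        if not len(df):
            continue
        ts = pd.to_datetime(df["timestamp"])
        col = ((ts - t0).dt.total_seconds() // 60 // bin_min).astype(int).to_numpy()
        np.add.at(values[i], col, df["rotations"].to_numpy())
        valid[i, col] = True
    return HeatmapMatrix(mouse_ids, values, valid, t0, bin_min)


def _id_key(mouse_id: str):
    parts = str(mouse_id).split("_")
    try:
        return (0,) + tuple(int(p) for p in parts)
    except ValueError:
        return (1, mouse_id)


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    meta = {"Date": None} if path.suffix.lower() == ".svg" else {}
    fig.savefig(path, dpi=150, metadata=meta or None)
    plt.close(fig)
    return path


def render_actogram(matrix: ActogramMatrix, path: str | Path, title: str = "") -> Path:
    """Classic bar-raster actogram; light phase shaded, rows scaled to their max."""
    n_days, n_cols = matrix.values.shape
    hours_span = n_cols * matrix.bin_min / 60.0
    fig, axes = plt.subplots(
        n_days, 1, figsize=(8, max(2, 0.45 * n_days)), sharex=True, squeeze=False
    )
    x = np.arange(n_cols) * matrix.bin_min / 60.0
    width = matrix.bin_min / 60.0
    for d in range(n_days):
        ax = axes[d, 0]
        for lit_start, lit_end in _mask_runs(matrix.light_mask):
            ax.axvspan(lit_start * width, lit_end * width, color="#fff3b0", lw=0)
        row = matrix.values[d].astype(float)
        rmax = row[matrix.valid[d]].max() if matrix.valid[d].any() else 0.0
        scaled = row / rmax if rmax > 0 else row
        scaled[~matrix.valid[d]] = 0.0
        ax.bar(x, scaled, width=width, align="edge", color="black")
        for gap_start, gap_end in _mask_runs(~matrix.valid[d]):
            ax.axvspan(gap_start * width, gap_end * width, color="0.85", lw=0)
        ax.set_ylim(0, 1.05)
        ax.set_yticks([])
        ax.set_ylabel(str(d + 1), rotation=0, va="center", fontsize=7)
        for spine in ("top", "right", "left"):
            ax.spines[spine].set_visible(False)
    axes[-1, 0].set_xlim(0, hours_span)
    axes[-1, 0].set_xlabel("time of day (h)")
    if title:
        fig.suptitle(title)
    return _save(fig, path)


def _mask_runs(mask: np.ndarray):
    """(start, end) index runs where a boolean mask is True; end exclusive."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def render_heatmap(matrix: HeatmapMatrix, path: str | Path, title: str = "") -> Path:
    """Cohort heatmap: one row per animal, color = rotations per bin."""
    fig, ax = plt.subplots(figsize=(10, max(2, 0.3 * len(matrix.mouse_ids))))
    vals = np.ma.masked_where(~matrix.valid, matrix.values)
    hours = matrix.values.shape[1] * matrix.bin_min / 60.0
    im = ax.imshow(
        vals, aspect="auto", interpolation="nearest", cmap="viridis",
        extent=(0, hours, len(matrix.mouse_ids) - 0.5, -0.5),
    )
    ax.set_yticks(range(len(matrix.mouse_ids)))
    ax.set_yticklabels(matrix.mouse_ids, fontsize=7)
    ax.set_xlabel("hours since study start")
    ax.set_ylabel("mouse id")
    fig.colorbar(im, ax=ax, label=f"rotations / {matrix.bin_min} min")
    if title:
        ax.set_title(title)
    return _save(fig, path)


def render_density(data: DensityData, path: str | Path, title: str = "") -> Path:
    """Density of per-minute rotation counts with mean (red) / median (blue) lines."""
    fig, ax = plt.subplots(figsize=(6, 4))
    if data.values.size == 0:
        ax.text(0.5, 0.5, "no nonzero minutes", ha="center", va="center",
                transform=ax.transAxes)
    else:
        ax.hist(data.values, bins=min(50, max(10, data.values.size // 5)),
                density=True, color="0.7", edgecolor="none")
        ax.axvline(data.mean, color="red", lw=1.5, label=f"mean = {data.mean:.1f}")
        ax.axvline(data.median, color="blue", lw=1.5, label=f"median = {data.median:.1f}")
        ax.legend(frameon=False)
    ax.set_xlabel("rotations per minute")
    ax.set_ylabel("density")
    if title:
        ax.set_title(title)
    return _save(fig, path)


def render_hourly_profile(
    profile: pd.DataFrame,
    path: str | Path,
    config: AnalysisConfig | None = None,
    title: str = "",
) -> Path:
    """Mean ± SEM hourly running distance, dark phase shaded gray."""
    config = config or AnalysisConfig()
    fig, ax = plt.subplots(figsize=(7, 4))
    wide = profile.pivot_table(index="zt_hour", columns="mouse_id", values="km_per_h")
    zt = wide.index.to_numpy()
    mean = wide.mean(axis=1).to_numpy()
    n = wide.notna().sum(axis=1).to_numpy()
    sd = wide.std(axis=1, ddof=1).to_numpy()
    sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    order = np.argsort(zt)
    ax.axvspan(12, 24, color="0.85", lw=0)
    ax.errorbar(zt[order], mean[order], yerr=sem[order], fmt="-o", ms=3, capsize=2,
                color="black")
    ax.set_xlabel("zeitgeber time (h; ZT12 = lights off)")
    ax.set_ylabel("running distance (km/h)")
    ax.set_xlim(0, 24)
    if title:
        ax.set_title(title)
    return _save(fig, path)


def export_matrix_csv(matrix: ActogramMatrix | HeatmapMatrix, path: str | Path) -> Path:
    """Sidecar CSV export of a matrix (NaN where invalid) for testability."""
    vals = matrix.values.astype(float).copy()
    vals[~matrix.valid] = np.nan
    if isinstance(matrix, ActogramMatrix):
        index = [d.isoformat() for d in matrix.days]
        index_name = "day"
    else:
        index = list(matrix.mouse_ids)
        index_name = "mouse_id"
    df = pd.DataFrame(vals, index=pd.Index(index, name=index_name))
    df.columns = [f"bin_{i}" for i in range(vals.shape[1])]
    df.to_csv(path)
    return Path(path)
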