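"""Replicate aggregation, one-way ANOVA, intensity time courses and plots.

Aggregation follows spreadsheet convention: mean ± sample standard
deviation (n-1 denominator) across independent replicates, computed only
over non-missing values. Condition comparisons use classical single-factor
ANOVA per time point; no multiple-testing correction is applied across
time points, and outputs say so.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .tracking import Track

__all__ = [
    "AnovaResult",
    "anova_single_factor",
    "intensity_time_course",
    "ConditionSeries",
    "aggregate_replicates",
    "compare_conditions",
    "plot_time_course",
    "plot_trajectories",
]


@dataclass(frozen=True)
class AnovaResult:
    """Single-factor ANOVA summary."""

    F: float
    df_between: int
    df_within: int
    p: float


def anova_single_factor(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA (F = MS_between / MS_within).

    Degenerate variance cases are defined explicitly: identical group
    means with positive within-variance give F = 0, p = 1; zero
    within-variance with distinct means gives F = inf, p = 0; all values
    equal gives F = 0, p = 1.
    """
    if len(groups) < 2:
        raise InputError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise InputError("every group needs at least two values")
    ns = np.array([len(a) for a in arrays])
    means = np.array([a.mean() for a in arrays])
    grand = np.concatenate(arrays).mean()
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(((a - m) ** 2).sum() for a, m in zip(arrays, means)))
    dfb = len(arrays) - 1
    dfw = int(ns.sum()) - len(arrays)
    if ssw == 0.0:
        f = 0.0 if ssb == 0.0 else float("inf")
        p = 1.0 if ssb == 0.0 else 0.0
    else:
        f = (ssb / dfb) / (ssw / dfw)
        p = float(stats.f.sf(f, dfb, dfw))
    return AnovaResult(F=float(f), df_between=dfb, df_within=dfw, p=p)


def intensity_time_course(
    detections: pd.DataFrame,
    n_frames: Optional[int] = None,
    mask: Optional[np.ndarray] = None,
    normalize: bool = False,
) -> pd.DataFrame:
    """Total detected-object intensity per time point.

    ``mask``, when given, is a boolean (Y, X) per-cell region; detections
    whose rounded centroid falls outside it are excluded. Frames without
    detections contribute 0. ``normalize=True`` divides by the first
    frame's total (which must be positive). Columns: frame, total_intensity.
    """
    required = {"frame", "x_px", "y_px", "intensity"}
    missing = required - set(detections.columns)
    if missing:
        raise InputError(f"detection table missing columns {sorted(missing)}")
    df = detections
    if mask is not None:
        yy = np.clip(np.round(df.y_px).astype(int), 0, mask.shape[0] - 1)
        xx = np.clip(np.round(df.x_px).astype(int), 0, mask.shape[1] - 1)
        df = df[mask[yy, xx]]
    last = int(df.frame.max()) + 1 if len(df) else 0
    n = n_frames if n_frames is not None else last
    totals = np.zeros(n)
    if len(df):
        sums = df.groupby("frame")["intensity"].sum()
        idx = sums.index.to_numpy(dtype=int)
        keep = idx < n
        totals[idx[keep]] = sums.to_numpy()[keep]
    if normalize:
        if n == 0 or totals[0] <= 0:
            raise InputError("cannot normalize: frame 0 total is not positive")
        totals = totals / totals[0]
    return pd.DataFrame({"frame": np.arange(n), "total_intensity": totals})


@dataclass(frozen=True)
class ConditionSeries:
    """Aggregated replicate time courses for one condition."""

    condition: str
    table: pd.DataFrame  # time, mean, sd, n


def aggregate_replicates(
    replicates: Sequence[pd.DataFrame],
    value_col: str = "fraction",
    time_col: str = "time_s",
    condition: str = "condition",
) -> ConditionSeries:
    """Mean ± sample SD per time point across replicate series.

    Replicates are aligned to the first replicate's time grid by nearest
    time bin; aggregates use only non-missing values. SD is NaN where a
    single replicate contributes.
    """
    if not replicates:
        raise InputError("no replicates given")
    for df in replicates:
        if time_col not in df.columns or value_col not in df.columns:
            raise InputError(f"replicate lacks columns {time_col!r}/{value_col!r}")
    grid = np.asarray(replicates[0][time_col], dtype=float)
    aligned = np.full((len(replicates), len(grid)), np.nan)
    for i, df in enumerate(replicates):
        t = df[time_col].to_numpy(dtype=float)
        v = df[value_col].to_numpy(dtype=float)
        for j, g in enumerate(grid):
            k = int(np.argmin(np.abs(t - g)))
            aligned[i, j] = v[k]
    with np.errstate(invalid="ignore"):
        n = np.sum(~np.isnan(aligned), axis=0)
        mean = np.nanmean(aligned, axis=0)
        sd = np.full(len(grid), np.nan)
        ok = n > 1
        sd[ok] = np.nanstd(aligned[:, ok], axis=0, ddof=1)
    table = pd.DataFrame({time_col: grid, "mean": mean, "sd": sd, "n": n})
    return ConditionSeries(condition=condition, table=table)


def compare_conditions(
    conditions: Mapping[str, Sequence[pd.DataFrame]],
    value_col: str = "fraction",
    time_col: str = "time_s",
) -> pd.DataFrame:
    """Tidy comparison table across conditions with per-time-point ANOVA.

    Input maps condition label to its replicate series. Output columns:
    condition, time, mean, sd, n, F, p — F/p repeat per time point and
    come from single-factor ANOVA over the replicate values of all
    conditions at that time point (no multiple-testing correction across
    time points). Requires >= 2 replicates per condition for the ANOVA.
    """
    if len(conditions) < 2:
        raise InputError("need at least two conditions to compare")
    series = {
        label: aggregate_replicates(reps, value_col, time_col, condition=label)
        for label, reps in conditions.items()
    }
    first = next(iter(series.values()))
    grid = first.table[time_col].to_numpy()

    # replicate values aligned per condition for the ANOVA
    aligned: dict[str, np.ndarray] = {}
    for label, reps in conditions.items():
        arr = np.full((len(reps), len(grid)), np.nan)
        for i, df in enumerate(reps):
            t = df[time_col].to_numpy(dtype=float)
            v = df[value_col].to_numpy(dtype=float)
            for j, g in enumerate(grid):
                arr[i, j] = v[int(np.argmin(np.abs(t - g)))]
        aligned[label] = arr

    f_vals = np.full(len(grid), np.nan)
    p_vals = np.full(len(grid), np.nan)
    for j in range(len(grid)):
        groups = []
        for label in conditions:
            g = aligned[label][:, j]
            g = g[~np.isnan(g)]
            if len(g) >= 2:
                groups.append(g)
        if len(groups) >= 2:
            res = anova_single_factor(groups)
            f_vals[j], p_vals[j] = res.F, res.p
    parts = []
    for label, cs in series.items():
        t = cs.table.copy()
        t.insert(0, "condition", label)
        t = t.rename(columns={time_col: "time"})
        t["F"] = f_vals
        t["p"] = p_vals
        parts.append(t)
    return pd.concat(parts, ignore_index=True)


def plot_time_course(
    comparison: pd.DataFrame, path: Union[str, Path], ylabel: str = "fraction"
) -> Path:
    """Mean ± SD time-course plot per condition from a comparison table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, grp in comparison.groupby("condition"):
        ax.errorbar(grp["time"], grp["mean"], yerr=grp["sd"], label=str(label), capsize=2)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_trajectories(
    tracks: Sequence[Track],
    path: Union[str, Path],
    field_size_px: Optional[tuple[int, int]] = None,
    title: str = "trajectories",
) -> Path:
    """Overlay all track paths in pixel coordinates (image convention)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for t in tracks:
        ax.plot(t.x, t.y, lw=0.8)
    if field_size_px is not None:
        h, w = field_size_px
        ax.set_xlim(0, w - 1)
        ax.set_ylim(h - 1, 0)
    else:
        ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
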