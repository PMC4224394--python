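"""Frame-to-frame global linking and track assembly.

Linking between consecutive frames is a global one-to-one assignment on a
combined distance + intensity cost,

    cost(i, j) = w_dist * d_ij / gate_radius + w_int * |I_i - I_j| / intensity_scale,

with pairs farther apart than the gating radius forbidden. Among
gate-feasible assignments the linker maximizes the number of links and,
among those, minimizes the total cost (solved as a linear assignment
problem with birth/death dummies). Unmatched detections end or start
tracks; there is no gap closing — a missed frame always splits a track.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .exceptions import ConfigurationError, InputError

__all__ = [
    "LinkParams",
    "Track",
    "link_frames",
    "build_tracks",
    "filter_tracks",
    "tracks_to_dataframe",
    "dataframe_to_tracks",
]


@dataclass(frozen=True)
class LinkParams:
    """Linking cost parameters.

    ``intensity_scale`` of None means "median detection intensity of the
    data being linked" (computed per call in :func:`build_tracks`).
    """

    gate_radius_px: float = 5.0
    w_dist: float = 1.0
    w_int: float = 0.5
    intensity_scale: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gate_radius_px <= 0:
            raise ConfigurationError("gate_radius_px must be > 0")
        if self.w_dist < 0 or self.w_int < 0 or self.w_dist + self.w_int <= 0:
            raise ConfigurationError("cost weights must be >= 0 and not both zero")
        if self.intensity_scale is not None and self.intensity_scale <= 0:
            raise ConfigurationError("intensity_scale must be > 0")


@dataclass
class Track:
    """A gap-free, time-ordered chain of detections."""

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.frames) >= 2 and not np.all(np.diff(self.frames) == 1):
            raise InputError("track frames must be strictly consecutive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])


def _resolve_scale(params: LinkParams, intensities: np.ndarray) -> float:
    if params.intensity_scale is not None:
        return params.intensity_scale
    pos = intensities[intensities > 0]
    scale = float(np.median(pos)) if len(pos) else 1.0
    return scale if scale > 0 else 1.0


def link_frames(
    dets_t: pd.DataFrame, dets_t1: pd.DataFrame, params: LinkParams = LinkParams()
) -> list[tuple[int, int]]:
    """Assign detections of frame t to frame t+1.

    Inputs are detection tables (x_px, y_px, intensity); the return value
    is a list of (row position in dets_t, row position in dets_t1) links.
    Empty inputs yield an empty assignment.
    """
    n, m = len(dets_t), len(dets_t1)
    if n == 0 or m == 0:
        return []
    a = dets_t[["x_px", "y_px"]].to_numpy(dtype=float)
    b = dets_t1[["x_px", "y_px"]].to_numpy(dtype=float)
    ia = dets_t["intensity"].to_numpy(dtype=float)
    ib = dets_t1["intensity"].to_numpy(dtype=float)
    scale = _resolve_scale(params, np.concatenate([ia, ib]))

    d = cdist(a, b)
    feasible = d <= params.gate_radius_px
    cost = params.w_dist * d / params.gate_radius_px + params.w_int * np.abs(
        ia[:, None] - ib[None, :]
    ) / scale

    # L exceeds any feasible total cost, so cardinality dominates;
    # forbidden links (4L) are always worse than a death + a birth (2L).
    L = float(cost[feasible].sum()) + 1.0 if feasible.any() else 1.0
    big = np.full((n + m, n + m), 0.0)
    big[:n, :m] = np.where(feasible, cost, 4.0 * L)
    big[:n, m:] = 4.0 * L
    big[n:, :m] = 4.0 * L
    big[np.arange(n), m + np.arange(n)] = L  # death of i
    big[n + np.arange(m), np.arange(m)] = L  # birth of j
    rows, cols = linear_sum_assignment(big)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < n and c < m and feasible[r, c]
    ]


def build_tracks(
    detections: pd.DataFrame, params: LinkParams = LinkParams()
) -> list[Track]:
    """Chain frame-to-frame links into tracks.

    Detections are canonically re-ordered within each frame (by x, y,
    intensity) before linking, so the resulting track set is invariant to
    the input row order. A track ends whenever its detection finds no
    gate-feasible partner in the next frame; length-1 chains (isolated
    singletons) are discarded. Frames must be non-negative integers.
    """
    required = {"frame", "x_px", "y_px", "intensity"}
    missing = required - set(detections.columns)
    if missing:
        raise InputError(f"detection table missing columns {sorted(missing)}")
    if len(detections) == 0:
        return []
    frames = detections["frame"].to_numpy()
    if not np.all(np.isfinite(frames)) or np.any(frames != np.floor(frames)):
        raise InputError("frame indices must be integers")
    if np.any(frames < 0):
        raise InputError("frame indices must be non-negative")

    if params.intensity_scale is None:
        params = LinkParams(
            gate_radius_px=params.gate_radius_px,
            w_dist=params.w_dist,
            w_int=params.w_int,
            intensity_scale=_resolve_scale(
                params, detections["intensity"].to_numpy(dtype=float)
            ),
        )

    df = detections.sort_values(
        ["frame", "x_px", "y_px", "intensity"], kind="mergesort"
    ).reset_index(drop=True)
    by_frame = {int(f): g for f, g in df.groupby("frame", sort=True)}
    frame_ids = sorted(by_frame)

    tracks: list[Track] = []
    next_id = 0
    # open chains: list of dicts with running arrays, keyed by row position
    open_chains: dict[int, dict] = {}

    def close(chain: dict) -> None:
        nonlocal next_id
        if len(chain["frames"]) >= 2:
            tracks.append(
                Track(
                    track_id=next_id,
                    frames=np.array(chain["frames"]),
                    x=np.array(chain["x"]),
                    y=np.array(chain["y"]),
                    intensity=np.array(chain["intensity"]),
                )
            )
            next_id += 1

    def start_chain(row) -> dict:
        return {
            "frames": [int(row.frame)],
            "x": [float(row.x_px)],
            "y": [float(row.y_px)],
            "intensity": [float(row.intensity)],
        }

    prev_frame: Optional[int] = None
    prev_chains: dict[int, dict] = {}
    for f in frame_ids:
        grp = by_frame[f].reset_index(drop=True)
        if prev_frame is None or f != prev_frame + 1:
            for chain in prev_chains.values():
                close(chain)
            prev_chains = {i: start_chain(r) for i, r in enumerate(grp.itertuples())}
        else:
            prev_grp = by_frame[prev_frame].reset_index(drop=True)
            links = link_frames(prev_grp, grp, params)
            linked_prev = {i for i, _ in links}
            linked_next = {}
            for i, j in links:
                linked_next[j] = prev_chains[i]
            for i, chain in prev_chains.items():
                if i not in linked_prev:
                    close(chain)
            new_chains: dict[int, dict] = {}
            for j, row in enumerate(grp.itertuples()):
                if j in linked_next:
                    chain = linked_next[j]
                    chain["frames"].append(int(row.frame))
                    chain["x"].append(float(row.x_px))
                    chain["y"].append(float(row.y_px))
                    chain["intensity"].append(float(row.intensity))
                    new_chains[j] = chain
                else:
                    new_chains[j] = start_chain(row)
            prev_chains = new_chains
        prev_frame = f
    for chain in prev_chains.values():
        close(chain)
    return tracks


def filter_tracks(tracks: Sequence[Track], min_frames: int = 6) -> list[Track]:
    """Keep only tracks spanning at least ``min_frames`` detections.

    The default of 6 retains trajectories of more than 5 consecutive
    frames, the standard false-track filter for these series.
    """
    if min_frames < 2:
        raise ConfigurationError("min_frames must be >= 2")
    return [t for t in tracks if len(t) >= min_frames]


def tracks_to_dataframe(tracks: Sequence[Track]) -> pd.DataFrame:
    """Long-form table: track_id, frame, x_px, y_px, intensity."""
    if not tracks:
        return pd.DataFrame(columns=["track_id", "frame", "x_px", "y_px", "intensity"])
    parts = [
        pd.DataFrame(
            {
                "track_id": t.track_id,
                "frame": t.frames,
                "x_px": t.x,
                "y_px": t.y,
                "intensity": t.intensity,
            }
        )
        for t in tracks
    ]
    return pd.concat(parts, ignore_index=True)


def dataframe_to_tracks(df: pd.DataFrame) -> list[Track]:
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                track_id=int(tid),
                frames=grp["frame"].to_numpy(),
                x=grp["x_px"].to_numpy(),
                y=grp["y_px"].to_numpy(),
                intensity=grp["intensity"].to_numpy(),
            )
        )
    return tracks
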