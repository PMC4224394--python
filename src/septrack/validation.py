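"""Ground-truth comparison utilities for detection and tracking.

These helpers quantify how well the measured pipeline recovers the
generator's ground truth: per-frame detection recall/precision under a
match radius, and track recovery with identity bookkeeping.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .tracking import Track

__all__ = ["detection_pr", "match_detections_to_truth", "evaluate_tracking"]


def _match_frame(det_xy: np.ndarray, truth_xy: np.ndarray, radius: float) -> list[tuple[int, int]]:
    """Optimal one-to-one matching within a radius (min total distance)."""
    if len(det_xy) == 0 or len(truth_xy) == 0:
        return []
    d = cdist(det_xy, truth_xy)
    feasible = d <= radius
    if not feasible.any():
        return []
    big = d.max() * (d.shape[0] + d.shape[1] + 1) + 1.0
    cost = np.where(feasible, d, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if feasible[r, c]]


def detection_pr(
    detections: pd.DataFrame, truth_tracks: pd.DataFrame, radius_px: float = 2.0
) -> tuple[float, float]:
    """(recall, precision) of a detection table against true positions.

    ``truth_tracks`` uses the ground-truth schema (object_id, frame, x_px,
    y_px). Matching is per frame, one-to-one, within ``radius_px``.
    """
    truth_by_frame = {int(f): g for f, g in truth_tracks.groupby("frame")}
    det_by_frame = {int(f): g for f, g in detections.groupby("frame")}
    n_truth = n_det = n_match = 0
    for f, tg in truth_by_frame.items():
        t_xy = tg[["x_px", "y_px"]].to_numpy(dtype=float)
        n_truth += len(t_xy)
        dg = det_by_frame.get(f)
        if dg is None:
            continue
        d_xy = dg[["x_px", "y_px"]].to_numpy(dtype=float)
        n_match += len(_match_frame(d_xy, t_xy, radius_px))
    n_det = len(detections)
    recall = n_match / n_truth if n_truth else float("nan")
    precision = n_match / n_det if n_det else float("nan")
    return recall, precision


def match_detections_to_truth(
    detections: pd.DataFrame, truth_tracks: pd.DataFrame, radius_px: float = 2.0
) -> pd.DataFrame:
    """Detection table with an ``object_id`` column (-1 where unmatched)."""
    out = detections.copy().reset_index(drop=True)
    out["object_id"] = -1
    truth_by_frame = {int(f): g for f, g in truth_tracks.groupby("frame")}
    for f, dg in out.groupby("frame"):
        tg = truth_by_frame.get(int(f))
        if tg is None:
            continue
        d_xy = dg[["x_px", "y_px"]].to_numpy(dtype=float)
        t_xy = tg[["x_px", "y_px"]].to_numpy(dtype=float)
        ids = tg["object_id"].to_numpy()
        for r, c in _match_frame(d_xy, t_xy, radius_px):
            out.loc[dg.index[r], "object_id"] = int(ids[c])
    return out


def evaluate_tracking(
    tracks: Sequence[Track],
    truth_tracks: pd.DataFrame,
    radius_px: float = 2.0,
    purity_min: float = 0.5,
    coverage_min: float = 0.8,
) -> dict:
    """Track-recovery summary against ground truth.

    For every predicted track, detections are matched to true objects per
    frame; the track's identity is its majority object and its *purity*
    the fraction of matched detections agreeing with it. A true object
    counts as *recovered* when the union of its frames covered by tracks
    of its identity (purity above ``purity_min``; majority rule by
    default) spans at least ``coverage_min`` of its frames. Identity
    switches — frames at which a track's matched object changes — are
    counted separately, so mixed tracks are visible in ``n_switches`` and
    ``mean_purity`` rather than silently voiding coverage.

    Returns a dict with recovered_fraction, n_switches, mean_purity and
    per-object coverage.
    """
    det = pd.concat(
        [
            pd.DataFrame(
                {"track_id": t.track_id, "frame": t.frames, "x_px": t.x, "y_px": t.y,
                 "intensity": t.intensity}
            )
            for t in tracks
        ],
        ignore_index=True,
    ) if tracks else pd.DataFrame(columns=["track_id", "frame", "x_px", "y_px", "intensity"])
    matched = match_detections_to_truth(det, truth_tracks, radius_px)

    n_switches = 0
    purities = []
    coverage: dict[int, set] = {}
    for tid, grp in matched.groupby("track_id"):
        grp = grp.sort_values("frame")
        ids = grp.object_id.to_numpy()
        known = ids[ids >= 0]
        if len(known) == 0:
            purities.append(0.0)
            continue
        vals, counts = np.unique(known, return_counts=True)
        major = int(vals[np.argmax(counts)])
        purity = counts.max() / len(known)
        purities.append(float(purity))
        n_switches += int(np.sum(np.diff(known) != 0))
        if purity >= purity_min:
            coverage.setdefault(major, set()).update(
                grp.frame[grp.object_id == major].tolist()
            )
    per_object = {}
    recovered = 0
    objects = truth_tracks.object_id.unique()
    for obj in objects:
        n_frames_obj = int((truth_tracks.object_id == obj).sum())
        cov = len(coverage.get(int(obj), ())) / n_frames_obj
        per_object[int(obj)] = cov
        if cov >= coverage_min:
            recovered += 1
    return {
        "recovered_fraction": recovered / len(objects) if len(objects) else float("nan"),
        "n_switches": n_switches,
        "mean_purity": float(np.mean(purities)) if purities else float("nan"),
        "coverage": per_object,
    }
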