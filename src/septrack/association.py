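"""Object-based colocalization and dwell-time analysis.

Colocalization is object-based: the fraction of objects in one channel
whose centroid lies within a radius of any object centroid in the other
channel. It is deliberately not symmetric; report both directions when
that matters. An association run is a maximal stretch of frames during
which a tracked object stays within the radius of one reference object
(with the same reference kept while it remains in range); its duration is
a dwell time. Runs truncated by the start or end of the track are flagged
censored and excluded from dwell means by default, since their true
duration is only bounded below.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError
from .tracking import Track

__all__ = [
    "object_coloc_fraction",
    "coloc_time_course",
    "AssociationEvent",
    "association_runs",
    "DwellStats",
    "dwell_stats",
    "events_to_dataframe",
]


def _xy(df: pd.DataFrame) -> np.ndarray:
    return df[["x_px", "y_px"]].to_numpy(dtype=float)


def object_coloc_fraction(
    dets_a: pd.DataFrame, dets_b: pd.DataFrame, radius_px: float
) -> float:
    """Fraction of A-objects whose nearest B-object is within the radius.

    Both tables must come from the same frame and field. Returns NaN when
    A is empty (no objects to classify).
    """
    if radius_px < 0:
        raise ConfigurationError("radius_px must be >= 0")
    if len(dets_a) == 0:
        return float("nan")
    if len(dets_b) == 0:
        return 0.0
    a, b = _xy(dets_a), _xy(dets_b)
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return float((d2.min(axis=1) <= radius_px**2).mean())


def coloc_time_course(
    dets_a: pd.DataFrame,
    dets_b: pd.DataFrame,
    radius_px: float,
    bin_frames: int = 1,
    frame_interval_ms: Optional[float] = None,
) -> pd.DataFrame:
    """Object-based colocalization fraction per time bin.

    Both inputs are detection tables with a ``frame`` column. Within each
    bin of ``bin_frames`` frames the fraction is the pooled count of
    colocalized A-objects over the pooled count of A-objects. Columns:
    ``frame_bin`` (bin start frame), ``fraction``, ``n_objects`` and, when
    ``frame_interval_ms`` is given, ``time_s`` (bin-center time).
    Bins without any A-object get fraction NaN. An empty A table yields an
    empty series.
    """
    if bin_frames < 1:
        raise ConfigurationError("bin_frames must be >= 1")
    if radius_px < 0:
        raise ConfigurationError("radius_px must be >= 0")
    if len(dets_a) == 0:
        cols = ["frame_bin", "fraction", "n_objects"]
        return pd.DataFrame(columns=cols)
    for df, name in ((dets_a, "A"), (dets_b, "B")):
        if "frame" not in df.columns:
            raise InputError(f"detection table {name} lacks a 'frame' column")
    b_by_frame = {int(f): g for f, g in dets_b.groupby("frame")}
    last = int(dets_a.frame.max())
    rows = []
    for start in range(0, last + 1, bin_frames):
        hits = 0
        total = 0
        sub = dets_a[(dets_a.frame >= start) & (dets_a.frame < start + bin_frames)]
        for f, grp in sub.groupby("frame"):
            bf = b_by_frame.get(int(f), None)
            n = len(grp)
            total += n
            if bf is None or len(bf) == 0:
                continue
            frac = object_coloc_fraction(grp, bf, radius_px)
            hits += int(round(frac * n))
        rows.append(
            (start, hits / total if total else float("nan"), total)
        )
    out = pd.DataFrame(rows, columns=["frame_bin", "fraction", "n_objects"])
    if frame_interval_ms is not None:
        out["time_s"] = (out.frame_bin + (bin_frames - 1) / 2.0) * frame_interval_ms / 1000.0
    return out


@dataclass(frozen=True)
class AssociationEvent:
    """A maximal run of frames spent within the radius of one reference.

    ``end_frame`` is inclusive; ``dwell_s`` counts end - start + 1 frame
    intervals. ``censored`` is True when the run touches the start or end
    of the track, so its true duration is only a lower bound.
    """

    track_id: int
    ref_id: int
    start_frame: int
    end_frame: int
    dwell_s: float
    censored_start: bool
    censored_end: bool
    n_gap_frames: int = 0

    @property
    def censored(self) -> bool:
        return self.censored_start or self.censored_end

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def association_runs(
    track: Track,
    refs: pd.DataFrame,
    radius_px: float = 3.0,
    frame_interval_ms: float = 154.0,
    max_gap_frames: int = 0,
) -> list[AssociationEvent]:
    """Find the association runs of one track on reference objects.

    ``refs`` is a table (frame, ref_id, x_px, y_px) of reference-object
    positions covering the track's frame span; frames missing from it
    simply have no reference in range. Per frame the track is associated
    when within ``radius_px`` of any reference; the assignment is sticky
    (the current reference is kept while it stays within the radius, and
    otherwise the nearest one is taken). Runs of the same reference
    separated by at most ``max_gap_frames`` unassociated frames are
    merged; a switch to a different reference always ends the run.
    """
    if radius_px < 0:
        raise ConfigurationError("radius_px must be >= 0")
    if max_gap_frames < 0:
        raise ConfigurationError("max_gap_frames must be >= 0")
    required = {"frame", "ref_id", "x_px", "y_px"}
    missing = required - set(refs.columns)
    if missing:
        raise InputError(f"reference table missing columns {sorted(missing)}")

    refs_by_frame = {int(f): g for f, g in refs.groupby("frame")}
    r2 = radius_px**2
    current: Optional[int] = None  # ref_id associated at the previous frame
    assoc = np.full(len(track), -1, dtype=int)  # ref_id per frame, -1 = none
    for k, f in enumerate(track.frames):
        grp = refs_by_frame.get(int(f))
        if grp is None or len(grp) == 0:
            current = None
            continue
        d2 = (grp.x_px.to_numpy() - track.x[k]) ** 2 + (
            grp.y_px.to_numpy() - track.y[k]
        ) ** 2
        ids = grp.ref_id.to_numpy()
        if current is not None:
            pos = np.where(ids == current)[0]
            if len(pos) and d2[pos[0]] <= r2:
                assoc[k] = current
                continue
        j = int(np.argmin(d2))
        if d2[j] <= r2:
            assoc[k] = int(ids[j])
            current = int(ids[j])
        else:
            current = None

    # maximal runs, merging across short gaps of the same reference
    events: list[AssociationEvent] = []
    dt_s = frame_interval_ms / 1000.0
    k = 0
    n = len(track)
    while k < n:
        if assoc[k] < 0:
            k += 1
            continue
        ref = int(assoc[k])
        start = k
        end = k
        gaps = 0
        j = k + 1
        while j < n:
            if assoc[j] == ref:
                end = j
                j += 1
            elif assoc[j] < 0:
                # look ahead across a gap of unassociated frames
                g = 0
                jj = j
                while jj < n and assoc[jj] < 0 and g < max_gap_frames:
                    g += 1
                    jj += 1
                if jj < n and assoc[jj] == ref and g <= max_gap_frames and g > 0:
                    gaps += g
                    end = jj
                    j = jj + 1
                else:
                    break
            else:
                break
        events.append(
            AssociationEvent(
                track_id=track.track_id,
                ref_id=ref,
                start_frame=int(track.frames[start]),
                end_frame=int(track.frames[end]),
                dwell_s=(end - start + 1) * dt_s,
                censored_start=start == 0,
                censored_end=end == n - 1,
                n_gap_frames=gaps,
            )
        )
        k = end + 1
    return events


@dataclass(frozen=True)
class DwellStats:
    """Summary of dwell times in seconds."""

    mean_s: float
    median_s: float
    n: int
    hist_counts: tuple[int, ...]
    hist_edges: tuple[float, ...]


def dwell_stats(
    events: Sequence[AssociationEvent],
    censoring: str = "exclude",
    bins: int = 10,
    min_frames: int = 1,
) -> DwellStats:
    """Mean/median/histogram of event dwell times.

    ``censoring='exclude'`` (default) drops events truncated by track
    boundaries; ``'include'`` keeps them (their dwell then underestimates
    the true residence time). ``min_frames`` discards events shorter than
    that many frames before anything else — runs of one or two frames are
    typically motile objects passing through the association radius, not
    docking events; for a memoryless dwell process the exclusion shifts
    the mean by only the cutoff duration. Raises on empty input or when
    filtering leaves no estimable event.
    """
    if censoring not in ("exclude", "include"):
        raise ConfigurationError(f"unknown censoring policy {censoring!r}")
    if min_frames < 1:
        raise ConfigurationError("min_frames must be >= 1")
    if len(events) == 0:
        raise InputError("no association events given")
    events = [e for e in events if e.n_frames >= min_frames]
    if not events:
        raise InputError(f"no events of at least {min_frames} frames")
    if censoring == "exclude":
        kept = [e for e in events if not e.censored]
        if not kept:
            raise InputError("all events are censored; nothing estimable")
    else:
        kept = list(events)
    d = np.array([e.dwell_s for e in kept])
    counts, edges = np.histogram(d, bins=bins)
    return DwellStats(
        mean_s=float(d.mean()),
        median_s=float(np.median(d)),
        n=len(d),
        hist_counts=tuple(int(c) for c in counts),
        hist_edges=tuple(float(e) for e in edges),
    )


def events_to_dataframe(events: Iterable[AssociationEvent]) -> pd.DataFrame:
    """Events CSV schema: track_id, ref_id, start_frame, end_frame, dwell_s, censored."""
    rows = [
        {
            "track_id": e.track_id,
            "ref_id": e.ref_id,
            "start_frame": e.start_frame,
            "end_frame": e.end_frame,
            "dwell_s": e.dwell_s,
            "censored": e.censored,
            "n_gap_frames": e.n_gap_frames,
        }
        for e in events
    ]
    cols = ["track_id", "ref_id", "start_frame", "end_frame", "dwell_s", "censored", "n_gap_frames"]
    return pd.DataFrame(rows, columns=cols)
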