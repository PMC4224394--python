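"""End-to-end convenience: simulate/load -> detect -> track -> measure.

Thin glue over the analysis modules so the CLI, tests and acceptance runs
share one code path. Every stage remains available separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .association import AssociationEvent, association_runs
from .config import SimConfig
from .io import Movie
from .motility import metrics_table
from .preprocess import DetectParams, bleach_correct, detect_movie
from .simulate import GroundTruth, simulate_movie
from .tracking import LinkParams, Track, build_tracks, filter_tracks

__all__ = [
    "AnalysisParams",
    "detect_and_track",
    "ref_table_from_channel",
    "movie_association_events",
    "AnalysisResult",
    "analyze_movie",
    "simulate_and_analyze",
    "pooled_motile_speed",
]


@dataclass(frozen=True)
class AnalysisParams:
    """Bundled analysis-stage parameters with the standard defaults."""

    detect: DetectParams = field(default_factory=DetectParams)
    link: LinkParams = field(default_factory=LinkParams)
    min_track_frames: int = 6
    motility_threshold_px: float = 3.0
    association_radius_px: float = 3.0
    max_gap_frames: int = 0
    bleach_correction: bool = True


def detect_and_track(
    movie: Movie, channel: int | str = 0, params: AnalysisParams = AnalysisParams()
) -> tuple[pd.DataFrame, list[Track]]:
    """Detect spots on one channel and assemble length-filtered tracks."""
    src = bleach_correct(movie) if params.bleach_correction else movie
    detections = detect_movie(src, channel=channel, params=params.detect)
    tracks = filter_tracks(
        build_tracks(detections, params.link), params.min_track_frames
    )
    return detections, tracks


def ref_table_from_channel(
    movie: Movie,
    channel: int | str = "ref",
    params: AnalysisParams = AnalysisParams(),
    cluster_radius_px: float = 2.5,
    min_frames: int = 6,
    fill_gaps: bool = True,
) -> pd.DataFrame:
    """Reference table (frame, ref_id, x_px, y_px) from a detected channel.

    Reference structures need identities that survive single-frame
    detection dropouts (a no-gap-closing tracker would split them), and
    they are stationary or slowly drifting. Detections are therefore
    clustered over time: each detection joins the nearest existing
    cluster centroid within ``cluster_radius_px`` (the centroid follows
    as a running mean, accommodating slow drift) or founds a new cluster.
    Clusters seen in fewer than ``min_frames`` frames are dropped.

    ``fill_gaps`` linearly interpolates each cluster's position over
    frames where its detection dropped out (between its first and last
    appearance): reference structures do not blink, so holes are
    detection noise, not absence.
    """
    src = bleach_correct(movie) if params.bleach_correction else movie
    detections = detect_movie(src, channel=channel, params=params.detect)
    if len(detections) == 0:
        return pd.DataFrame(columns=["frame", "ref_id", "x_px", "y_px"])
    centroids: list[np.ndarray] = []
    counts: list[int] = []
    assigned = np.empty(len(detections), dtype=int)
    det = detections.sort_values(["frame", "x_px", "y_px"]).reset_index(drop=True)
    xy = det[["x_px", "y_px"]].to_numpy(dtype=float)
    for i in range(len(det)):
        if centroids:
            c = np.asarray(centroids)
            d = np.hypot(c[:, 0] - xy[i, 0], c[:, 1] - xy[i, 1])
            j = int(np.argmin(d))
            if d[j] <= cluster_radius_px:
                assigned[i] = j
                counts[j] += 1
                centroids[j] = c[j] + (xy[i] - c[j]) / counts[j]
                continue
        centroids.append(xy[i].copy())
        counts.append(1)
        assigned[i] = len(centroids) - 1
    det["ref_id"] = assigned
    keep = det.groupby("ref_id")["frame"].nunique()
    det = det[det.ref_id.map(keep) >= min_frames]
    # one position per (frame, ref) — duplicates within the radius collapse
    det = det.sort_values(["frame", "ref_id"]).drop_duplicates(["frame", "ref_id"])
    out = det[["frame", "ref_id", "x_px", "y_px"]].reset_index(drop=True)
    if fill_gaps and len(out):
        parts = []
        for rid, grp in out.groupby("ref_id"):
            grp = grp.set_index("frame").sort_index()
            full = np.arange(grp.index.min(), grp.index.max() + 1)
            grp = grp.reindex(full)
            grp["ref_id"] = rid
            grp[["x_px", "y_px"]] = grp[["x_px", "y_px"]].interpolate(method="linear")
            parts.append(grp.rename_axis("frame").reset_index())
        out = (
            pd.concat(parts, ignore_index=True)
            .sort_values(["frame", "ref_id"])
            .reset_index(drop=True)[["frame", "ref_id", "x_px", "y_px"]]
        )
    return out


def movie_association_events(
    tracks: Sequence[Track],
    refs: pd.DataFrame,
    frame_interval_ms: float,
    radius_px: float = 3.0,
    max_gap_frames: int = 0,
) -> list[AssociationEvent]:
    """Association runs pooled over all tracks of a movie."""
    events: list[AssociationEvent] = []
    for t in tracks:
        events.extend(
            association_runs(
                t,
                refs,
                radius_px=radius_px,
                frame_interval_ms=frame_interval_ms,
                max_gap_frames=max_gap_frames,
            )
        )
    return events


@dataclass
class AnalysisResult:
    """Everything one movie's analysis produces."""

    detections: pd.DataFrame
    tracks: list[Track]
    metrics: pd.DataFrame
    refs: Optional[pd.DataFrame] = None
    events: Optional[list[AssociationEvent]] = None
    truth: Optional[GroundTruth] = None


def analyze_movie(
    movie: Movie,
    params: AnalysisParams = AnalysisParams(),
    coat_channel: int | str = 0,
    ref_channel: Optional[int | str] = None,
) -> AnalysisResult:
    """Full single-movie analysis; adds association when a ref channel is given."""
    detections, tracks = detect_and_track(movie, channel=coat_channel, params=params)
    metrics = metrics_table(tracks, movie.meta, params.motility_threshold_px)
    refs = events = None
    if ref_channel is not None:
        refs = ref_table_from_channel(movie, channel=ref_channel, params=params)
        events = movie_association_events(
            tracks,
            refs,
            frame_interval_ms=movie.meta.frame_interval_ms,
            radius_px=params.association_radius_px,
            max_gap_frames=params.max_gap_frames,
        )
    return AnalysisResult(
        detections=detections, tracks=tracks, metrics=metrics, refs=refs, events=events
    )


def simulate_and_analyze(
    config: SimConfig,
    params: AnalysisParams = AnalysisParams(),
    with_association: bool = True,
) -> AnalysisResult:
    """Simulate one movie at ``config`` and run the full analysis on it."""
    movie, truth = simulate_movie(config)
    result = analyze_movie(
        movie,
        params=params,
        coat_channel="coat",
        ref_channel="ref" if with_association else None,
    )
    result.truth = truth
    return result


def pooled_motile_speed(metrics_list: Sequence[pd.DataFrame]) -> tuple[float, int]:
    """Mean motile-step speed pooled over movies, weighted by step counts.

    Tracks without motile steps are skipped (their speed is missing).
    Returns (speed in µm/s, number of contributing tracks).
    """
    speeds = []
    for m in metrics_list:
        ok = m.mean_motile_speed_um_s.notna()
        n_motile = (1.0 - m.immobile_fraction[ok]) * m.n_steps[ok]
        speeds.append(
            pd.DataFrame(
                {"speed": m.mean_motile_speed_um_s[ok], "w": n_motile}
            )
        )
    allspeeds = pd.concat(speeds, ignore_index=True) if speeds else pd.DataFrame()
    if not len(allspeeds) or allspeeds.w.sum() == 0:
        return float("nan"), 0
    v = float(np.average(allspeeds.speed, weights=allspeeds.w))
    return v, int(len(allspeeds))
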