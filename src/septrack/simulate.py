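"""Synthetic two-channel movie generator with full ground truth.

The generator emulates TIRF acquisitions of fluorescently tagged coat
objects (channel ``coat``) that alternate between a filament-bound,
essentially immobile state and a directed motile state, together with a
reference channel (``ref``) of larger, dimmer endosome-like structures
that a configurable fraction of object-frames colocalizes with.

The motion model is a two-state continuous-time Markov switch with
exponential sojourn times. While bound, the object sits at an anchor on
the filament field and wiggles with independent per-frame Gaussian jitter;
while motile it travels at constant speed along a heading that diffuses
slowly between frames. On binding, the object snaps to the nearest
filament point; boundaries are reflective so the object count is constant
and detection recall is well defined.

Image formation: each object is a 2-D Gaussian; signal plus background
decays exponentially with the bleaching time constant, and the camera adds
Poisson shot noise and Gaussian read noise. Everything is reproducible for
a fixed config seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from .config import SimConfig
from .exceptions import ConfigurationError
from .io import Movie, MovieMetadata, write_movie

__all__ = [
    "FilamentField",
    "GroundTruth",
    "make_filament_field",
    "simulate_tracks",
    "render_movie",
    "simulate_movie",
    "write_simulation",
]

# independent deterministic RNG streams per stage, all keyed on the config seed
_STREAM_FIELD = 11
_STREAM_TRACKS = 22
_STREAM_RENDER = 33


def _rng(stage: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([stage, seed])


@dataclass(frozen=True)
class FilamentField:
    """A set of 2-D polylines (x, y pixel coordinates) inside the field."""

    filaments: tuple[np.ndarray, ...]
    field_size_px: tuple[int, int]

    def all_points(self) -> np.ndarray:
        if not self.filaments:
            return np.empty((0, 2))
        return np.concatenate(self.filaments, axis=0)


@dataclass
class GroundTruth:
    """Exact per-frame object positions/states plus the designed associations.

    ``tracks``: object_id, frame, x_px, y_px, state ('bound' | 'motile').
    ``association_intervals``: maximal frame runs during which an object's
    true position lies within the association radius of a reference object
    (object_id, ref_id, start_frame, end_frame; end inclusive).
    ``ref_positions``: frame, ref_id, x_px, y_px for every frame a
    reference object exists.
    ``bound_intervals``: the underlying state process
    (object_id, start_frame, end_frame, anchor_x, anchor_y, completed) --
    ``completed`` is False for intervals truncated by the series bounds.
    """

    tracks: pd.DataFrame
    association_intervals: pd.DataFrame
    ref_positions: pd.DataFrame
    bound_intervals: pd.DataFrame
    config: SimConfig

    def positions(self, object_id: int) -> np.ndarray:
        sub = self.tracks[self.tracks.object_id == object_id]
        return sub[["x_px", "y_px"]].to_numpy()


def _reflect(value: float, low: float, high: float) -> float:
    """Fold a coordinate into [low, high] by mirror reflection."""
    span = high - low
    if span <= 0:
        return low
    period = 2.0 * span
    q = (value - low) % period
    if q > span:
        q = period - q
    return low + q


def make_filament_field(config: SimConfig) -> FilamentField:
    """Generate a random field of persistent filament polylines.

    Each filament is a correlated random walk: fixed-length segments whose
    heading diffuses with standard deviation sqrt(step/persistence) per
    segment, started at a uniform position/direction and clipped to the
    field. Deterministic for a fixed config seed.
    """
    h, w = config.field_size_px
    if h <= 0 or w <= 0:
        raise ConfigurationError("field size must be positive")
    rng = _rng(_STREAM_FIELD, config.seed)
    step = 1.5
    base_len = 0.9 * min(h, w)
    filaments = []
    for _ in range(config.n_filaments):
        length = base_len * rng.uniform(0.6, 1.4)
        n_seg = max(2, int(length / step))
        x = rng.uniform(0, w - 1)
        y = rng.uniform(0, h - 1)
        heading = rng.uniform(0, 2 * np.pi)
        sd = np.sqrt(step / config.filament_persistence)
        pts = np.empty((n_seg, 2))
        pts[0] = (x, y)
        for i in range(1, n_seg):
            heading += rng.normal(0.0, sd)
            x = _reflect(x + step * np.cos(heading), 0.0, w - 1.0)
            y = _reflect(y + step * np.sin(heading), 0.0, h - 1.0)
            pts[i] = (x, y)
        filaments.append(pts)
    return FilamentField(filaments=tuple(filaments), field_size_px=(h, w))


def _runs_of(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal values: list of (value, start, end) inclusive."""
    runs = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            runs.append((int(values[start]), start, i - 1))
            start = i
    return runs


def simulate_tracks(config: SimConfig, field: Optional[FilamentField] = None) -> GroundTruth:
    """Simulate object trajectories, states and reference-channel layout.

    Objects start in their stationary state distribution. Bound sojourns
    anchor the object to the nearest filament point (or to its current
    position when the field is empty); motile sojourns move it at the
    configured speed with a slowly diffusing heading and reflective
    boundary handling.

    Reference objects are placed at a subset of binding anchors chosen so
    that the realized fraction of object-frames within the association
    radius is as close as possible to ``ref_channel.coloc_fraction``
    (static mode). When ``coloc_profile`` is set, each bound interval is
    instead reference-associated with the per-frame probability of the
    profile at its start, and the reference object exists only for that
    interval (transient mode, time-varying colocalization).
    """
    if field is None:
        field = make_filament_field(config)
    h, w = config.field_size_px
    n_frames = config.n_frames
    rng = _rng(_STREAM_TRACKS, config.seed)
    dt = config.frame_interval_s
    speed = config.speed_px_per_s  # px / s
    jitter = config.localization_jitter_px
    heading_sd = config.heading_diffusion_rad * np.sqrt(dt)

    fil_pts = field.all_points()
    tree = cKDTree(fil_pts) if len(fil_pts) else None

    p_bound = config.bound_dwell_s / (config.bound_dwell_s + config.free_dwell_s)
    # Binding happens at discrete *sites*: filament points kept pairwise
    # separated by at least site_sep (covering both vesicle volume
    # exclusion and the association-radius flicker band, so that a bound
    # object is either firmly within a reference's radius or firmly
    # outside it). Objects returning near a known site reuse it; a site
    # hosts one object at a time.
    flick = max(1.5, 4.0 * config.localization_jitter_px)
    site_sep = max(config.binding_exclusion_px, config.ref_channel.radius_px + flick)
    sites: list[np.ndarray] = []
    site_intervals: list[list[tuple[float, float]]] = []  # absolute seconds

    xs = np.empty((config.n_objects, n_frames))
    ys = np.empty((config.n_objects, n_frames))
    bound = np.zeros((config.n_objects, n_frames), dtype=bool)
    # anchor run id per frame (-1 while motile), to delimit bound intervals
    anchor_run = np.full((config.n_objects, n_frames), -1, dtype=int)
    anchors: list[np.ndarray] = []  # per run id: anchor position

    def nearest_anchor(pos: np.ndarray, t0: float, t1: float) -> np.ndarray:
        """Binding site for an object at ``pos``: reuse a free nearby site
        or found a new one keeping the global site separation."""
        if tree is None:
            site = pos.copy()
            sites.append(site)
            site_intervals.append([(t0, t1)])
            return site.copy()

        def is_free(j: int) -> bool:
            return all(e <= t0 or s >= t1 for s, e in site_intervals[j])

        site_arr = np.asarray(sites) if sites else np.empty((0, 2))
        if len(site_arr):
            d_site = np.hypot(*(site_arr - pos).T)
            order = np.argsort(d_site)
            for j in order:
                if d_site[j] > site_sep:
                    break
                if is_free(j):  # nearby site, free over the whole sojourn
                    site_intervals[j].append((t0, t1))
                    return site_arr[j].copy()
        k = min(64, len(fil_pts))
        _, idx = tree.query(pos, k=k)
        idx = np.atleast_1d(idx)
        best = None
        best_clear = -np.inf
        for i in idx:
            cand = fil_pts[i]
            clear = (
                np.min(np.hypot(*(site_arr - cand).T)) if len(site_arr) else np.inf
            )
            if clear >= site_sep:
                best = cand
                break
            if clear > best_clear:
                best_clear, best = clear, cand
        site = np.asarray(best, dtype=float).copy()
        sites.append(site)
        site_intervals.append([(t0, t1)])
        return site.copy()

    def bind(pos: np.ndarray, t_abs: float) -> tuple[np.ndarray, float]:
        duration = rng.exponential(config.bound_dwell_s)
        anchor = nearest_anchor(pos, t_abs, t_abs + duration)
        return anchor, duration

    for obj in range(config.n_objects):
        pos = np.array([rng.uniform(0, w - 1), rng.uniform(0, h - 1)])
        is_bound = rng.random() < p_bound
        heading = rng.uniform(0, 2 * np.pi)
        run_id = -1
        if is_bound:
            anchor, remaining = bind(pos, 0.0)
            pos = anchor.copy()
            anchors.append(anchor.copy())
            run_id = len(anchors) - 1
        else:
            anchor = pos.copy()
            remaining = rng.exponential(config.free_dwell_s)

        for k in range(n_frames):
            if is_bound:
                jx = rng.normal(0.0, jitter) if jitter > 0 else 0.0
                jy = rng.normal(0.0, jitter) if jitter > 0 else 0.0
                xs[obj, k] = _reflect(anchor[0] + jx, 0.0, w - 1.0)
                ys[obj, k] = _reflect(anchor[1] + jy, 0.0, h - 1.0)
                bound[obj, k] = True
                anchor_run[obj, k] = run_id
            else:
                xs[obj, k] = pos[0]
                ys[obj, k] = pos[1]

            if k == n_frames - 1:
                break

            # advance one frame interval, handling mid-frame state switches
            if not is_bound:
                heading += rng.normal(0.0, heading_sd)
            t_left = dt
            while t_left > 1e-12:
                step_t = min(t_left, remaining)
                if not is_bound:
                    nx = pos[0] + speed * step_t * np.cos(heading)
                    ny = pos[1] + speed * step_t * np.sin(heading)
                    rx = _reflect(nx, 0.0, w - 1.0)
                    ry = _reflect(ny, 0.0, h - 1.0)
                    if rx != nx:
                        heading = np.pi - heading
                    if ry != ny:
                        heading = -heading
                    pos[0], pos[1] = rx, ry
                t_left -= step_t
                remaining -= step_t
                if remaining <= 1e-12:
                    t_abs = (k + 1) * dt - t_left
                    if is_bound:
                        is_bound = False
                        pos = anchor.copy()
                        heading = rng.uniform(0, 2 * np.pi)
                        remaining = rng.exponential(config.free_dwell_s)
                        run_id = -1
                    else:
                        is_bound = True
                        anchor, remaining = bind(pos, t_abs)
                        pos = anchor.copy()
                        anchors.append(anchor.copy())
                        run_id = len(anchors) - 1

    tracks = pd.DataFrame(
        {
            "object_id": np.repeat(np.arange(config.n_objects), n_frames),
            "frame": np.tile(np.arange(n_frames), config.n_objects),
            "x_px": xs.ravel(),
            "y_px": ys.ravel(),
            "state": np.where(bound.ravel(), "bound", "motile"),
        }
    )

    # -- bound intervals ---------------------------------------------------
    rows = []
    for obj in range(config.n_objects):
        for run, start, end in _runs_of(anchor_run[obj]):
            if run < 0:
                continue
            completed = start > 0 and end < n_frames - 1
            ax, ay = anchors[run]
            rows.append((obj, start, end, ax, ay, completed, run))
    bound_intervals = pd.DataFrame(
        rows,
        columns=[
            "object_id",
            "start_frame",
            "end_frame",
            "anchor_x",
            "anchor_y",
            "completed",
            "run_id",
        ],
    )

    ref_positions, ref_sites = _place_refs(config, bound_intervals, xs, ys, rng)
    association_intervals = _geometric_intervals(config, xs, ys, ref_positions)

    return GroundTruth(
        tracks=tracks,
        association_intervals=association_intervals,
        ref_positions=ref_positions,
        bound_intervals=bound_intervals.drop(columns=["run_id"]),
        config=config,
    )


def _place_refs(
    config: SimConfig,
    bound_intervals: pd.DataFrame,
    xs: np.ndarray,
    ys: np.ndarray,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Choose reference-object positions/lifetimes from the binding anchors."""
    h, w = config.field_size_px
    n_frames = config.n_frames
    radius = config.ref_channel.radius_px
    pos_all = np.stack([xs.ravel(), ys.ravel()], axis=1)  # (n_obj*T, 2)
    rows = []  # (ref_id, start_frame, end_frame, x, y) lifetimes
    sites = []

    if config.coloc_profile is not None:
        profile = np.asarray(config.coloc_profile, dtype=float)
        ref_id = 0
        for iv in bound_intervals.itertuples():
            if rng.random() < profile[iv.start_frame]:
                rows.append((ref_id, iv.start_frame, iv.end_frame, iv.anchor_x, iv.anchor_y))
                sites.append((iv.anchor_x, iv.anchor_y))
                ref_id += 1
    elif config.ref_channel.coloc_fraction > 0 and len(bound_intervals):
        target = config.ref_channel.coloc_fraction * len(pos_all)
        all_anchors = bound_intervals[["anchor_x", "anchor_y"]].to_numpy()
        uniq = np.unique(np.round(all_anchors, 6), axis=0)
        # a site is admissible only if no distinct anchor sits in the
        # annulus around the association radius, where bound-state jitter
        # would flicker in and out of range
        flick = max(1.5, 4.0 * config.localization_jitter_px)
        lo, hi = max(0.0, radius - flick), radius + flick
        sep = max(2.0 * radius, 3.0 * config.ref_channel.sigma_px)

        order = rng.permutation(len(bound_intervals))
        covered = np.zeros(len(pos_all), dtype=bool)
        selected: list[np.ndarray] = []
        n_covered_at: list[int] = [0]
        for i in order:
            a = all_anchors[i]
            d_anchor = np.hypot(*(uniq - a).T)
            in_annulus = (d_anchor > lo) & (d_anchor < hi)
            if in_annulus.any():
                continue
            if selected and np.min(np.hypot(*(np.asarray(selected) - a).T)) < sep:
                continue
            selected.append(a)
            d2 = np.sum((pos_all - a) ** 2, axis=1)
            covered |= d2 <= radius**2
            n_covered_at.append(int(covered.sum()))
        best_k = int(np.argmin(np.abs(np.asarray(n_covered_at) - target)))
        for ref_id, a in enumerate(selected[:best_k]):
            rows.append((ref_id, 0, n_frames - 1, a[0], a[1]))
            sites.append((a[0], a[1]))

    # decoy refs: uniform positions clear of selected sites and of every
    # binding anchor (they should only ever see brief motile passes)
    n_decoy = config.ref_channel.n_decoy_refs
    site_arr = np.asarray(sites) if sites else np.empty((0, 2))
    anchor_arr = bound_intervals[["anchor_x", "anchor_y"]].to_numpy()
    next_id = len(rows)
    for _ in range(n_decoy):
        for _attempt in range(100):
            p = np.array([rng.uniform(0, w - 1), rng.uniform(0, h - 1)])
            clear_sites = not len(site_arr) or np.min(np.hypot(*(site_arr - p).T)) > 2 * radius
            clear_anchors = not len(anchor_arr) or np.min(np.hypot(*(anchor_arr - p).T)) > radius + 2
            if clear_sites and clear_anchors:
                break
        rows.append((next_id, 0, n_frames - 1, p[0], p[1]))
        next_id += 1

    # expand lifetimes into per-frame positions, with optional slow drift
    drift_sd = config.ref_channel.drift_px_per_frame
    frames_list, ids_list, xs_list, ys_list = [], [], [], []
    for ref_id, start, end, x0, y0 in rows:
        nf = end - start + 1
        fx = np.full(nf, x0)
        fy = np.full(nf, y0)
        if drift_sd > 0:
            fx = fx + np.cumsum(rng.normal(0, drift_sd, nf))
            fy = fy + np.cumsum(rng.normal(0, drift_sd, nf))
            fx = np.array([_reflect(v, 0.0, w - 1.0) for v in fx])
            fy = np.array([_reflect(v, 0.0, h - 1.0) for v in fy])
        frames_list.append(np.arange(start, end + 1))
        ids_list.append(np.full(nf, ref_id, dtype=int))
        xs_list.append(fx)
        ys_list.append(fy)
    if frames_list:
        ref_positions = pd.DataFrame(
            {
                "frame": np.concatenate(frames_list),
                "ref_id": np.concatenate(ids_list),
                "x_px": np.concatenate(xs_list),
                "y_px": np.concatenate(ys_list),
            }
        ).sort_values(["frame", "ref_id"], ignore_index=True)
    else:
        ref_positions = pd.DataFrame(columns=["frame", "ref_id", "x_px", "y_px"])
    return ref_positions, site_arr


def _geometric_intervals(
    config: SimConfig, xs: np.ndarray, ys: np.ndarray, ref_positions: pd.DataFrame
) -> pd.DataFrame:
    """Maximal runs of frames with the nearest existing ref within radius."""
    cols = ["object_id", "ref_id", "start_frame", "end_frame"]
    if not len(ref_positions):
        return pd.DataFrame(columns=cols)
    n_frames = config.n_frames
    radius = config.ref_channel.radius_px
    ref_ids = np.sort(ref_positions.ref_id.unique())
    n_refs = len(ref_ids)
    id_index = {r: i for i, r in enumerate(ref_ids)}
    # (T, n_refs) position grids, NaN where the ref does not exist
    rx = np.full((n_frames, n_refs), np.nan)
    ry = np.full((n_frames, n_refs), np.nan)
    fi = ref_positions.frame.to_numpy()
    ci = ref_positions.ref_id.map(id_index).to_numpy()
    rx[fi, ci] = ref_positions.x_px.to_numpy()
    ry[fi, ci] = ref_positions.y_px.to_numpy()

    rows = []
    for obj in range(xs.shape[0]):
        dx = rx - xs[obj][:, None]
        dy = ry - ys[obj][:, None]
        d2 = dx * dx + dy * dy
        d2 = np.where(np.isnan(d2), np.inf, d2)
        nearest = np.argmin(d2, axis=1)
        within = d2[np.arange(n_frames), nearest] <= radius**2
        labels = np.where(within, nearest, -1)
        for val, start, end in _runs_of(labels):
            if val >= 0:
                rows.append((obj, int(ref_ids[val]), start, end))
    return pd.DataFrame(rows, columns=cols)


def _stamp_gaussian(
    frame: np.ndarray, x: float, y: float, amp: float, sigma: float
) -> None:
    """Add a 2-D Gaussian of peak ``amp`` at (x, y) in place."""
    h, w = frame.shape
    r = max(3, int(np.ceil(4 * sigma)))
    x0, x1 = max(0, int(np.floor(x)) - r), min(w, int(np.floor(x)) + r + 1)
    y0, y1 = max(0, int(np.floor(y)) - r), min(h, int(np.floor(y)) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    gx = np.exp(-((np.arange(x0, x1) - x) ** 2) / (2 * sigma**2))
    gy = np.exp(-((np.arange(y0, y1) - y) ** 2) / (2 * sigma**2))
    frame[y0:y1, x0:x1] += amp * np.outer(gy, gx)


def render_movie(truth: GroundTruth, config: Optional[SimConfig] = None) -> Movie:
    """Render the two-channel movie for a simulated ground truth.

    Channel 0 (``coat``) carries the tracked objects, channel 1 (``ref``)
    the reference structures. Per-object peak amplitudes vary by +/-15%
    around ``spot_amplitude`` (stable over time) so that intensity is
    informative for identity during linking. Signal plus background is
    scaled by exp(-t / bleach_tau_frames) before Poisson shot noise and
    additive Gaussian read noise are applied; bleaching the background
    along with the signal reflects autofluorescence fading with the dye
    and makes multiplicative intensity normalization its exact inverse.
    """
    if config is None:
        config = truth.config
    h, w = config.field_size_px
    n_frames = config.n_frames
    rng = _rng(_STREAM_RENDER, config.seed)

    amps = config.spot_amplitude * rng.uniform(0.85, 1.15, size=config.n_objects)

    tr = truth.tracks
    ox = tr.x_px.to_numpy().reshape(config.n_objects, n_frames)
    oy = tr.y_px.to_numpy().reshape(config.n_objects, n_frames)

    refs_by_frame: dict[int, np.ndarray] = {}
    if len(truth.ref_positions):
        for f, grp in truth.ref_positions.groupby("frame"):
            refs_by_frame[int(f)] = grp[["x_px", "y_px"]].to_numpy()

    data = np.empty((n_frames, 2, h, w))
    for t in range(n_frames):
        decay = np.exp(-t / config.bleach_tau_frames)
        coat = np.zeros((h, w))
        for obj in range(config.n_objects):
            _stamp_gaussian(coat, ox[obj, t], oy[obj, t], amps[obj], config.psf_sigma_px)
        ref = np.zeros((h, w))
        for rxy in refs_by_frame.get(t, ()):
            _stamp_gaussian(
                ref, rxy[0], rxy[1], config.ref_channel.amplitude, config.ref_channel.sigma_px
            )
        for c, img in enumerate((coat, ref)):
            lam = (img + config.background) * decay
            noisy = rng.poisson(lam).astype(float)
            if config.read_noise_sd > 0:
                noisy += rng.normal(0.0, config.read_noise_sd, size=lam.shape)
            data[t, c] = np.clip(noisy, 0, None)

    meta = MovieMetadata(
        pixel_size_nm=config.pixel_size_nm,
        frame_interval_ms=config.frame_interval_ms,
        n_frames=n_frames,
        channel_names=("coat", "ref"),
    )
    return Movie(data=data, meta=meta, extra={"seed": config.seed})


def simulate_movie(config: SimConfig) -> tuple[Movie, GroundTruth]:
    """Convenience: filament field -> ground truth -> rendered movie."""
    field = make_filament_field(config)
    truth = simulate_tracks(config, field)
    return render_movie(truth, config), truth


def write_simulation(config: SimConfig, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Simulate and write movie (TIFF + sidecar), ground truth CSVs, config.

    Returns the mapping of artifact names to paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    movie, truth = simulate_movie(config)
    paths = {
        "movie": out / "movie.tif",
        "truth_tracks": out / "truth_tracks.csv",
        "truth_associations": out / "truth_associations.csv",
        "truth_refs": out / "truth_ref_positions.csv",
        "config": out / "config.yaml",
    }
    movie.extra["config"] = config.to_dict()
    write_movie(movie, paths["movie"])
    truth.tracks.to_csv(paths["truth_tracks"], index=False)
    truth.association_intervals.to_csv(paths["truth_associations"], index=False)
    truth.ref_positions.to_csv(paths["truth_refs"], index=False)
    paths["config"].write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return paths
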