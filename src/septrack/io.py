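"""Movie container and file I/O.

Movies are multi-page TIFF stacks, dimension order T -> C -> Y -> X (one
page per frame/channel pair, frame-major), 16-bit unsigned on disk. A
sidecar key-value text file (YAML) carries the physical calibration that
TIFF pages do not: pixel size, frame interval, channel names and, for
simulated data, the full generator configuration and seed.

Tables (detections, tracks, events, metrics) are plain CSV with the column
schemas documented on the writer functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import InputError

__all__ = [
    "MovieMetadata",
    "Movie",
    "write_movie",
    "read_movie",
    "write_detections",
    "read_detections",
    "write_tracks",
    "read_tracks",
]

DETECTION_COLUMNS = ["frame", "x_px", "y_px", "intensity", "area_px"]
TRACK_COLUMNS = ["track_id", "frame", "x_px", "y_px", "intensity"]


@dataclass(frozen=True)
class MovieMetadata:
    """Physical calibration of an acquisition."""

    pixel_size_nm: float
    frame_interval_ms: float
    n_frames: int
    channel_names: tuple[str, ...] = ("ch0",)

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise InputError("pixel_size_nm must be > 0")
        if self.frame_interval_ms <= 0:
            raise InputError("frame_interval_ms must be > 0")

    @property
    def frame_interval_s(self) -> float:
        return self.frame_interval_ms / 1000.0


@dataclass
class Movie:
    """A time-ordered multi-channel intensity stack.

    ``data`` has shape (T, C, Y, X); all channels share frame count and
    shape by construction.
    """

    data: np.ndarray
    meta: MovieMetadata
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.data)
        if a.ndim == 3:  # single channel convenience
            a = a[:, None, :, :]
        if a.ndim != 4:
            raise InputError("movie data must have shape (T, C, Y, X)")
        if not np.all(np.isfinite(a)):
            raise InputError("movie intensities must be finite")
        self.data = a
        if a.shape[0] != self.meta.n_frames:
            raise InputError(
                f"frame count {a.shape[0]} disagrees with metadata "
                f"({self.meta.n_frames})"
            )
        if a.shape[1] != len(self.meta.channel_names):
            raise InputError("channel count disagrees with channel_names")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, which: Union[int, str]) -> np.ndarray:
        """Return one channel as a (T, Y, X) view."""
        if isinstance(which, str):
            try:
                which = self.meta.channel_names.index(which)
            except ValueError:
                raise InputError(
                    f"unknown channel {which!r}; have {self.meta.channel_names}"
                ) from None
        return self.data[:, which, :, :]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(tiff_path.suffix + ".meta.yaml")


def write_movie(movie: Movie, path: Union[str, Path]) -> Path:
    """Write a movie as multi-page uint16 TIFF plus a YAML sidecar.

    Pages are ordered frame-major: (t0,c0), (t0,c1), (t1,c0), ...
    Returns the sidecar path.
    """
    path = Path(path)
    t, c, h, w = movie.data.shape
    pages = np.clip(np.round(movie.data), 0, np.iinfo(np.uint16).max)
    pages = pages.reshape(t * c, h, w).astype(np.uint16)
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = _sidecar_path(path)
    payload = {
        "pixel_size_nm": float(movie.meta.pixel_size_nm),
        "frame_interval_ms": float(movie.meta.frame_interval_ms),
        "n_frames": int(t),
        "n_channels": int(c),
        "channel_names": list(movie.meta.channel_names),
    }
    payload.update(movie.extra)
    sidecar.write_text(yaml.safe_dump(payload, sort_keys=False))
    return sidecar


def read_movie(
    path: Union[str, Path],
    *,
    pixel_size_nm: Optional[float] = None,
    frame_interval_ms: Optional[float] = None,
    n_channels: Optional[int] = None,
    channel_names: Optional[Sequence[str]] = None,
) -> Movie:
    """Read a multi-page TIFF movie, using the sidecar when present.

    Explicit keyword arguments override sidecar values; a plain
    single-channel stack without sidecar needs ``pixel_size_nm`` and
    ``frame_interval_ms``.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    sidecar = _sidecar_path(path)
    info: dict = {}
    if sidecar.exists():
        info = yaml.safe_load(sidecar.read_text()) or {}
    px = pixel_size_nm if pixel_size_nm is not None else info.get("pixel_size_nm")
    dt = (
        frame_interval_ms
        if frame_interval_ms is not None
        else info.get("frame_interval_ms")
    )
    if px is None or dt is None:
        raise InputError(
            f"{path}: no sidecar metadata; pass pixel_size_nm and frame_interval_ms"
        )
    nc = n_channels if n_channels is not None else info.get("n_channels", 1)
    names = tuple(
        channel_names
        if channel_names is not None
        else info.get("channel_names", [f"ch{i}" for i in range(nc)])
    )
    if pages.shape[0] % nc != 0:
        raise InputError(f"{path}: page count {pages.shape[0]} not divisible by {nc} channels")
    t = pages.shape[0] // nc
    data = pages.reshape(t, nc, pages.shape[1], pages.shape[2])
    meta = MovieMetadata(
        pixel_size_nm=float(px),
        frame_interval_ms=float(dt),
        n_frames=t,
        channel_names=names,
    )
    extra = {
        k: v
        for k, v in info.items()
        if k
        not in {"pixel_size_nm", "frame_interval_ms", "n_frames", "n_channels", "channel_names"}
    }
    return Movie(data=data.astype(float), meta=meta, extra=extra)


def _write_table(df: pd.DataFrame, columns: list[str], path: Union[str, Path]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(f"table missing columns {missing}")
    df.loc[:, columns].to_csv(path, index=False)


def write_detections(detections: pd.DataFrame, path: Union[str, Path]) -> None:
    """CSV schema: frame, x_px, y_px, intensity, area_px."""
    _write_table(detections, DETECTION_COLUMNS, path)


def read_detections(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: detection CSV missing columns {missing}")
    return df


def write_tracks(tracks_df: pd.DataFrame, path: Union[str, Path]) -> None:
    """CSV schema: track_id, frame, x_px, y_px, intensity."""
    _write_table(tracks_df, TRACK_COLUMNS, path)


def read_tracks(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: track CSV missing columns {missing}")
    return df
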