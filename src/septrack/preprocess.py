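"""Photobleaching correction and à-trous wavelet spot detection.

Spot detection follows the standard isotropic undecimated (à-trous)
wavelet construction for fluorescence microscopy: the image is smoothed
repeatedly with the separable B3-spline kernel (1,4,6,4,1)/16, dilated by
inserting 2**(j-1) - 1 zeros between taps at scale j; detail planes are
differences of successive smooths and sum back to the input exactly.
Spots are connected components of pixels exceeding a robust (MAD-based)
per-plane threshold simultaneously on the selected detail scales, and are
localized to sub-pixel precision by the intensity-weighted centroid over
the background-subtracted image (background = the smooth residual plane).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import watershed

from .exceptions import ConfigurationError, DegenerateInputError
from .io import Movie

__all__ = [
    "bleach_correct",
    "atrous_decompose",
    "DetectParams",
    "detect_spots",
    "detect_movie",
]

_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def bleach_correct(
    movie: Movie, reference: str = "first_frame", statistic: str = "mean"
) -> Movie:
    """Photobleaching correction by multiplicative intensity normalization.

    Each frame of each channel is rescaled so its per-frame statistic
    (default: mean) equals the reference level of that channel — either
    the first frame's level or the median level across frames.

    Raises
    ------
    DegenerateInputError
        If any frame's statistic is not strictly positive (the frame index
        and channel are named).
    """
    if reference not in ("first_frame", "global_median"):
        raise ConfigurationError(f"unknown reference {reference!r}")
    if statistic not in ("mean", "median"):
        raise ConfigurationError(f"unknown statistic {statistic!r}")
    stat = np.mean if statistic == "mean" else np.median
    data = movie.data.astype(float).copy()
    for c in range(movie.n_channels):
        levels = np.array([stat(data[t, c]) for t in range(movie.n_frames)])
        bad = np.where(levels <= 0)[0]
        if len(bad):
            raise DegenerateInputError(
                f"frame {bad[0]} of channel {movie.meta.channel_names[c]!r} has "
                f"non-positive {statistic} intensity"
            )
        target = levels[0] if reference == "first_frame" else np.median(levels)
        data[:, c] *= (target / levels)[:, None, None]
    return Movie(data=data, meta=movie.meta, extra=dict(movie.extra))


def _scale_kernel(j: int) -> np.ndarray:
    """B3 kernel dilated for scale j (2**(j-1) - 1 zeros between taps)."""
    hole = 2 ** (j - 1) - 1
    k = np.zeros(4 * (hole + 1) + 1)
    k[:: hole + 1] = _B3
    return k


def atrous_decompose(
    image: np.ndarray, n_scales: int
) -> tuple[list[np.ndarray], np.ndarray]:
    """À-trous wavelet decomposition into detail planes plus smooth residual.

    Returns ``(details, residual)`` with ``sum(details) + residual``
    reconstructing the input exactly (up to float rounding). Boundary
    handling is mirror reflection.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ConfigurationError("atrous_decompose expects a 2-D image")
    if not np.all(np.isfinite(image)):
        raise ConfigurationError("image must be finite")
    if n_scales < 1:
        raise ConfigurationError("n_scales must be >= 1")
    c = image
    details = []
    for j in range(1, n_scales + 1):
        k = _scale_kernel(j)
        if len(k) > min(image.shape):
            raise ConfigurationError(
                f"scale {j} kernel ({len(k)} taps) exceeds image size {image.shape}"
            )
        s = ndimage.convolve1d(c, k, axis=0, mode="mirror")
        s = ndimage.convolve1d(s, k, axis=1, mode="mirror")
        details.append(c - s)
        c = s
    return details, c


def _plane_noise_sd(plane: np.ndarray) -> float:
    """Robust per-plane noise scale: 1.4826 * MAD about the median."""
    med = np.median(plane)
    return 1.4826 * float(np.median(np.abs(plane - med)))


@dataclass(frozen=True)
class DetectParams:
    """Spot-detection parameters.

    ``detection_scales`` are 1-based à-trous scales whose thresholded
    detail planes are intersected; ``k_mad`` is the threshold in robust
    noise-sd units; components smaller than ``min_area_px`` are dropped.
    """

    n_scales: int = 3
    detection_scales: tuple[int, ...] = (2, 3)
    k_mad: float = 3.0
    min_area_px: int = 2
    # multi-peak components are split by watershed at local maxima of the
    # band-passed image; secondary peaks closer than split_min_sep_px or
    # below split_rel_height of the component peak are not split out
    split_min_sep_px: float = 3.0
    split_rel_height: float = 0.25

    def __post_init__(self) -> None:
        if self.n_scales < 1:
            raise ConfigurationError("n_scales must be >= 1")
        if not self.detection_scales or any(
            s < 1 or s > self.n_scales for s in self.detection_scales
        ):
            raise ConfigurationError("detection_scales must lie in [1, n_scales]")
        if self.k_mad <= 0 or self.min_area_px < 1:
            raise ConfigurationError("k_mad must be > 0 and min_area_px >= 1")
        if self.split_min_sep_px <= 0 or not 0 < self.split_rel_height <= 1:
            raise ConfigurationError("invalid component-splitting parameters")


_EIGHT_CONN = np.ones((3, 3), dtype=bool)


def detect_spots(image: np.ndarray, params: DetectParams = DetectParams()) -> pd.DataFrame:
    """Detect diffraction-limited spots in one frame.

    Returns a DataFrame with columns x_px, y_px (sub-pixel centroid,
    0-based pixel-center convention, x = column), intensity (component sum
    of the background-subtracted image) and area_px. An empty image yields
    an empty table, not an error.
    """
    details, residual = atrous_decompose(image, params.n_scales)
    mask = np.ones(image.shape, dtype=bool)
    band = np.zeros(image.shape)
    for s in params.detection_scales:
        plane = details[s - 1]
        mask &= plane > params.k_mad * _plane_noise_sd(plane)
        band += plane
    labels, n = ndimage.label(mask, structure=_EIGHT_CONN)
    cols = ["x_px", "y_px", "intensity", "area_px"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    labels = _split_components(labels, band, params)
    bg_sub = np.clip(np.asarray(image, dtype=float) - residual, 0.0, None)
    rows = []
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        comp = labels[sl] == lab
        area = int(comp.sum())
        if area < params.min_area_px:
            continue
        wts = np.where(comp, bg_sub[sl], 0.0)
        total = wts.sum()
        if total <= 0:
            continue
        yy, xx = np.mgrid[sl[0].start : sl[0].stop, sl[1].start : sl[1].stop]
        rows.append(
            (
                float((wts * xx).sum() / total),
                float((wts * yy).sum() / total),
                float(total),
                area,
            )
        )
    return pd.DataFrame(rows, columns=cols)


def _split_components(labels: np.ndarray, band: np.ndarray, params: DetectParams) -> np.ndarray:
    """Split connected components containing several spot peaks.

    Overlapping spots stay above threshold between their peaks whenever the
    saddle exceeds the noise floor, so one component can hold two objects.
    Local maxima of the band-passed image seed a watershed within each such
    component; maxima closer than ``split_min_sep_px`` to a higher one, or
    below ``split_rel_height`` of the component peak, are absorbed.
    """
    is_max = (ndimage.maximum_filter(band, size=3) == band) & (labels > 0)
    ys, xs = np.nonzero(is_max)
    if len(ys) == 0:
        return labels
    out = labels.copy()
    next_label = int(labels.max()) + 1
    order = np.argsort(band[ys, xs])[::-1]
    comp_of = labels[ys, xs]
    for lab in np.unique(comp_of):
        sel = order[comp_of[order] == lab]
        if len(sel) < 2:
            continue
        peak_val = band[ys[sel[0]], xs[sel[0]]]
        kept: list[int] = []
        for i in sel:
            if band[ys[i], xs[i]] < params.split_rel_height * peak_val:
                continue
            if kept and np.min(
                np.hypot(ys[kept] - ys[i], xs[kept] - xs[i])
            ) < params.split_min_sep_px:
                continue
            kept.append(int(i))
        if len(kept) < 2:
            continue
        comp_mask = labels == lab
        markers = np.zeros(labels.shape, dtype=int)
        for j, i in enumerate(kept):
            markers[ys[i], xs[i]] = next_label + j
        ws = watershed(-band, markers=markers, mask=comp_mask)
        out[comp_mask] = ws[comp_mask]
        next_label += len(kept)
    return out


def detect_movie(
    movie: Movie,
    channel: int | str = 0,
    params: DetectParams = DetectParams(),
    frames: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Run :func:`detect_spots` on every frame of one channel.

    Returns the detection table (frame, x_px, y_px, intensity, area_px).
    """
    stack = movie.channel(channel)
    frames = range(movie.n_frames) if frames is None else frames
    parts = []
    for t in frames:
        det = detect_spots(stack[t], params)
        det.insert(0, "frame", int(t))
        parts.append(det)
    if not parts:
        return pd.DataFrame(columns=["frame", "x_px", "y_px", "intensity", "area_px"])
    return pd.concat(parts, ignore_index=True)
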