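"""Shared fixtures: small rendered scenes and one full control-movie analysis.

The expensive end-to-end artifacts (a 600-frame control movie with its
analysis) are session-scoped so detection, tracking and association tests
share a single simulation.
"""

from __future__ import annotations

import numpy as np
import pytest

import septrack as st
from septrack.pipeline import AnalysisParams, analyze_movie


def gaussian_frame(shape, spots, background=0.0, noise_sd=0.0, rng=None):
    """Render Gaussian spots (x, y, amplitude, sigma) onto one frame."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full(shape, float(background))
    for x, y, amp, sigma in spots:
        img += amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        img = img + rng.normal(0, noise_sd, shape)
    return img


@pytest.fixture(scope="session")
def control_run():
    """One 600-frame control movie, its ground truth and full analysis."""
    cfg = st.control_config(seed=2)
    movie, truth = st.simulate_movie(cfg)
    result = analyze_movie(
        movie,
        params=AnalysisParams(max_gap_frames=1),
        coat_channel="coat",
        ref_channel="ref",
    )
    result.truth = truth
    return cfg, movie, result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
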