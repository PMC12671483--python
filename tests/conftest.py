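"""Shared fixtures: synthetic movies and parameter sets reused across tests."""

import numpy as np
import pytest

from rushquant import clutch as cl
from rushquant import synth


@pytest.fixture(scope="session")
def default_params() -> cl.ClutchParams:
    return cl.ClutchParams()


@pytest.fixture(scope="session")
def fn_movie():
    """Default-geometry FN-mode two-channel movie with ground truth."""
    cfg = synth.MovieConfig(seed=11)
    return cfg, *synth.generate_timelapse(cfg)


@pytest.fixture(scope="session")
def collagen_movie():
    cfg = synth.MovieConfig(seed=11, condition="collagen")
    return cfg, *synth.generate_timelapse(cfg)


@pytest.fixture(scope="session")
def tirf_movie():
    """Default-noise TIRF flash movie, static cell outline."""
    cfg = synth.MovieConfig(seed=21, n_frames=30, protrusion_sectors=())
    return cfg, *synth.generate_tirf_movie(cfg)


def match_events(detected, truth, max_px: float = 3.0, max_frames: int = 1):
    """Greedy one-to-one matching of detected events to ground truth.

    Returns (n_matched, recall, precision). A pair matches when within
    max_px spatially and max_frames temporally.
    """
    truth_used = np.zeros(len(truth), dtype=bool)
    n_match = 0
    for det in detected.itertuples():
        best, best_d = None, np.inf
        for j, tr in enumerate(truth.itertuples()):
            if truth_used[j] or abs(det.frame - tr.frame) > max_frames:
                continue
            d = np.hypot(det.row - tr.row, det.col - tr.col)
            if d <= max_px and d < best_d:
                best, best_d = j, d
        if best is not None:
            truth_used[best] = True
            n_match += 1
    recall = n_match / len(truth) if len(truth) else np.nan
    precision = n_match / len(detected) if len(detected) else np.nan
    return n_match, recall, precision
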