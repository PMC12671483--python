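"""Scalar assay fixtures: per-cell flow-cytometry-style signal tables and
immunoblot band-intensity pairs with known truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ScalarFixtureSpec:
    """Log-normal per-cell signals per time point, plus band pairs.

    ``surface_location``/``total_location`` are the log-space locations of the
    surface-label and total signals at each time point (the delivery schedule
    lives in the gap between them); ``scale`` is the common log-space SD
    (0 gives the deterministic degenerate case). ``band_ratios`` are the true
    mature/immature ratios of the generated band pairs.
    """

    time_points: tuple[float, ...] = (0.0, 15.0, 30.0, 60.0)
    surface_location: tuple[float, ...] = (2.0, 2.3, 2.6, 3.0)
    total_location: tuple[float, ...] = (5.0, 5.0, 5.0, 5.0)
    scale: float = 0.3
    n_cells: int = 200
    band_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    band_lower: float = 1000.0

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        if not len(self.time_points) == len(self.surface_location) == len(self.total_location):
            raise ValueError("per-time-point fields must have equal length")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def generate_scalar_fixtures(
    spec: ScalarFixtureSpec, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the per-cell table and the band-pair table.

    Returns ``(cells, bands)``: cells has columns (cell_id, time_point,
    surface, total) with log-normal draws; bands has (lane, upper, lower,
    true_ratio) with upper = true_ratio * lower exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for tp, mu_s, mu_t in zip(spec.time_points, spec.surface_location, spec.total_location):
        if spec.scale == 0:
            surface = np.full(spec.n_cells, np.exp(mu_s))
            total = np.full(spec.n_cells, np.exp(mu_t))
        else:
            surface = rng.lognormal(mu_s, spec.scale, size=spec.n_cells)
            total = rng.lognormal(mu_t, spec.scale, size=spec.n_cells)
        for i in range(spec.n_cells):
            rows.append(
                {"cell_id": i, "time_point": tp, "surface": surface[i], "total": total[i]}
            )
    cells = pd.DataFrame(rows)
    bands = pd.DataFrame(
        {
            "lane": np.arange(len(spec.band_ratios)),
            "upper": [r * spec.band_lower for r in spec.band_ratios],
            "lower": spec.band_lower,
            "true_ratio": spec.band_ratios,
        }
    )
    return cells, bands
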