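"""Scalar assay metrics: flow-cytometry surface-delivery index and immunoblot
maturation ratio."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SurfaceDeliverySeries",
    "BandPair",
    "geometric_mean",
    "surface_delivery_index",
    "maturation_ratio",
]


def geometric_mean(samples) -> float:
    """Geometric mean computed in log space; requires strictly positive samples."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if np.any(x <= 0):
        raise ValueError("geometric mean undefined for nonpositive samples")
    return float(np.exp(np.mean(np.log(x))))


@dataclass
class SurfaceDeliverySeries:
    """Per-time-point surface/total geometric-mean ratios and the T0-subtracted index."""

    table: pd.DataFrame  # columns time_point, surface_geomean, total_geomean, ratio, index

    @property
    def index_values(self) -> np.ndarray:
        return self.table["index"].to_numpy()


def surface_delivery_index(
    surface_by_time: dict, total_by_time: dict, t0
) -> SurfaceDeliverySeries:
    """Surface-delivery index per time point.

    For each time point, the geometric mean of the surface-label signal is
    divided by the geometric mean of the total signal; the ratio at T0 is
    then subtracted from all time points, so the index is 0 at T0 and
    invariant under a common positive rescaling of all signals.
    """
    if set(surface_by_time) != set(total_by_time):
        raise ValueError("surface and total tables cover different time points")
    if t0 not in surface_by_time:
        raise ValueError(f"t0 = {t0!r} not among the time points")
    rows = []
    for tp in sorted(surface_by_time):
        gs = geometric_mean(surface_by_time[tp])
        gt = geometric_mean(total_by_time[tp])
        rows.append({"time_point": tp, "surface_geomean": gs, "total_geomean": gt,
                     "ratio": gs / gt})
    table = pd.DataFrame(rows)
    ref = float(table.loc[table["time_point"] == t0, "ratio"].iloc[0])
    table["index"] = table["ratio"] - ref
    return SurfaceDeliverySeries(table=table)


@dataclass(frozen=True)
class BandPair:
    """Immunoblot band pair: slower-migrating mature form over faster immature form."""

    upper: float  # mature band intensity
    lower: float  # immature band intensity

    def __post_init__(self) -> None:
        if self.upper < 0 or self.lower < 0:
            raise ValueError("band intensities must be >= 0")


def maturation_ratio(band: BandPair) -> float:
    """Mature/immature intensity ratio (upper band over lower band)."""
    if band.lower <= 0:
        raise ValueError("lower (immature) band intensity must be > 0")
    return band.upper / band.lower
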