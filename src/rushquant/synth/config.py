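"""Configuration and container types for the synthetic-data generators."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass(frozen=True)
class AdhesionSpec:
    """Geometry and kinetics of the synthetic focal adhesions.

    Adhesions are elongated structures near the cell edge, oriented radially.
    Each one nucleates at its distal tip (the end farther from the cell
    centroid) and extends inward toward the cell body at ``growth_rate``.
    """

    count: int = 8
    length_um: float = 3.0  # final long-axis length
    width_um: float = 1.0  # short-axis width
    nucleation_frames: tuple[int, ...] | None = None  # default: all at frame 0
    growth_rate_um_per_min: float = 0.3  # inward extension speed
    edge_margin_um: float = 1.0  # tip distance inside the cell edge
    peak_intensity: float = 600.0  # marker-channel amplitude above background


@dataclass(frozen=True)
class EventSpec:
    """Exocytosis flash events for the TIRF generator.

    ``fa_bias`` is the fraction of events placed within ``fa_radius_um`` of an
    adhesion pixel; the remainder are uniform over the cell mask. Flashes rise
    instantaneously and decay exponentially with time constant ``decay_frames``.
    """

    count: int = 50
    fa_bias: float = 0.5
    amplitude: float = 300.0
    decay_frames: float = 2.0
    fa_radius_um: float = 0.5
    sigma_px: float = 1.5


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: scaled-Poisson photon stage then additive Gaussian read noise."""

    photon_gain: float = 1.0  # intensity units per photon
    read_noise_sd: float = 2.0


@dataclass(frozen=True)
class MovieConfig:
    """Parameters of a synthetic two-channel trafficking movie or TIRF movie.

    The cargo channel follows the secretory schedule: ER texture before the
    release frame, a Golgi blob for ``golgi_residence`` minutes after release,
    then surface accumulation that is adhesion-targeted in ``FN`` mode and
    spatially uniform in ``collagen`` mode. ``protrusion_sectors`` are
    (start_deg, end_deg, speed_um_per_min) wedges whose cell-edge radius
    changes linearly in time (positive speed = protrusion).
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.1  # um/pixel
    frame_interval: float = 1.0  # min
    n_frames: int = 40
    condition: str = "FN"  # "FN" | "collagen"
    release_frame: int = 5
    golgi_residence: float = 15.0  # min
    protrusion_sectors: tuple[tuple[float, float, float], ...] = (
        (-40.0, 40.0, 0.1),
        (140.0, 180.0, -0.08),
    )
    adhesion_spec: AdhesionSpec = field(default_factory=AdhesionSpec)
    event_spec: EventSpec = field(default_factory=EventSpec)
    noise: NoiseModel = field(default_factory=NoiseModel)
    cell_radius_um: float = 8.0
    background: float = 100.0  # in-cell baseline intensity, both channels
    tirf_adhesion_intensity: float = 80.0  # static adhesion signal in TIRF movies
    protrusion_cargo_bias: float = 1.0  # extra surface cargo in protruding wedges
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0 <= self.release_frame < self.n_frames:
            raise ValueError("release_frame must lie in [0, n_frames)")
        if not 0.0 <= self.event_spec.fa_bias <= 1.0:
            raise ValueError("event_spec.fa_bias must lie in [0, 1]")
        if self.condition not in ("FN", "collagen"):
            raise ValueError("condition must be 'FN' or 'collagen'")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        for a0, a1, _speed in self.protrusion_sectors:
            if not (-180.0 <= a0 < a1 <= 180.0):
                raise ValueError("sector angles must satisfy -180 <= start < end <= 180")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MovieConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key, sub in (("adhesion_spec", AdhesionSpec), ("event_spec", EventSpec), ("noise", NoiseModel)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        for key in ("image_shape",):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "protrusion_sectors" in raw:
            raw["protrusion_sectors"] = tuple(tuple(s) for s in raw["protrusion_sectors"])
        if "nucleation_frames" in raw:
            raw["nucleation_frames"] = tuple(raw["nucleation_frames"])
        return cls(**raw)


@dataclass
class SyntheticMovie:
    """Rendered image stacks plus acquisition metadata."""

    channels: dict[str, np.ndarray]  # name -> (frames, rows, cols) uint16
    pixel_size: float
    frame_interval: float
    condition: str
    seed: int

    def save(self, out_dir) -> None:
        """Write one multi-page 16-bit TIFF per channel plus a metadata JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, stack in self.channels.items():
            tifffile.imwrite(out / f"{name}.tif", stack.astype(np.uint16))
        meta = {
            "pixel_size": self.pixel_size,
            "frame_interval": self.frame_interval,
            "condition": self.condition,
            "seed": self.seed,
            "channels": sorted(self.channels),
        }
        with open(out / "metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2)


@dataclass
class GroundTruth:
    """Truth records backing a synthetic movie.

    ``events`` has columns (frame, row, col, amplitude, fa_biased);
    ``adhesions`` one row per adhesion (label, t_appear_frame, lifetime_min,
    tip_row, tip_col); ``centroid_paths`` per (frame, label) centroids.
    Region masks for consecutive-frame intervals carry the protrusion truth.
    """

    cell_masks: np.ndarray  # (frames, rows, cols) bool
    adhesion_labels: np.ndarray | None = None  # (frames, rows, cols) int32
    adhesions: pd.DataFrame | None = None
    centroid_paths: pd.DataFrame | None = None
    events: pd.DataFrame | None = None
    protruding_masks: np.ndarray | None = None  # (frames-1, rows, cols) bool
    retracting_masks: np.ndarray | None = None
    cargo_schedule: pd.DataFrame | None = None

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(out / "cell_masks.tif", self.cell_masks.astype(np.uint8))
        if self.adhesion_labels is not None:
            tifffile.imwrite(out / "adhesion_labels.tif", self.adhesion_labels.astype(np.int32))
        for name in ("adhesions", "centroid_paths", "events", "cargo_schedule"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(out / f"{name}.csv", index=False)
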