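"""Renderers for the two-channel trafficking time-lapse and the TIRF flash movie."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .config import GroundTruth, MovieConfig, SyntheticMovie

# Surface-phase schedule constants (intensity above background, ramped in over
# _RAMP_MIN minutes after Golgi exit). FN mode targets adhesions with a
# distal-tip-first front; collagen mode accumulates uniformly on the membrane.
_ER_LEVEL = 150.0
_GOLGI_LEVEL = 400.0
_ADHESION_CARGO_LEVEL = 400.0
_MEMBRANE_CARGO_LEVEL = 150.0
_PROTRUSION_CARGO_LEVEL = 100.0
_RAMP_MIN = 10.0
_FRONT_SPREAD_MIN = 10.0  # minutes for the tip-to-center cargo front to traverse an adhesion


def _radius_map(theta_deg: np.ndarray, t_min: float, config: MovieConfig) -> np.ndarray:
    """Cell-edge radius (um) at each angle for time t (sector-wise linear motion)."""
    r = np.full_like(theta_deg, config.cell_radius_um, dtype=float)
    for a0, a1, speed in config.protrusion_sectors:
        sel = (theta_deg >= a0) & (theta_deg < a1)
        r[sel] = config.cell_radius_um + speed * t_min
    return np.maximum(r, 0.1)


def _grid(config: MovieConfig):
    h, w = config.image_shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    dy, dx = rows - cr, cols - cc
    dist_um = np.hypot(dy, dx) * config.pixel_size
    theta_deg = np.degrees(np.arctan2(dy, dx))
    return (cr, cc), dist_um, theta_deg


def cell_mask_at(config: MovieConfig, frame: int) -> np.ndarray:
    """Boolean cell mask at a frame, following the protrusion-sector schedule."""
    _, dist_um, theta_deg = _grid(config)
    t = frame * config.frame_interval
    return dist_um <= _radius_map(theta_deg, t, config)


def expected_cell_area_um2(config: MovieConfig, frame: int) -> float:
    """Analytic cell area at a frame: A = integral of r(theta)^2/2 dtheta."""
    t = frame * config.frame_interval
    r0 = config.cell_radius_um
    area = math.pi * r0**2
    for a0, a1, speed in config.protrusion_sectors:
        r = max(r0 + speed * t, 0.1)
        area += 0.5 * (r**2 - r0**2) * math.radians(a1 - a0)
    return area


def _sector_mask(config: MovieConfig, protruding_only: bool = True) -> np.ndarray:
    _, _, theta_deg = _grid(config)
    out = np.zeros(config.image_shape, dtype=bool)
    for a0, a1, speed in config.protrusion_sectors:
        if (speed > 0) == protruding_only:
            out |= (theta_deg >= a0) & (theta_deg < a1)
    return out


class _Adhesion:
    """One radially oriented adhesion nucleating at its distal tip."""

    def __init__(self, label, theta_deg, t_nucleate_frame, config: MovieConfig):
        self.label = label
        self.theta = math.radians(theta_deg)
        self.t0 = t_nucleate_frame
        spec = config.adhesion_spec
        t_min = t_nucleate_frame * config.frame_interval
        r_edge = config.cell_radius_um
        for a0, a1, speed in config.protrusion_sectors:
            if a0 <= theta_deg < a1:
                r_edge = max(r_edge + speed * t_min, 0.1)
        tip_dist = max(r_edge - spec.edge_margin_um, 0.5)
        (cr, cc) = ((config.image_shape[0] - 1) / 2.0, (config.image_shape[1] - 1) / 2.0)
        px = config.pixel_size
        self.tip = (
            cr + (tip_dist / px) * math.sin(self.theta),
            cc + (tip_dist / px) * math.cos(self.theta),
        )
        # inward unit vector (toward the centroid), pixel units
        self.inward = (-math.sin(self.theta), -math.cos(self.theta))
        self.config = config

    def length_um(self, frame: int) -> float:
        spec = self.config.adhesion_spec
        if frame < self.t0:
            return 0.0
        dt = (frame - self.t0) * self.config.frame_interval
        return min(spec.length_um, spec.width_um + spec.growth_rate_um_per_min * dt)

    def footprint(self, frame: int, shape) -> np.ndarray | None:
        """Elliptical footprint mask from the (fixed) distal tip inward."""
        L = self.length_um(frame)
        if L <= 0:
            return None
        spec = self.config.adhesion_spec
        px = self.config.pixel_size
        half_l, half_w = (L / 2.0) / px, (spec.width_um / 2.0) / px
        ctr = (self.tip[0] + self.inward[0] * half_l, self.tip[1] + self.inward[1] * half_l)
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        dl = (rows - ctr[0]) * self.inward[0] + (cols - ctr[1]) * self.inward[1]
        dw = -(rows - ctr[0]) * self.inward[1] + (cols - ctr[1]) * self.inward[0]
        return (dl / half_l) ** 2 + (dw / half_w) ** 2 <= 1.0

    def render(self, frame: int, image: np.ndarray) -> None:
        """Add an anisotropic Gaussian (sigma ratio 4:1, long axis radial)."""
        L = self.length_um(frame)
        if L <= 0:
            return
        spec = self.config.adhesion_spec
        px = self.config.pixel_size
        sigma_w = (spec.width_um / px) / 2.355  # FWHM = width
        sigma_l = max(4.0 * sigma_w, (L / px) / 2.355)
        half_l = (L / 2.0) / px
        ctr = (self.tip[0] + self.inward[0] * half_l, self.tip[1] + self.inward[1] * half_l)
        rows, cols = np.mgrid[0 : image.shape[0], 0 : image.shape[1]].astype(float)
        dl = (rows - ctr[0]) * self.inward[0] + (cols - ctr[1]) * self.inward[1]
        dw = -(rows - ctr[0]) * self.inward[1] + (cols - ctr[1]) * self.inward[0]
        image += spec.peak_intensity * np.exp(-0.5 * ((dl / sigma_l) ** 2 + (dw / sigma_w) ** 2))

    def tip_distance_px(self, shape) -> np.ndarray:
        """Along-axis distance (px) of every pixel from the distal tip."""
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        return (rows - self.tip[0]) * self.inward[0] + (cols - self.tip[1]) * self.inward[1]


def apply_camera_noise(signal: np.ndarray, noise, rng: np.random.Generator) -> np.ndarray:
    """Scaled-Poisson photon noise then Gaussian read noise; returns uint16."""
    g = noise.photon_gain
    photons = rng.poisson(np.maximum(signal, 0.0) / g)
    out = photons * g + rng.normal(0.0, noise.read_noise_sd, size=signal.shape)
    return np.clip(np.round(out), 0, 65535).astype(np.uint16)


def _make_adhesions(config: MovieConfig, rng: np.random.Generator) -> list[_Adhesion]:
    spec = config.adhesion_spec
    angles = np.linspace(-180.0, 180.0, spec.count, endpoint=False)
    angles = angles + rng.uniform(-5.0, 5.0, size=spec.count)
    angles = np.clip(angles, -180.0, 179.9)
    if spec.nucleation_frames is not None:
        if len(spec.nucleation_frames) != spec.count:
            raise ValueError("nucleation_frames length must equal adhesion count")
        nuc = list(spec.nucleation_frames)
    else:
        nuc = [0] * spec.count
    return [_Adhesion(i + 1, angles[i], nuc[i], config) for i in range(spec.count)]


def generate_timelapse(config: MovieConfig) -> tuple[SyntheticMovie, GroundTruth]:
    """Render the two-channel trafficking movie and its ground truth.

    Channel ``adhesion`` carries the adhesion-marker signal; channel ``cargo``
    follows the ER -> Golgi -> surface schedule, accumulating on adhesions in
    FN mode and uniformly on the membrane in collagen mode. Identical seeds
    give bit-identical stacks.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    n = config.n_frames
    (cr, cc), dist_um, theta_deg = _grid(config)

    adhesions = _make_adhesions(config, rng)
    # static ER texture (smoothed multiplicative noise) and Golgi center
    texture = ndi.gaussian_filter(rng.normal(1.0, 0.5, size=(h, w)), 3.0)
    texture = np.clip(texture, 0.2, None)
    golgi_ctr = (cr + rng.uniform(-5, 5), cc + rng.uniform(-5, 5))
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    golgi = np.exp(
        -0.5 * (((rows - golgi_ctr[0]) / (1.5 / config.pixel_size)) ** 2
                + ((cols - golgi_ctr[1]) / (1.5 / config.pixel_size)) ** 2)
    )
    # perinuclear ER stays clear of the edge-proximal adhesion band
    er_region = dist_um <= 0.45 * config.cell_radius_um
    protr_wedge = _sector_mask(config, protruding_only=True)

    ch_adh = np.zeros((n, h, w), dtype=np.uint16)
    ch_cargo = np.zeros((n, h, w), dtype=np.uint16)
    cell_masks = np.zeros((n, h, w), dtype=bool)
    labels = np.zeros((n, h, w), dtype=np.int32)
    sched_rows = []
    cpath_rows = []

    for f in range(n):
        t_min = f * config.frame_interval
        cmask = dist_um <= _radius_map(theta_deg, t_min, config)
        cell_masks[f] = cmask

        adh_img = np.zeros((h, w))
        for a in adhesions:
            fp = a.footprint(f, (h, w))
            if fp is None:
                continue
            fp &= cmask
            labels[f][fp] = a.label
            a.render(f, adh_img)
            if fp.any():
                rr, cc_ = np.nonzero(fp)
                cpath_rows.append({"frame": f, "label": a.label, "row": rr.mean(), "col": cc_.mean()})

        rel_t = (f - config.release_frame) * config.frame_interval
        er_level = _ER_LEVEL if f < config.release_frame else 0.0
        golgi_level = (
            _GOLGI_LEVEL if 0.0 <= rel_t < config.golgi_residence else 0.0
        )
        deliv = 0.0
        if rel_t >= config.golgi_residence:
            deliv = min(1.0, (rel_t - config.golgi_residence) / _RAMP_MIN)

        cargo = np.full((h, w), config.background) * cmask
        if er_level:
            cargo += er_level * texture * (er_region & cmask)
        if golgi_level:
            cargo += golgi_level * golgi * cmask
        adh_level = mem_level = prot_level = 0.0
        if deliv > 0:
            if config.condition == "FN":
                adh_level = _ADHESION_CARGO_LEVEL * deliv
                front_um = config.adhesion_spec.length_um * (
                    (rel_t - config.golgi_residence) / _FRONT_SPREAD_MIN
                )
                front_px = front_um / config.pixel_size
                for a in adhesions:
                    fp = a.footprint(f, (h, w))
                    if fp is None:
                        continue
                    covered = fp & cmask & (a.tip_distance_px((h, w)) <= front_px)
                    cargo[covered] += adh_level
            else:
                mem_level = _MEMBRANE_CARGO_LEVEL * deliv
                cargo[cmask] += mem_level
            prot_level = _PROTRUSION_CARGO_LEVEL * deliv * config.protrusion_cargo_bias
            if prot_level:
                cargo[cmask & protr_wedge] += prot_level
        sched_rows.append(
            {
                "frame": f,
                "phase": ("ER" if er_level else "Golgi" if golgi_level else
                          "surface" if deliv > 0 else "transit"),
                "er_level": er_level,
                "golgi_level": golgi_level,
                "adhesion_level": adh_level,
                "membrane_level": mem_level,
                "protrusion_level": prot_level,
            }
        )

        marker = (np.full((h, w), config.background) + adh_img) * cmask
        ch_adh[f] = apply_camera_noise(marker, config.noise, rng)
        ch_cargo[f] = apply_camera_noise(cargo, config.noise, rng)

    adh_rows = []
    for a in adhesions:
        present = [f for f in range(n) if (labels[f] == a.label).any()]
        if not present:
            continue
        adh_rows.append(
            {
                "label": a.label,
                "t_appear_frame": present[0],
                "lifetime_min": (present[-1] - present[0]) * config.frame_interval,
                "tip_row": a.tip[0],
                "tip_col": a.tip[1],
            }
        )
    protruding = np.zeros((n - 1, h, w), dtype=bool)
    retracting = np.zeros((n - 1, h, w), dtype=bool)
    for f in range(1, n):
        protruding[f - 1] = cell_masks[f] & ~cell_masks[f - 1]
        retracting[f - 1] = cell_masks[f - 1] & ~cell_masks[f]

    movie = SyntheticMovie(
        channels={"adhesion": ch_adh, "cargo": ch_cargo},
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
        condition=config.condition,
        seed=config.seed,
    )
    truth = GroundTruth(
        cell_masks=cell_masks,
        adhesion_labels=labels,
        adhesions=pd.DataFrame(adh_rows),
        centroid_paths=pd.DataFrame(cpath_rows),
        protruding_masks=protruding,
        retracting_masks=retracting,
        cargo_schedule=pd.DataFrame(sched_rows),
    )
    return movie, truth


def generate_tirf_movie(config: MovieConfig) -> tuple[SyntheticMovie, GroundTruth]:
    """Render a single-channel TIRF movie of instantaneous surface flashes.

    The cell outline and adhesion footprints are static (frame-0 geometry).
    A fraction ``fa_bias`` of events is placed within ``fa_radius_um`` of an
    adhesion pixel, the rest uniformly over the cell mask; each flash is a
    Gaussian spot decaying exponentially over subsequent frames.
    """
    spec = config.event_spec
    if not 0.0 <= spec.fa_bias <= 1.0:
        raise ValueError("fa_bias must lie in [0, 1]")
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    n = config.n_frames
    _, dist_um, theta_deg = _grid(config)
    cmask = dist_um <= _radius_map(theta_deg, 0.0, config)

    labels0 = np.zeros((h, w), dtype=np.int32)
    for a in _make_adhesions(config, rng):
        fp = a.footprint(n - 1, (h, w))
        if fp is not None:
            labels0[fp & cmask] = a.label
    fa_mask = labels0 > 0
    fa_pixels = np.transpose(np.nonzero(fa_mask))
    cell_pixels = np.transpose(np.nonzero(cmask))
    if cell_pixels.size == 0:
        raise ValueError("empty cell mask")

    radius_px = spec.fa_radius_um / config.pixel_size
    n_biased = int(round(spec.fa_bias * spec.count))
    ev_rows = []
    for k in range(spec.count):
        frame = int(rng.integers(1, max(2, n - 1)))
        if k < n_biased and fa_pixels.size:
            base = fa_pixels[rng.integers(len(fa_pixels))]
            for _ in range(100):
                ang = rng.uniform(0, 2 * math.pi)
                rad = radius_px * math.sqrt(rng.uniform())
                r = base[0] + rad * math.sin(ang)
                c = base[1] + rad * math.cos(ang)
                if 0 <= int(round(r)) < h and 0 <= int(round(c)) < w and cmask[int(round(r)), int(round(c))]:
                    break
            biased = True
        else:
            pick = cell_pixels[rng.integers(len(cell_pixels))]
            r = pick[0] + rng.uniform(-0.5, 0.5)
            c = pick[1] + rng.uniform(-0.5, 0.5)
            biased = False
        ev_rows.append(
            {"frame": frame, "row": float(r), "col": float(c),
             "amplitude": spec.amplitude, "fa_biased": biased}
        )
    events = pd.DataFrame(
        ev_rows, columns=["frame", "row", "col", "amplitude", "fa_biased"]
    ).sort_values("frame", ignore_index=True)

    stack = np.zeros((n, h, w))
    stack += np.where(cmask, config.background, 5.0)
    stack += config.tirf_adhesion_intensity * fa_mask  # static adhesion signal
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    horizon = max(1, int(round(5 * spec.decay_frames)))
    for rec in events.itertuples():
        spot = np.exp(
            -0.5 * (((rows - rec.row) / spec.sigma_px) ** 2 + ((cols - rec.col) / spec.sigma_px) ** 2)
        )
        for f in range(rec.frame, min(n, rec.frame + horizon + 1)):
            amp = rec.amplitude * math.exp(-(f - rec.frame) / spec.decay_frames)
            stack[f] += amp * spot

    out = np.empty((n, h, w), dtype=np.uint16)
    for f in range(n):
        out[f] = apply_camera_noise(stack[f], config.noise, rng)

    movie = SyntheticMovie(
        channels={"tirf": out},
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
        condition=config.condition,
        seed=config.seed,
    )
    truth = GroundTruth(
        cell_masks=np.broadcast_to(cmask, (n, h, w)).copy(),
        adhesion_labels=np.broadcast_to(labels0, (n, h, w)).copy(),
        events=events,
    )
    return movie, truth
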