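"""Micropattern scene generator: ligand-line / dual-line / dot geometries with
exact rasterized masks and a cargo image with a stated on-pattern enrichment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class PatternGeometry:
    """Micropattern geometry in micrometers, rasterized at ``pixel_size``."""

    line_width_um: float = 9.0
    period_um: float = 18.0
    second_width_um: float | None = None  # dual_lines: width of the second ligand
    dot_radius_um: float = 1.5
    dot_spacing_um: float = 6.0
    enrichment: float = 3.0  # on-pattern cargo multiplier
    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.1
    cell_radius_um: float = 10.0
    background: float = 100.0
    noise_sd: float = 2.0


@dataclass
class PatternScene:
    """Masks and cargo image for one micropattern scene."""

    cargo: np.ndarray
    pattern_mask: np.ndarray  # primary-ligand (FN) pixels
    second_mask: np.ndarray | None  # second ligand for dual_lines, else None
    cell_mask: np.ndarray
    geometry: PatternGeometry


def generate_micropattern_scene(
    kind: str, geometry: PatternGeometry, seed: int = 0
) -> PatternScene:
    """Rasterize a micropattern and render a cargo image enriched on it.

    ``lines``: vertical primary-ligand stripes of ``line_width_um`` repeating
    every ``period_um``. ``dual_lines``: the inter-stripe gaps carry a second
    ligand. ``dots``: a square grid of primary-ligand discs. The cargo image
    equals ``background`` inside the cell, multiplied by ``enrichment`` on
    pattern pixels, plus Gaussian noise.
    """
    g = geometry
    if g.pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    h, w = g.image_shape
    width_px = int(round(g.line_width_um / g.pixel_size))
    period_px = int(round(g.period_um / g.pixel_size))
    if kind in ("lines", "dual_lines"):
        if width_px < 1 or period_px < 1:
            raise ValueError("degenerate line geometry (zero width or period)")
        if width_px > period_px:
            raise ValueError("line width exceeds the period")
    cols = np.arange(w)
    rows_g, cols_g = np.mgrid[0:h, 0:w]

    second = None
    if kind == "lines":
        pattern = np.broadcast_to((cols % period_px) < width_px, (h, w)).copy()
    elif kind == "dual_lines":
        phase = cols % period_px
        pattern = np.broadcast_to(phase < width_px, (h, w)).copy()
        sw_px = (
            int(round(g.second_width_um / g.pixel_size))
            if g.second_width_um is not None
            else period_px - width_px
        )
        second = np.broadcast_to(
            (phase >= width_px) & (phase < width_px + sw_px), (h, w)
        ).copy()
    elif kind == "dots":
        rad_px = g.dot_radius_um / g.pixel_size
        spacing_px = g.dot_spacing_um / g.pixel_size
        if rad_px <= 0 or spacing_px <= 0:
            raise ValueError("degenerate dot geometry")
        pattern = np.zeros((h, w), dtype=bool)
        for cr in np.arange(spacing_px / 2, h, spacing_px):
            for cc in np.arange(spacing_px / 2, w, spacing_px):
                pattern |= (rows_g - cr) ** 2 + (cols_g - cc) ** 2 <= rad_px**2
    else:
        raise ValueError(f"unknown pattern kind {kind!r}")

    ctr = ((h - 1) / 2.0, (w - 1) / 2.0)
    cell = (
        np.hypot(rows_g - ctr[0], cols_g - ctr[1]) * g.pixel_size <= g.cell_radius_um
    )
    rng = np.random.default_rng(seed)
    cargo = np.where(cell, g.background, 0.0)
    cargo = np.where(pattern & cell, cargo * g.enrichment, cargo)
    cargo = np.clip(cargo + rng.normal(0.0, g.noise_sd, size=(h, w)), 0, None)
    return PatternScene(
        cargo=cargo, pattern_mask=pattern, second_mask=second, cell_mask=cell, geometry=g
    )
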