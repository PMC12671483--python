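"""Focal-adhesion segmentation, cargo-recruitment and tip-to-center profiling.

Adhesions are segmented from the marker channel by a global threshold (Otsu by
default), labeled with 8-connectivity and filtered by area (> 0.6 um^2 by
default, the conventional focal-adhesion size cut). Cargo recruitment is
always reported relative to the pre-release intensity in the same region, so
expression-level differences between cells cancel. Mature adhesions are
profiled by splitting their ROI into four equal-count areas ordered from the
distal tip (Area 1, pointing away from the cell body) to the proximal end
(Area 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu, gaussian
from skimage.measure import label as sk_label, regionprops

__all__ = [
    "SubdividedROI",
    "segment_adhesions",
    "cargo_intensity_in_adhesions",
    "relative_recruitment",
    "adhesion_area_sum",
    "subdivide_adhesion_roi",
    "tip_to_center_profile",
    "link_adhesion_tracks",
    "filter_adhesion_tracks",
]

_EIGHT = np.ones((3, 3), dtype=bool)


def segment_adhesions(
    marker_frame: np.ndarray,
    pixel_size: float,
    min_area_um2: float = 0.6,
    threshold_method: str = "otsu",
    smooth_sigma: float = 0.0,
    cell_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment adhesions in one marker frame.

    Returns the label mask and a table with one row per adhesion:
    label, area_um2, centroid_row, centroid_col, mean_marker_intensity and,
    when a cell mask is given, edge_distance_um (centroid to the nearest
    outside-cell pixel). Objects with area <= min_area_um2 are discarded
    (strict inequality retains only larger adhesions). A blank or constant
    frame yields an empty table, not an error.
    """
    img = np.asarray(marker_frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("marker_frame must be 2-D")
    if np.any(img < 0):
        raise ValueError("marker_frame must be nonnegative")
    if smooth_sigma > 0:
        img = gaussian(img, sigma=smooth_sigma, preserve_range=True)
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=np.int32), _empty_table()
    # threshold from in-cell intensities when a cell mask is given, so the
    # cell/outside contrast does not dominate the histogram
    pool = img[cell_mask.astype(bool)] if cell_mask is not None else img
    if pool.size == 0 or pool.max() == pool.min():
        return np.zeros(img.shape, dtype=np.int32), _empty_table()
    if threshold_method == "otsu":
        thr = threshold_otsu(pool)
    elif threshold_method == "mean":
        thr = pool.mean()
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    binary = img > thr
    if cell_mask is not None:
        binary &= cell_mask.astype(bool)
    labels = sk_label(binary, connectivity=2)  # 8-connected
    min_px = min_area_um2 / pixel_size**2
    edge_dist = None
    if cell_mask is not None:
        edge_dist = ndi.distance_transform_edt(cell_mask.astype(bool)) * pixel_size
    rows = []
    keep = np.zeros(labels.max() + 1, dtype=np.int32)
    next_label = 1
    for prop in regionprops(labels, intensity_image=img):
        if prop.area <= min_px:
            continue
        keep[prop.label] = next_label
        r, c = prop.centroid
        rows.append(
            {
                "label": next_label,
                "area_um2": prop.area * pixel_size**2,
                "centroid_row": r,
                "centroid_col": c,
                "mean_marker_intensity": prop.intensity_mean,
                "edge_distance_um": (
                    float(edge_dist[int(round(r)), int(round(c))]) if edge_dist is not None else np.nan
                ),
            }
        )
        next_label += 1
    return keep[labels], pd.DataFrame(rows) if rows else _empty_table()


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["label", "area_um2", "centroid_row", "centroid_col",
                 "mean_marker_intensity", "edge_distance_um"]
    )


def cargo_intensity_in_adhesions(
    cargo_frame: np.ndarray, label_mask: np.ndarray
) -> tuple[pd.DataFrame, float | None]:
    """Mean cargo intensity per adhesion label and over all adhesion pixels.

    The per-cell value is the mean over the union of adhesion pixels; it is
    None (flagged absent) when the mask holds no labels.
    """
    cargo = np.asarray(cargo_frame, dtype=float)
    if cargo.shape != label_mask.shape:
        raise ValueError("cargo frame and label mask shapes differ")
    labels = np.unique(label_mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        return pd.DataFrame(columns=["label", "mean_cargo_intensity"]), None
    means = ndi.mean(cargo, labels=label_mask, index=labels)
    per_label = pd.DataFrame({"label": labels, "mean_cargo_intensity": means})
    per_cell = float(cargo[label_mask > 0].mean())
    return per_label, per_cell


def relative_recruitment(series, t0_index: int = 0) -> np.ndarray:
    """Normalize an intensity series to its value at the reference index.

    The reference is typically the last pre-release time point, so the value
    there is exactly 1 and later values are fold recruitment.
    """
    values = np.asarray(series, dtype=float)
    ref = values[t0_index]
    if not ref > 0:
        raise ValueError(f"reference value at index {t0_index} must be > 0, got {ref}")
    return values / ref


def adhesion_area_sum(table: pd.DataFrame, t0_frame: int, frame_col: str = "frame") -> pd.Series:
    """Per-frame total adhesion area relative to the total at the t0 frame."""
    sums = table.groupby(frame_col)["area_um2"].sum()
    if t0_frame not in sums.index:
        raise ValueError(f"no adhesions recorded at t0 frame {t0_frame}")
    ref = sums.loc[t0_frame]
    if not ref > 0:
        raise ValueError("adhesion area at t0 is zero")
    return sums / ref


@dataclass
class SubdividedROI:
    """Four equal-count sub-areas of an adhesion ROI, distal (1) to proximal (4)."""

    masks: list[np.ndarray]  # four boolean masks, disjoint, covering the ROI
    axis: np.ndarray  # unit vector tip -> proximal (row, col)
    tip: tuple[int, int]

    @property
    def pixel_counts(self) -> list[int]:
        return [int(m.sum()) for m in self.masks]


def subdivide_adhesion_roi(roi_mask: np.ndarray, distal_tip: tuple[int, int]) -> SubdividedROI:
    """Split a connected ROI into 4 contiguous equal-count areas along its axis.

    Pixels are ranked by their projection onto the ROI major axis oriented
    from the distal tip toward the proximal end and split at the 25/50/75
    rank quantiles; counts differ by at most 1 and Area 1 contains the tip.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px < 4:
        raise ValueError("ROI must contain at least 4 pixels")
    tr, tc = int(distal_tip[0]), int(distal_tip[1])
    if not mask[tr, tc]:
        raise ValueError("distal tip pixel must lie inside the ROI")
    coords = np.transpose(np.nonzero(mask)).astype(float)
    centered = coords - coords.mean(axis=0)
    # principal axis of the pixel cloud
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, np.argmax(eigvals)]
    proj = coords @ axis
    tip_proj = np.array([tr, tc], dtype=float) @ axis
    if tip_proj > proj.mean():  # orient so the tip sits at the low end
        axis = -axis
        proj = -proj
    order = np.argsort(proj, kind="stable")
    bounds = [round(k * n_px / 4) for k in range(5)]
    masks = []
    for k in range(4):
        m = np.zeros_like(mask)
        sel = coords[order[bounds[k] : bounds[k + 1]]].astype(int)
        m[sel[:, 0], sel[:, 1]] = True
        masks.append(m)
    if not masks[0][tr, tc]:
        # tie ordering put the tip just past the first split; swap it in
        for k in range(1, 4):
            if masks[k][tr, tc]:
                masks[k][tr, tc] = False
                masks[0][tr, tc] = True
                donor = np.transpose(np.nonzero(masks[0]))
                far = donor[np.argmax(donor @ axis)]
                masks[0][far[0], far[1]] = False
                masks[k][far[0], far[1]] = True
                break
    return SubdividedROI(masks=masks, axis=axis, tip=(tr, tc))


def tip_to_center_profile(
    cargo_stack: np.ndarray,
    subdivision: SubdividedROI,
    t_appear_frame: int,
    frame_interval: float,
    baseline_offset_min: float = 2.5,
) -> pd.DataFrame:
    """Per-area cargo intensity relative to baseline before cargo appearance.

    Baseline is each area's mean intensity ``baseline_offset_min`` minutes
    before the appearance frame. Areas with nonpositive baseline are flagged
    (NaN series, ``valid`` False) rather than divided.
    """
    offset = int(round(baseline_offset_min / frame_interval))
    base_frame = t_appear_frame - offset
    if base_frame < 0:
        raise ValueError(
            f"baseline frame {base_frame} precedes movie start "
            f"(appearance frame {t_appear_frame}, offset {offset} frames)"
        )
    n_frames = cargo_stack.shape[0]
    out = {}
    for i, m in enumerate(subdivision.masks, start=1):
        series = np.array([cargo_stack[f][m].mean() for f in range(n_frames)], dtype=float)
        base = series[base_frame]
        if base > 0:
            out[f"area{i}"] = series / base
        else:
            out[f"area{i}"] = np.full(n_frames, np.nan)
    df = pd.DataFrame(out)
    df.insert(0, "frame", np.arange(n_frames))
    df.insert(1, "time_min", (df["frame"] - t_appear_frame) * frame_interval)
    return df


def detect_cargo_appearance(
    cargo_stack: np.ndarray,
    roi_mask: np.ndarray,
    release_frame: int,
    threshold_multiple: float = 1.5,
) -> int | None:
    """First frame where the ROI cargo mean exceeds a multiple of the
    pre-release ROI mean, or None if it never does."""
    means = np.array([cargo_stack[f][roi_mask].mean() for f in range(cargo_stack.shape[0])])
    pre = means[:release_frame].mean() if release_frame > 0 else means[0]
    if not pre > 0:
        raise ValueError("pre-release ROI mean must be > 0")
    hits = np.nonzero(means > threshold_multiple * pre)[0]
    hits = hits[hits >= release_frame]
    return int(hits[0]) if hits.size else None


def link_adhesion_tracks(
    tables: list[pd.DataFrame],
    frame_interval: float,
    max_displacement_um: float = 1.0,
    pixel_size: float = 0.1,
) -> pd.DataFrame:
    """Greedy nearest-centroid frame-to-frame linking of per-frame adhesion tables.

    Returns one row per track: track_id, t_appear_frame, last_frame,
    lifetime_min, mean edge_distance_um, and the per-frame label links as a
    list column. The displacement gate is in micrometers.
    """
    gate_px = max_displacement_um / pixel_size
    tracks: list[dict] = []
    active: dict[int, dict] = {}
    for f, tab in enumerate(tables):
        cents = tab[["centroid_row", "centroid_col"]].to_numpy(dtype=float) if len(tab) else np.empty((0, 2))
        labels = tab["label"].to_numpy() if len(tab) else np.array([], dtype=int)
        edges = tab["edge_distance_um"].to_numpy(dtype=float) if len(tab) else np.array([])
        used = np.zeros(len(tab), dtype=bool)
        new_active: dict[int, dict] = {}
        for tid, tr in active.items():
            if len(tab):
                d = np.hypot(*(cents - tr["centroid"]).T)
                d[used] = np.inf
                j = int(np.argmin(d))
                if d[j] <= gate_px:
                    used[j] = True
                    tr["centroid"] = cents[j]
                    tr["last_frame"] = f
                    tr["links"].append((f, int(labels[j])))
                    tr["edge_sum"] += edges[j]
                    tr["n_obs"] += 1
                    new_active[tid] = tr
                    continue
            tracks.append(tr)
        for j in range(len(tab)):
            if not used[j]:
                tid = len(tracks) + len(new_active)
                new_active[tid] = {
                    "track_id": tid,
                    "t_appear_frame": f,
                    "last_frame": f,
                    "centroid": cents[j],
                    "links": [(f, int(labels[j]))],
                    "edge_sum": float(edges[j]) if edges.size else np.nan,
                    "n_obs": 1,
                }
        active = new_active
    tracks.extend(active.values())
    rows = [
        {
            "track_id": tr["track_id"],
            "t_appear_frame": tr["t_appear_frame"],
            "last_frame": tr["last_frame"],
            "lifetime_min": (tr["last_frame"] - tr["t_appear_frame"]) * frame_interval,
            "edge_distance_um": tr["edge_sum"] / tr["n_obs"],
            "links": tr["links"],
        }
        for tr in tracks
    ]
    return pd.DataFrame(rows)


def filter_adhesion_tracks(
    tracks: pd.DataFrame,
    min_lifetime_min: float = 15.0,
    max_edge_distance_um: float = 2.0,
) -> pd.DataFrame:
    """Keep edge-proximal, long-lived tracks.

    Retains tracks with lifetime >= min_lifetime_min (a track lasting exactly
    the minimum is kept) and edge distance <= max_edge_distance_um.
    """
    sel = (tracks["lifetime_min"] >= min_lifetime_min) & (
        tracks["edge_distance_um"] <= max_edge_distance_um
    )
    return tracks[sel].reset_index(drop=True)
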