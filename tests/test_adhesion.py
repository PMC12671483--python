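"""Tests for adhesion segmentation, recruitment and tip-to-center profiling."""

from collections import deque

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rushquant import adhesion as adh
from rushquant import synth


def flood_fill_count(binary: np.ndarray, min_px: float) -> int:
    """Independent 8-connected component counter (BFS flood fill)."""
    seen = np.zeros_like(binary, dtype=bool)
    count = 0
    h, w = binary.shape
    for sr in range(h):
        for sc in range(w):
            if binary[sr, sc] and not seen[sr, sc]:
                size = 0
                q = deque([(sr, sc)])
                seen[sr, sc] = True
                while q:
                    r, c = q.popleft()
                    size += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                q.append((rr, cc))
                if size > min_px:
                    count += 1
    return count


def blob_image(areas_px, shape=(120, 200), value=1000.0):
    """Rectangular blobs of the given pixel areas on a zero background."""
    img = np.zeros(shape)
    col = 5
    for a in areas_px:
        wdt = int(np.ceil(np.sqrt(a)))
        hgt = int(np.ceil(a / wdt))
        block = np.zeros(wdt * hgt)
        block[:a] = value
        img[5 : 5 + hgt, col : col + wdt] = block.reshape(hgt, wdt)
        col += wdt + 8
    return img


class TestSegmentation:
    def test_area_filter_keeps_only_large_blob(self):
        # 50 px and 70 px at 0.1 um/px -> 0.50 and 0.70 um^2; only 0.70 kept
        img = blob_image([50, 70])
        labels, tab = adh.segment_adhesions(img, pixel_size=0.1)
        assert len(tab) == 1
        assert tab["area_um2"].iloc[0] == pytest.approx(0.70)
        assert labels.max() == 1

    def test_blank_image_yields_empty_table(self):
        labels, tab = adh.segment_adhesions(np.zeros((32, 32)), pixel_size=0.1)
        assert len(tab) == 0 and labels.max() == 0

    def test_count_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(4)
        img = np.zeros((100, 100))
        for _ in range(12):
            r, c = rng.integers(5, 90, size=2)
            img[r : r + rng.integers(2, 12), c : c + rng.integers(2, 12)] = 500.0
        min_px = 0.6 / 0.1**2
        labels, tab = adh.segment_adhesions(img, pixel_size=0.1)
        binary = img > (img.max() + img.min()) / 2 * 0  # oracle thresholds at >0
        binary = img > 0
        assert len(tab) == flood_fill_count(binary, min_px)

    def test_idempotent_on_binary_output(self):
        img = blob_image([80, 120])
        labels, _ = adh.segment_adhesions(img, pixel_size=0.1)
        relabels, retab = adh.segment_adhesions((labels > 0).astype(float) * 100, pixel_size=0.1)
        assert np.array_equal(relabels > 0, labels > 0)

    def test_fn_recruitment_exceeds_collagen(self, fn_movie, collagen_movie):
        cfg, fn_m, fn_t = fn_movie
        _, col_m, col_t = collagen_movie
        f = cfg.n_frames - 1  # late post-release frame
        _, fn_mean = adh.cargo_intensity_in_adhesions(
            fn_m.channels["cargo"][f].astype(float), fn_t.adhesion_labels[f]
        )
        _, col_mean = adh.cargo_intensity_in_adhesions(
            col_m.channels["cargo"][f].astype(float), col_t.adhesion_labels[f]
        )
        assert fn_mean > col_mean


class TestCargoIntensity:
    def test_uniform_cargo_uniform_means(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[2:4, 2:4] = 1
        labels[6:9, 6:9] = 2
        per_label, per_cell = adh.cargo_intensity_in_adhesions(np.full((10, 10), 7.0), labels)
        assert np.all(per_label["mean_cargo_intensity"] == 7.0)
        assert per_cell == 7.0

    def test_two_pixel_mean(self):
        cargo = np.zeros((2, 2))
        cargo[0, 0], cargo[0, 1] = 3.0, 5.0
        labels = np.zeros((2, 2), dtype=int)
        labels[0, :] = 1
        per_label, _ = adh.cargo_intensity_in_adhesions(cargo, labels)
        assert per_label["mean_cargo_intensity"].iloc[0] == 4.0

    def test_no_labels_flagged_absent(self):
        per_label, per_cell = adh.cargo_intensity_in_adhesions(
            np.ones((5, 5)), np.zeros((5, 5), dtype=int)
        )
        assert per_cell is None and len(per_label) == 0

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_matches_pixel_list_average(self, seed):
        rng = np.random.default_rng(seed)
        cargo = rng.uniform(0, 100, size=(20, 20))
        labels = rng.integers(0, 4, size=(20, 20))
        per_label, per_cell = adh.cargo_intensity_in_adhesions(cargo, labels)
        for rec in per_label.itertuples():
            assert rec.mean_cargo_intensity == pytest.approx(
                cargo[labels == rec.label].mean()
            )
        assert per_cell == pytest.approx(cargo[labels > 0].mean())


class TestRelativeSeries:
    def test_normalization(self):
        assert np.allclose(adh.relative_recruitment([10, 15, 20], 0), [1.0, 1.5, 2.0])

    def test_constant_series(self):
        assert np.all(adh.relative_recruitment([4, 4, 4], 0) == 1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            adh.relative_recruitment([0.0, 1.0], 0)

    def test_area_sum_relative(self):
        table = pd.DataFrame(
            {"frame": [0, 0, 1, 1], "area_um2": [1.0, 2.5, 3.0, 4.0]}
        )
        rel = adh.adhesion_area_sum(table, t0_frame=0)
        assert rel.loc[0] == 1.0
        assert rel.loc[1] == pytest.approx(7.0 / 3.5)

    def test_area_sum_matches_pixel_count_oracle(self, fn_movie):
        cfg, _movie, truth = fn_movie
        rows = []
        for f in (0, cfg.n_frames - 1):
            for lbl in np.unique(truth.adhesion_labels[f]):
                if lbl:
                    rows.append(
                        {"frame": f, "area_um2": (truth.adhesion_labels[f] == lbl).sum()
                         * cfg.pixel_size**2}
                    )
        table = pd.DataFrame(rows)
        rel = adh.adhesion_area_sum(table, t0_frame=0)
        px0 = (truth.adhesion_labels[0] > 0).sum()
        px1 = (truth.adhesion_labels[cfg.n_frames - 1] > 0).sum()
        assert rel.loc[cfg.n_frames - 1] == pytest.approx(px1 / px0)


class TestSubdivision:
    def test_rectangle_splits_into_equal_blocks(self):
        mask = np.zeros((60, 20), dtype=bool)
        mask[10:50, 6:14] = True  # 40 x 8 rectangle
        sub = adh.subdivide_adhesion_roi(mask, distal_tip=(10, 9))
        assert sub.pixel_counts == [80, 80, 80, 80]
        # each area is a contiguous 10-row x 8-col block
        for k, m in enumerate(sub.masks):
            rr, cc = np.nonzero(m)
            assert rr.min() == 10 + 10 * k and rr.max() == 19 + 10 * k
        assert sub.masks[0][10, 9]

    def test_counts_within_one_and_cover_roi(self):
        rng = np.random.default_rng(8)
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:30, 10:13] = True
        extra = rng.integers(5, 30, size=(10, 2))
        mask[extra[:, 0], 12] = True
        tip = (5, 11)
        sub = adh.subdivide_adhesion_roi(mask, tip)
        counts = sub.pixel_counts
        assert max(counts) - min(counts) <= 1
        union = np.zeros_like(mask)
        for m in sub.masks:
            assert not (union & m).any()
            union |= m
        assert np.array_equal(union, mask)

    def test_area1_contains_generator_tip(self, fn_movie):
        cfg, _movie, truth = fn_movie
        f = cfg.n_frames - 1
        rec = truth.adhesions.iloc[0]
        roi = truth.adhesion_labels[f] == rec["label"]
        tip = (int(round(rec["tip_row"])), int(round(rec["tip_col"])))
        if not roi[tip]:  # snap to the nearest ROI pixel
            rr, cc = np.nonzero(roi)
            j = np.argmin(np.hypot(rr - tip[0], cc - tip[1]))
            tip = (rr[j], cc[j])
        sub = adh.subdivide_adhesion_roi(roi, tip)
        assert sub.masks[0][tip]

    def test_small_roi_rejected(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2:4] = True
        with pytest.raises(ValueError):
            adh.subdivide_adhesion_roi(mask, (2, 2))

    def test_tip_outside_roi_rejected(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 1:4] = True
        with pytest.raises(ValueError):
            adh.subdivide_adhesion_roi(mask, (0, 0))


class TestTipToCenterProfile:
    def test_constant_cargo_all_ones(self):
        stack = np.full((6, 20, 20), 50.0)
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 8:12] = True
        sub = adh.subdivide_adhesion_roi(mask, (5, 9))
        prof = adh.tip_to_center_profile(stack, sub, t_appear_frame=3, frame_interval=1.0,
                                         baseline_offset_min=2.0)
        for k in range(1, 5):
            assert np.allclose(prof[f"area{k}"], 1.0)

    def test_distal_area_rises_before_proximal(self, fn_movie):
        """Generator delivers cargo tip-first: Area 1 crosses 1.5x before Area 4."""
        cfg, movie, truth = fn_movie
        f_last = cfg.n_frames - 1
        rec = truth.adhesions.iloc[0]
        roi = truth.adhesion_labels[f_last] == rec["label"]
        rr, cc = np.nonzero(roi)
        tip = (int(round(rec["tip_row"])), int(round(rec["tip_col"])))
        if not roi[tip]:
            j = np.argmin(np.hypot(rr - tip[0], cc - tip[1]))
            tip = (rr[j], cc[j])
        sub = adh.subdivide_adhesion_roi(roi, tip)
        cargo = movie.channels["cargo"].astype(float)
        appear = adh.detect_cargo_appearance(cargo, roi, cfg.release_frame)
        assert appear is not None
        prof = adh.tip_to_center_profile(
            cargo, sub, appear, cfg.frame_interval, baseline_offset_min=2.5
        )
        def first_crossing(col):
            vals = prof[col].to_numpy()
            hits = np.nonzero(vals[appear:] >= 1.5)[0]  # post-appearance rise only
            return appear + hits[0] if hits.size else np.inf
        assert first_crossing("area1") < first_crossing("area4")

    def test_baseline_before_start_rejected(self):
        stack = np.full((4, 10, 10), 5.0)
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 4:6] = True
        sub = adh.subdivide_adhesion_roi(mask, (2, 4))
        with pytest.raises(ValueError):
            adh.tip_to_center_profile(stack, sub, t_appear_frame=1, frame_interval=1.0,
                                      baseline_offset_min=5.0)

    def test_zero_baseline_flagged_not_divided(self):
        stack = np.zeros((4, 10, 10))
        stack[2:] = 10.0
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 4:6] = True
        sub = adh.subdivide_adhesion_roi(mask, (2, 4))
        prof = adh.tip_to_center_profile(stack, sub, t_appear_frame=2, frame_interval=1.0,
                                         baseline_offset_min=2.0)
        assert prof["area1"].isna().all()


class TestTrackFilter:
    @staticmethod
    def _tracks():
        return pd.DataFrame(
            {
                "track_id": [0, 1, 2, 3],
                "lifetime_min": [10.0, 15.0, 30.0, 40.0],
                "edge_distance_um": [1.0, 1.5, 3.0, 0.5],
            }
        )

    def test_short_lifetime_removed(self):
        out = adh.filter_adhesion_tracks(self._tracks())
        assert 0 not in out["track_id"].values

    def test_boundary_lifetime_retained(self):
        out = adh.filter_adhesion_tracks(self._tracks())
        assert 1 in out["track_id"].values

    def test_far_from_edge_removed(self):
        out = adh.filter_adhesion_tracks(self._tracks())
        assert 2 not in out["track_id"].values

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 9999))
    def test_matches_row_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tracks = pd.DataFrame(
            {
                "track_id": np.arange(20),
                "lifetime_min": rng.uniform(0, 40, 20),
                "edge_distance_um": rng.uniform(0, 5, 20),
            }
        )
        out = adh.filter_adhesion_tracks(tracks, 15.0, 2.0)
        expected = sum(
            1 for _, row in tracks.iterrows()
            if row.lifetime_min >= 15.0 and row.edge_distance_um <= 2.0
        )
        assert len(out) == expected


class TestTrackLinking:
    def test_links_stationary_objects_across_frames(self, fn_movie):
        cfg, _movie, truth = fn_movie
        tables = []
        for f in range(cfg.n_frames):
            rows = []
            for lbl in np.unique(truth.adhesion_labels[f]):
                if lbl:
                    rr, cc = np.nonzero(truth.adhesion_labels[f] == lbl)
                    rows.append({"label": lbl, "centroid_row": rr.mean(),
                                 "centroid_col": cc.mean(), "edge_distance_um": 1.0})
            tables.append(pd.DataFrame(rows))
        tracks = adh.link_adhesion_tracks(tables, cfg.frame_interval,
                                          max_displacement_um=2.0, pixel_size=cfg.pixel_size)
        assert len(tracks) == cfg.adhesion_spec.count
        assert (tracks["lifetime_min"] == (cfg.n_frames - 1) * cfg.frame_interval).all()
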