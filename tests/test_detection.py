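"""Detection contracts: median background, strict thresholding, area filter."""

from dataclasses import replace

import numpy as np
import pytest

from deformcyte.detection import (CellRegion, binarize, detect_regions,
                                  detect_sequence, estimate_background)
from deformcyte.synthetic import FrameSequence

from conftest import make_mask


def _seq(frames):
    return FrameSequence(frames=np.asarray(frames, dtype=np.uint8),
                         donor_id="t")


def flood_fill_components(mask, connectivity):
    """Brute-force connected components by BFS (oracle)."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    H, W = mask.shape
    for r in range(H):
        for c in range(W):
            if mask[r, c] and not seen[r, c]:
                queue = [(r, c)]
                seen[r, c] = True
                comp = []
                while queue:
                    y, x = queue.pop()
                    comp.append((y, x))
                    for dy, dx in offsets:
                        ny, nx = y + dy, x + dx
                        if (0 <= ny < H and 0 <= nx < W and mask[ny, nx]
                                and not seen[ny, nx]):
                            seen[ny, nx] = True
                            queue.append((ny, nx))
                comps.append(frozenset(comp))
    return set(comps)


class TestEstimateBackground:
    def test_identical_frames_recovered(self):
        frame = np.full((20, 30), 100, dtype=np.uint8)
        frame[5:10, 5:10] = 50
        seq = _seq([frame] * 8)
        bg = estimate_background(seq, n=5, seed=0, sigma=0.0)
        assert np.allclose(bg.background, frame)
        assert bg.n_sampled == 5

    def test_median_removes_transient_cell(self):
        """A dark cell present in <50% of frames vanishes from the median
        (checked against the exact full-stack sorted median)."""
        rng = np.random.default_rng(0)
        base = rng.integers(90, 110, size=(25, 40)).astype(np.uint8)
        frames = np.repeat(base[None], 40, axis=0).copy()
        for i in range(15):            # cell covers the patch in 15/40 frames
            frames[i, 10:15, 20:25] = 30
        seq = _seq(frames)
        bg = estimate_background(seq, n=40, seed=1, sigma=0.0)
        exact = np.median(frames.astype(float), axis=0)
        assert np.abs(bg.background - exact).max() <= 1e-9
        assert np.abs(bg.background - base.astype(float)).max() <= 1.0

    def test_sampling_robust_to_seed(self):
        rng = np.random.default_rng(3)
        frames = rng.normal(100, 1.5, size=(300, 15, 20))
        frames = np.clip(frames, 0, 255).astype(np.uint8)
        seq = _seq(frames)
        b1 = estimate_background(seq, n=100, seed=1, sigma=0.0)
        b2 = estimate_background(seq, n=100, seed=2, sigma=0.0)
        assert np.abs(b1.background - b2.background).max() <= 1.0
        assert b1.n_sampled == 100
        assert len(set(b1.sample_indices)) == 100

    def test_short_sequence_uses_all_frames(self):
        seq = _seq(np.zeros((7, 5, 5)))
        bg = estimate_background(seq, n=100, seed=0)
        assert bg.n_sampled == 7

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_background(_seq(np.zeros((0, 5, 5))), seed=0)


class TestBinarize:
    def _bg(self, value, shape=(10, 10)):
        from deformcyte.detection import MedianBackground
        return MedianBackground(np.full(shape, float(value)), 1,
                                np.array([0]), sigma=0.0)

    def test_frame_equal_to_background_empty(self):
        bg = self._bg(100)
        frame = np.full((10, 10), 100, dtype=np.uint8)
        assert not binarize(frame, bg).any()

    def test_threshold_is_strict(self):
        """|diff| must strictly exceed 5: +5 excluded, +6 included."""
        bg = self._bg(100)
        frame = np.full((10, 10), 100, dtype=np.uint8)
        frame[3, 3] = 105
        assert not binarize(frame, bg).any()
        frame[3, 3] = 106
        mask = binarize(frame, bg)
        assert mask[3, 3] and mask.sum() == 1

    def test_contrast_sign_symmetric(self):
        bg = self._bg(100)
        dark = np.full((10, 10), 100, dtype=np.uint8)
        dark[2:5, 2:5] = 80
        bright = np.full((10, 10), 100, dtype=np.uint8)
        bright[2:5, 2:5] = 120
        assert (binarize(dark, bg) == binarize(bright, bg)).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            binarize(np.zeros((5, 5), dtype=np.uint8), self._bg(0, (6, 6)))


class TestDetectRegions:
    def test_empty_mask(self):
        assert detect_regions(np.zeros((10, 10), dtype=bool)) == []

    def test_area_filter_is_strict(self):
        """Exactly 50 px is rejected ('larger than 50'); 51 px passes."""
        mask50 = make_mask((30, 30), [(5, 5, 5, 10)])    # 50 px
        assert detect_regions(mask50) == []
        mask51 = mask50.copy()
        mask51[10, 5] = True                              # 51 px
        regions = detect_regions(mask51)
        assert len(regions) == 1 and regions[0].area == 51

    def test_bbox_contains_all_pixels_and_is_half_open(self):
        mask = make_mask((30, 30), [(5, 6, 7, 9)])
        (r,) = detect_regions(mask, min_area=10)
        assert r.bbox == (5, 6, 12, 15)
        rr, cc = r.coords[:, 0], r.coords[:, 1]
        assert rr.min() == 5 and rr.max() == 11
        assert cc.min() == 6 and cc.max() == 14
        assert r.centroid == (8.0, 10.0)

    @pytest.mark.parametrize("connectivity,expected", [(8, 1), (4, 2)])
    def test_diagonal_gap_follows_connectivity(self, connectivity, expected):
        """Two blobs touching only diagonally merge under 8-connectivity but
        not under 4-connectivity; verified against a BFS flood-fill oracle."""
        mask = make_mask((40, 40), [(5, 5, 8, 8), (13, 13, 8, 8)])
        regions = detect_regions(mask, min_area=10, connectivity=connectivity)
        assert len(regions) == expected
        oracle = flood_fill_components(mask, connectivity)
        big = {c for c in oracle if len(c) > 10}
        assert len(big) == expected
        got = {frozenset((int(a), int(b)) for a, b in r.coords)
               for r in regions}
        assert got == big

    def test_components_match_flood_fill_on_random_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            mask = rng.random((30, 30)) < 0.35
            for conn in (4, 8):
                regions = detect_regions(mask, min_area=0, connectivity=conn)
                got = {frozenset((int(a), int(b)) for a, b in r.coords)
                       for r in regions}
                assert got == flood_fill_components(mask, conn)

    def test_output_sorted_by_min_col_then_min_row(self):
        mask = make_mask((50, 80), [(30, 5, 9, 9), (5, 30, 9, 9),
                                    (20, 55, 9, 9)])
        regions = detect_regions(mask, min_area=10)
        assert [r.bbox[1] for r in regions] == [5, 30, 55]


class TestDetectSequence:
    def test_recovers_planted_cells(self, clean_video):
        """On a noise-free video, region counts and centroids match the
        planted ground truth (cells > 50 px, non-touching)."""
        seq, gt = clean_video
        per_frame = detect_sequence(seq, seed=0)
        for fi, regions in enumerate(per_frame):
            truth = gt.observations(fi)
            interior = [ob for ob in truth
                        if 6 < ob.centroid[1] < seq.shape[1] - 6]
            if len(interior) != len(truth):
                continue        # cells straddling the frame edge
            assert len(regions) == len(truth)
            got = sorted(r.centroid for r in regions)
            want = sorted(ob.centroid for ob in truth)
            for g, w in zip(got, want):
                assert abs(g[0] - w[0]) <= 1.0 and abs(g[1] - w[1]) <= 1.0

    def test_invariant_to_constant_offset(self, clean_video):
        """Background subtraction cancels a constant intensity offset."""
        seq, _ = clean_video
        shifted = FrameSequence(
            frames=np.clip(seq.frames.astype(int) + 12, 0, 255).astype(np.uint8),
            donor_id="s")
        a = detect_sequence(seq, seed=0)
        b = detect_sequence(shifted, seed=0)
        for ra, rb in zip(a, b):
            assert [r.bbox for r in ra] == [r.bbox for r in rb]
            assert [r.area for r in ra] == [r.area for r in rb]
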