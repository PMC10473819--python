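"""Patch geometry, overlap aggregation, segmentation and dQC-map unit tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynqc import (
    GeometryError,
    ImageSeries,
    SegmenterContractError,
    aggregate,
    build_overlap_index,
    compute_dqc_map,
    extract_patches,
    plan_patch_grid,
    segment_series,
)

from conftest import constant_field_segmenter, lookup_segmenter, naive_aggregate


class TestPlanPatchGrid:
    @pytest.mark.parametrize(
        "M, N, K, w, n_expected",
        [
            (128, 128, 64, 16, 25),    # coarse segmentation grid: 5 x 5 anchors
            (128, 128, 64, 2, 1089),   # dense dQC grid: 33 x 33 anchors
            (64, 64, 64, 16, 1),       # patch equals image
        ],
    )
    def test_reference_geometries(self, M, N, K, w, n_expected):
        grid = plan_patch_grid(M, N, K, w)
        assert grid.n_patches == n_expected
        if n_expected == 1:
            assert grid.origins == ((0, 0),)

    def test_flush_origin_appended_when_stride_misses_edge(self):
        grid = plan_patch_grid(11, 11, 4, 3)
        rows = sorted({r for r, _ in grid.origins})
        assert rows == [0, 3, 6, 7]  # 7 = 11 - 4 appended for edge coverage

    @pytest.mark.parametrize(
        "M, N, K, w",
        [(10, 10, 11, 2), (10, 10, 0, 1), (10, 10, 4, 0), (10, 10, 4, 5)],
    )
    def test_invalid_geometry_rejected(self, M, N, K, w):
        with pytest.raises(GeometryError):
            plan_patch_grid(M, N, K, w)

    @given(
        M=st.integers(4, 30),
        N=st.integers(4, 30),
        K=st.integers(1, 8),
        w=st.integers(1, 8),
    )
    @settings(max_examples=60, deadline=None)
    def test_full_coverage_and_ordering(self, M, N, K, w):
        """Every pixel is covered and origins are unique, sorted row-major."""
        if K > min(M, N) or w > K:
            return
        grid = plan_patch_grid(M, N, K, w)
        assert sorted(set(grid.origins)) == list(grid.origins)
        covered = np.zeros((M, N), dtype=bool)
        for r, c in grid.origins:
            assert 0 <= r <= M - K and 0 <= c <= N - K
            covered[r : r + K, c : c + K] = True
        assert covered.all()


class TestOverlapIndex:
    def test_single_patch_grid_counts_one_everywhere(self):
        idx = build_overlap_index(plan_patch_grid(16, 16, 16, 4))
        assert (idx.count == 1).all()

    def test_reference_coverage_counts(self):
        idx = build_overlap_index(plan_patch_grid(128, 128, 64, 16))
        assert idx.count[64, 64] == 16  # central pixel sees 4x4 anchors
        assert idx.count[0, 0] == 1     # corner pixel only the first patch
        assert len(idx.patches_covering(64, 64)) == 16

    def test_counts_match_bruteforce_membership(self, rng):
        for _ in range(5):
            M, N = rng.integers(6, 20, size=2)
            K = int(rng.integers(2, min(M, N) + 1))
            w = int(rng.integers(1, K + 1))
            idx = build_overlap_index(plan_patch_grid(int(M), int(N), K, w))
            for m in range(int(M)):
                for n in range(int(N)):
                    assert idx.count[m, n] == len(idx.patches_covering(m, n)) >= 1


class TestExtractPatches:
    def test_quadrants_of_a_ramp(self):
        data = np.arange(16, dtype=float).reshape(4, 4, 1)
        grid = plan_patch_grid(4, 4, 2, 2)
        blocks = extract_patches(ImageSeries(data), grid)
        assert blocks.shape == (4, 2, 2, 1)
        np.testing.assert_array_equal(blocks[0][:, :, 0], [[0, 1], [4, 5]])
        np.testing.assert_array_equal(blocks[3][:, :, 0], [[10, 11], [14, 15]])

    def test_single_patch_equals_series(self, rng):
        data = rng.random((5, 5, 3))
        grid = plan_patch_grid(5, 5, 5, 1)
        np.testing.assert_array_equal(extract_patches(ImageSeries(data), grid)[0], data)

    def test_extent_mismatch_rejected(self, rng):
        grid = plan_patch_grid(8, 8, 4, 2)
        with pytest.raises(GeometryError):
            extract_patches(ImageSeries(rng.random((9, 8, 2))), grid)


class TestAggregate:
    def test_identical_patches_mean_is_value_std_zero(self):
        grid = plan_patch_grid(4, 4, 2, 1)
        idx = build_overlap_index(grid)
        stack = np.full((grid.n_patches, 2, 2, 1), 0.7)
        np.testing.assert_allclose(aggregate(stack, idx, "mean"), 0.7, atol=1e-15)
        np.testing.assert_allclose(aggregate(stack, idx, "std"), 0.0, atol=1e-15)

    def test_two_patch_disagreement_closed_form(self):
        # K=2, w=1 on 2x3: middle column covered by both patches
        grid = plan_patch_grid(2, 3, 2, 1)
        idx = build_overlap_index(grid)
        stack = np.stack([np.zeros((2, 2, 1)), np.ones((2, 2, 1))])
        mean = aggregate(stack, idx, "mean")
        std = aggregate(stack, idx, "std")
        assert mean[0, 1, 0] == 0.5 and std[0, 1, 0] == 0.5
        assert std[0, 0, 0] == 0.0 and std[0, 2, 0] == 0.0  # single coverage exact

    def test_three_patch_population_std(self):
        # K=3, w=1 on 3x5: middle column covered by all three patches
        grid = plan_patch_grid(3, 5, 3, 1)
        idx = build_overlap_index(grid)
        stack = np.stack(
            [np.full((3, 3, 1), v) for v in (0.0, 0.5, 1.0)]
        )
        std = aggregate(stack, idx, "std")
        np.testing.assert_allclose(std[1, 2, 0], np.sqrt(1.0 / 6.0), rtol=1e-14)

    def test_matches_naive_loop_on_random_instances(self, rng):
        """Vectorized aggregation equals a per-pixel brute-force loop."""
        for _ in range(20):
            M, N = (int(x) for x in rng.integers(4, 17, size=2))
            T = int(rng.integers(1, 4))
            K = int(rng.integers(2, min(8, M, N) + 1))
            w = int(rng.choice([x for x in (1, 2, 4) if x <= K]))
            grid = plan_patch_grid(M, N, K, w)
            idx = build_overlap_index(grid)
            stack = rng.random((grid.n_patches, K, K, T))
            for mode in ("mean", "std"):
                got = aggregate(stack, idx, mode)
                want = naive_aggregate(stack, grid, mode)
                assert np.abs(got - want).max() <= 1e-12

    @given(data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_std_bounded_by_half(self, data):
        """Std of probabilities in [0,1] is at most 0.5 for any coverage."""
        M = data.draw(st.integers(4, 12))
        N = data.draw(st.integers(4, 12))
        K = data.draw(st.integers(2, min(M, N)))
        w = data.draw(st.integers(1, K))
        seed = data.draw(st.integers(0, 2**20))
        grid = plan_patch_grid(M, N, K, w)
        idx = build_overlap_index(grid)
        stack = np.random.default_rng(seed).random((grid.n_patches, K, K, 2))
        std = aggregate(stack, idx, "std")
        assert std.min() >= 0.0 and std.max() <= 0.5


class TestSegmentSeries:
    def test_threshold_inclusive_at_half(self):
        """A mean probability of exactly 0.5 is foreground."""
        series = ImageSeries(np.zeros((4, 4, 1)))
        mask = segment_series(series, lambda p, o: np.full_like(p, 0.5), 4, 2)
        assert (mask.data == 1).all()

    def test_all_zero_probabilities_give_empty_mask(self):
        series = ImageSeries(np.zeros((6, 6, 2)))
        mask = segment_series(series, lambda p, o: np.zeros_like(p), 3, 3)
        assert mask.data.sum() == 0

    def test_single_patch_identity_pipeline(self, small_bundle):
        gt_prob = small_bundle.gt.data.astype(float)
        seg = constant_field_segmenter(gt_prob)
        M, N, _ = small_bundle.series.shape
        mask = segment_series(small_bundle.series, seg, M, 1)
        np.testing.assert_array_equal(mask.data, small_bundle.gt.data)

    def test_contract_violation_rejected(self):
        series = ImageSeries(np.zeros((4, 4, 1)))
        with pytest.raises(SegmenterContractError):
            segment_series(series, lambda p, o: np.full_like(p, 1.2), 2, 2)


class TestDqcMap:
    def test_position_agnostic_segmenter_gives_null_map(self, rng):
        """When every patch reports the same per-pixel scores there is no disagreement."""
        field = rng.random((12, 12, 3))
        series = ImageSeries(np.zeros((12, 12, 3)))
        dqc = compute_dqc_map(series, constant_field_segmenter(field), 6, 2)
        assert np.abs(dqc).max() <= 1e-12

    def test_stride_invariance_for_position_agnostic_segmenter(self, rng):
        field = np.clip(rng.random((16, 16, 2)), 0, 1)
        series = ImageSeries(np.zeros((16, 16, 2)))
        seg = constant_field_segmenter(field)
        masks = [segment_series(series, seg, 8, w).data for w in (2, 4, 8)]
        assert all(np.array_equal(masks[0], m) for m in masks[1:])

    def test_deviant_patch_flagged_exactly_on_its_footprint(self):
        grid = plan_patch_grid(9, 9, 3, 3)
        stack = np.full((grid.n_patches, 3, 3, 1), 0.4)
        stack[4] = 0.9  # center patch disagrees (footprint rows/cols 3..5)
        series = ImageSeries(np.zeros((9, 9, 1)))
        dqc = compute_dqc_map(series, lookup_segmenter(stack, grid), 3, 3)
        inside = dqc[3:6, 3:6, 0]
        outside = dqc.copy()
        outside[3:6, 3:6, 0] = 0
        # non-overlapping w = K grid: only the deviant footprint can differ,
        # and it has single coverage there, so std is 0 everywhere
        assert np.abs(outside).max() <= 1e-12
        assert np.abs(inside).max() <= 1e-12

    def test_deviant_patch_with_overlap_raises_map_on_footprint_only(self):
        grid = plan_patch_grid(8, 8, 4, 2)
        stack = np.full((grid.n_patches, 4, 4, 1), 0.4)
        stack[0] = 0.95
        series = ImageSeries(np.zeros((8, 8, 1)))
        dqc = compute_dqc_map(series, lookup_segmenter(stack, grid), 4, 2)
        r0, c0 = grid.origins[0]
        foot = np.zeros((8, 8, 1), dtype=bool)
        foot[r0 : r0 + 4, c0 : c0 + 4, :] = True
        shared = foot.copy()
        shared[0, 0, 0] = False  # corner pixel covered only by the deviant patch
        assert dqc[shared].max() > 0.1
        assert np.abs(dqc[~foot]).max() <= 1e-12
        assert dqc[0, 0, 0] == 0.0

    def test_matches_naive_loop_on_random_stack(self, rng):
        grid = plan_patch_grid(16, 16, 8, 2)
        stack = rng.random((grid.n_patches, 8, 8, 3))
        series = ImageSeries(np.zeros((16, 16, 3)))
        dqc = compute_dqc_map(series, lookup_segmenter(stack, grid), 8, 2)
        want = naive_aggregate(stack, grid, "std")
        assert np.abs(dqc - want).max() <= 1e-12

    def test_warns_when_dqc_grid_coarser_than_segmentation(self, rng):
        series = ImageSeries(np.zeros((8, 8, 1)))
        with pytest.warns(UserWarning, match="coarser"):
            compute_dqc_map(series, lambda p, o: np.zeros_like(p), 4, 4, w_S=2)

    def test_determinism_bit_identical(self, small_bundle, small_segmenter):
        seg = small_segmenter()
        a = compute_dqc_map(small_bundle.series, seg, 16, 4)
        b = compute_dqc_map(small_bundle.series, seg, 16, 4)
        assert np.array_equal(a, b)
        sa = segment_series(small_bundle.series, seg, 16, 8)
        sb = segment_series(small_bundle.series, seg, 16, 8)
        assert np.array_equal(sa.data, sb.data)
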