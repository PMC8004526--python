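import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchreg.deform import DisplacementField, DistanceMap, zero_field
from patchreg.sampling import (
    PatchPair,
    allocate_samples,
    build_training_set,
    distance_histogram,
    draw_feedback_centers,
    extract_patch_pair,
    grid_centers,
)
from patchreg.volumes_io import Volume3D

from .conftest import smooth_random_field


class TestGridCenters:
    def test_exact_fit_single_center(self):
        assert grid_centers((64, 64, 64), 64, 32) == [(32, 32, 32)]

    def test_128_cube(self):
        centers = grid_centers((128, 128, 128), 64, 32)
        assert len(centers) == 27

    def test_end_alignment(self):
        centers = grid_centers((100, 64, 64), 64, 32)
        # axis 0: starts 0, 32 plus end-aligned 36 -> 3; axes 1-2: 1 each
        assert len(centers) == 3
        zs = sorted({c[0] for c in centers})
        assert zs == [32, 64, 68]

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            grid_centers((32, 32, 32), 64, 32)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(16, 80), st.integers(1, 16))
    def test_windows_cover_axis(self, L, s):
        # coverage of [0, L) is guaranteed for step <= window
        w = 16
        centers = grid_centers((L, w, w), w, s)
        covered = np.zeros(L, dtype=bool)
        for c in sorted({c[0] for c in centers}):
            covered[c - w // 2:c - w // 2 + w] = True
        assert covered.all()


class TestExtractPatchPair:
    def _volumes(self, shape=(16, 16, 16)):
        z, y, x = np.indices(shape, dtype=np.float64)
        fixed = Volume3D(data=x / shape[2])
        moving = Volume3D(data=y / shape[1])
        vec = np.stack([x, y, z], axis=-1)
        return fixed, moving, DisplacementField(vectors=vec)

    def test_exact_fit_full_volume(self):
        fixed, moving, gt = self._volumes()
        pair = extract_patch_pair(fixed, moving, gt, (8, 8, 8), 16, 9)
        np.testing.assert_array_equal(pair.fixed_patch, fixed.data.astype(np.float32))
        assert pair.target.shape == (3, 9, 9, 9)

    def test_zero_field_zero_target(self):
        fixed, moving, _ = self._volumes()
        pair = extract_patch_pair(fixed, moving, zero_field((16, 16, 16)), (8, 8, 8), 16, 5)
        np.testing.assert_array_equal(pair.target, 0.0)

    def test_ramp_field_slicing_oracle(self):
        fixed, moving, gt = self._volumes()
        c, o = (8, 8, 8), 5
        pair = extract_patch_pair(fixed, moving, gt, c, 16, o)
        lo = [ci - o // 2 for ci in c]
        block = gt.vectors[lo[0]:lo[0] + o, lo[1]:lo[1] + o, lo[2]:lo[2] + o]
        np.testing.assert_array_equal(pair.target, np.moveaxis(block, -1, 0))

    def test_out_of_bounds_rejected(self):
        fixed, moving, gt = self._volumes()
        with pytest.raises(ValueError):
            extract_patch_pair(fixed, moving, gt, (2, 8, 8), 16, 5)

    def test_patchpair_contract(self):
        with pytest.raises(ValueError):
            PatchPair(fixed_patch=np.zeros((8, 8, 8), dtype=np.float32),
                      moving_patch=np.zeros((8, 8, 8), dtype=np.float32),
                      target=np.zeros((3, 9, 9, 9), dtype=np.float32),
                      center=(4, 4, 4))


class TestDistanceHistogram:
    def test_all_zero_map(self):
        alloc = distance_histogram(DistanceMap(values=np.zeros((5, 5, 5))))
        assert alloc.n_bins == 0

    def test_hand_rounding(self):
        vals = np.zeros((4, 1, 1))
        vals[:, 0, 0] = [0.4, 1.2, 1.4, 2.6]
        alloc = distance_histogram(DistanceMap(values=vals))
        assert alloc.n_bins == 3
        np.testing.assert_array_equal(alloc.n_per_bin, [2, 0, 1])

    def test_constant_two(self):
        alloc = distance_histogram(DistanceMap(values=np.full((10, 10, 10), 2.0)))
        np.testing.assert_array_equal(alloc.n_per_bin, [0, 1000])


class TestAllocateSamples:
    def test_symmetric_bins(self):
        alloc = allocate_samples([100, 100], alpha=0.5, A=10)
        np.testing.assert_array_equal(alloc.s_per_bin, [5, 5])

    def test_hand_evaluation(self):
        # weights (1/100)^.5=0.1, (1/10)^.5=0.31623; quotas 26.43, 83.57
        alloc = allocate_samples([100, 10], alpha=0.5, A=110)
        np.testing.assert_array_equal(alloc.s_per_bin, [26, 84])

    def test_small_alpha_flattens(self):
        n = [10000, 100, 10]
        flat = allocate_samples(n, alpha=1.0 / 32.0, A=300).s_per_bin
        steep = allocate_samples(n, alpha=0.5, A=300).s_per_bin
        assert np.var(flat) < np.var(steep)

    def test_empty_bins_get_zero(self):
        alloc = allocate_samples([50, 0, 50], alpha=0.5, A=10)
        assert alloc.s_per_bin[1] == 0
        assert alloc.s_per_bin.sum() == 10

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            allocate_samples([0, 0], alpha=0.5, A=5)

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.integers(0, 10 ** 6), min_size=1, max_size=12).filter(lambda l: any(l)),
        st.sampled_from([1.0, 0.5, 0.25, 0.125, 1.0 / 16, 1.0 / 32]),
        st.integers(0, 10 ** 4),
    )
    def test_sum_exact_and_monotone(self, n, alpha, A):
        alloc = allocate_samples(n, alpha=alpha, A=A)
        assert int(alloc.s_per_bin.sum()) == A
        s, counts = alloc.s_per_bin, np.asarray(n)
        for i in range(len(n)):
            for j in range(len(n)):
                if 0 < counts[i] < counts[j]:
                    assert s[i] >= s[j]


class TestDrawFeedbackCenters:
    def _dmap(self):
        vals = np.zeros((20, 20, 20))
        vals[8:12, 8:12, 8:12] = 2.0  # 64 eligible interior voxels in bin 2
        return DistanceMap(values=vals)

    def test_exhaustive_draw(self):
        vals = np.zeros((20, 20, 20))
        vals[9, 9, 9] = vals[10, 10, 10] = vals[11, 11, 11] = 2.0
        alloc = allocate_samples([0, 3], alpha=0.5, A=3)
        centers = draw_feedback_centers(DistanceMap(values=vals), alloc, margin=8, seed=0)
        assert sorted(centers) == [(9, 9, 9), (10, 10, 10), (11, 11, 11)]

    def test_determinism(self):
        alloc = allocate_samples([0, 64], alpha=0.5, A=10)
        a = draw_feedback_centers(self._dmap(), alloc, margin=8, seed=42)
        b = draw_feedback_centers(self._dmap(), alloc, margin=8, seed=42)
        assert a == b

    def test_bin_membership(self):
        vals = np.zeros((24, 24, 24))
        gen = np.random.default_rng(1)
        vals[gen.random((24, 24, 24)) < 0.5] = 1.0
        vals[4:8, 4:8, 4:8] = 3.0
        dmap = DistanceMap(values=vals)
        alloc = allocate_samples(distance_histogram(dmap).n_per_bin, alpha=0.5, A=20)
        centers = draw_feedback_centers(dmap, alloc, margin=4, seed=9)
        rounded = np.floor(vals + 0.5).astype(int)
        drawn_bins = sorted({rounded[c] for c in centers})
        for c in centers:
            assert rounded[c] in (1, 3)
        assert drawn_bins == [1, 3]

    def test_with_replacement_fallback(self, caplog):
        vals = np.zeros((20, 20, 20))
        vals[10, 10, 10] = 2.0
        alloc = allocate_samples([0, 5], alpha=0.5, A=5)
        with caplog.at_level("WARNING"):
            centers = draw_feedback_centers(DistanceMap(values=vals), alloc,
                                            margin=8, seed=0)
        assert centers == [(10, 10, 10)] * 5
        assert "replacement" in caplog.text

    def test_no_eligible_voxels(self):
        vals = np.zeros((20, 20, 20))
        alloc = allocate_samples([4], alpha=0.5, A=4)
        with pytest.raises(ValueError):
            draw_feedback_centers(DistanceMap(values=vals), alloc, margin=8, seed=0)


class TestBuildTrainingSet:
    def _pair(self, magnitude=0.0):
        gen = np.random.default_rng(2)
        from scipy import ndimage

        fixed = Volume3D(data=ndimage.gaussian_filter(gen.random((16, 16, 16)), 1.5))
        field = smooth_random_field((16, 16, 16), magnitude, seed=4)
        from patchreg._residual import invert_field
        from patchreg.deform import warp

        moving = warp(fixed, invert_field(field)) if magnitude else fixed
        return fixed, moving, field

    def test_single_pair_single_factor(self):
        samples = build_training_set([self._pair()], w=16, o=5, step=16)
        assert len(samples) == 1

    def test_factors_multiply_count(self):
        samples = build_training_set([self._pair(1.0)], w=16, o=5, step=16,
                                     augment_factors=[1.0, -1.0, 2.0])
        assert len(samples) == 3

    def test_zero_field_zero_targets(self):
        samples = build_training_set([self._pair(0.0)], w=16, o=5, step=16,
                                     augment_factors=[1.0, -1.0])
        for s in samples:
            np.testing.assert_allclose(s.target, 0.0, atol=1e-9)

    def test_scaled_factor_scales_targets(self):
        base = build_training_set([self._pair(1.0)], w=16, o=5, step=16)[0]
        doubled = build_training_set([self._pair(1.0)], w=16, o=5, step=16,
                                     augment_factors=[2.0])[0]
        np.testing.assert_allclose(doubled.target, 2.0 * base.target, atol=1e-6)
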