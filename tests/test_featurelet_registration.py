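import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from featreg import ImageVolume, RegistrationConfig
from featreg.featurelet_registration import (
    VoxelBox,
    partition_grid_shape,
    partition_moving_image,
    register_featurelet,
    run_registration,
    search_region_for,
    global_prealign,
)

from conftest import textured_volume


def exhaustive_scan(patch, fixed_data, search, box, config):
    """Oracle: score every integer offset keeping the patch in the search
    region; return the best offset (the optimizer must land in its cell)."""
    from featreg.featurelet_registration import _MetricEvaluator

    ev = _MetricEvaluator(np.asarray(patch, float), fixed_data, box.lo, config)
    los = [s - m for s, m in zip(search.lo, box.lo)]
    his = [s - m for s, m in zip(search.hi, box.hi)]
    offsets = np.array(
        [
            (a, b, c)
            for a in range(int(los[0]), int(his[0]) + 1)
            for b in range(int(los[1]), int(his[1]) + 1)
            for c in range(int(los[2]), int(his[2]) + 1)
        ],
        dtype=float,
    )
    scores = ev.scores(offsets)
    return offsets[int(np.argmax(scores))], float(scores.max())


class TestPartition:
    def test_exact_tiling(self):
        boxes = partition_moving_image((30, 30, 30), (15, 15, 15))
        assert len(boxes) == 8
        assert all(b.shape == (15, 15, 15) for b in boxes)

    def test_truncated_last_box(self):
        boxes = partition_moving_image((40, 40, 40), (15, 15, 15))
        assert len(boxes) == 27
        extents = sorted({b.hi[0] - b.lo[0] for b in boxes})
        assert extents == [10, 15]
        # exhaustive voxel-coverage count
        cover = np.zeros((40, 40, 40), dtype=int)
        for b in boxes:
            cover[b.slices()] += 1
        assert (cover == 1).all()

    def test_single_box(self):
        boxes = partition_moving_image((15, 15, 15), (15, 15, 15))
        assert boxes == [VoxelBox((0, 0, 0), (15, 15, 15))]

    def test_featurelet_larger_than_volume_rejected(self):
        with pytest.raises(ValueError):
            partition_moving_image((10, 10, 10), (15, 15, 15))

    @given(
        dims=st.tuples(*[st.integers(1, 40)] * 3),
        size=st.tuples(*[st.integers(1, 15)] * 3),
    )
    def test_partition_covers_disjointly(self, dims, size):
        size = tuple(min(s, d) for s, d in zip(size, dims))
        boxes = partition_moving_image(dims, size)
        assert len(boxes) == int(np.prod(partition_grid_shape(dims, size)))
        cover = np.zeros(dims, dtype=int)
        for b in boxes:
            cover[b.slices()] += 1
        assert (cover == 1).all()


class TestSearchRegion:
    def test_centered_with_floor_convention(self):
        box = VoxelBox((15, 15, 15), (30, 30, 30))
        search = search_region_for(box, (60, 60, 60), (30, 30, 30))
        assert search == VoxelBox((7, 7, 7), (37, 37, 37))

    def test_clipped_at_corner_still_contains_footprint(self):
        box = VoxelBox((0, 0, 0), (15, 15, 15))
        search = search_region_for(box, (60, 60, 60), (30, 30, 30))
        assert search == VoxelBox((0, 0, 0), (30, 30, 30))

    def test_search_equal_featurelet_pins_displacement(self):
        vol = textured_volume((20, 20, 20), seed=3)
        cfg = RegistrationConfig(
            featurelet_size=(8, 8, 8), search_size=(8, 8, 8), max_iterations=50
        )
        box = VoxelBox((6, 6, 6), (14, 14, 14))
        search = search_region_for(box, vol, (8, 8, 8))
        disp, _, _ = register_featurelet(
            vol.data[box.slices()], vol, search, cfg, moving_region=box
        )
        assert np.linalg.norm(disp) < 1e-6


class TestRegisterFeaturelet:
    def test_identity_content_recovers_zero(self):
        vol = textured_volume((30, 30, 30), seed=5)
        cfg = RegistrationConfig(featurelet_size=(10, 10, 10), search_size=(20, 20, 20))
        box = VoxelBox((10, 10, 10), (20, 20, 20))
        search = search_region_for(box, vol, cfg.search_size)
        disp, merit, converged = register_featurelet(
            vol.data[box.slices()], vol, search, cfg, moving_region=box
        )
        assert converged
        assert np.linalg.norm(disp) < 0.1
        assert merit.value > 0.99

    @pytest.mark.parametrize("metric", ["NC", "MI"])
    def test_known_shift_matches_exhaustive_scan_cell(self, metric):
        """Descent must land in the same integer-translation cell as a brute
        exhaustive scan of the metric over the search region."""
        moving = textured_volume((32, 32, 32), seed=7, smooth=2.5)
        shift = (3, -2, 1)
        # fixed(x) = moving(x + d): content displaced by -d, pull-back d
        fixed_data = np.roll(moving.data, shift=[-s for s in shift], axis=(0, 1, 2))
        fixed = ImageVolume(fixed_data)
        cfg = RegistrationConfig(
            featurelet_size=(10, 10, 10), search_size=(20, 20, 20), metric=metric
        )
        box = VoxelBox((11, 11, 11), (21, 21, 21))
        search = search_region_for(box, fixed, cfg.search_size)
        patch = moving.data[box.slices()]
        disp, merit, converged = register_featurelet(
            patch, fixed, search, cfg, moving_region=box
        )
        best_o, best_score = exhaustive_scan(patch, fixed.data, search, box, cfg)
        assert np.all(np.abs(np.asarray(disp) - (-best_o)) <= 0.5 + 1e-9)
        assert tuple(-best_o) == shift  # the oracle itself found the truth
        assert converged
        if metric == "NC":
            assert np.all(np.abs(np.asarray(disp) - shift) < 0.5)

    def test_flat_patch_degenerate(self):
        vol = textured_volume((20, 20, 20), seed=1)
        cfg = RegistrationConfig(featurelet_size=(6, 6, 6), search_size=(12, 12, 12))
        box = VoxelBox((7, 7, 7), (13, 13, 13))
        search = search_region_for(box, vol, cfg.search_size)
        disp, merit, converged = register_featurelet(
            np.zeros((6, 6, 6)), vol, search, cfg, moving_region=box
        )
        assert disp == (0.0, 0.0, 0.0)
        assert not converged
        assert merit.degenerate


class TestRunRegistration:
    def test_identity_registration_near_zero_everywhere(self):
        vol = textured_volume((24, 24, 24), seed=11)
        cfg = RegistrationConfig(featurelet_size=(8, 8, 8), search_size=(16, 16, 16))
        feats = run_registration(vol, vol, cfg)
        assert len(feats) == 27
        for f in feats:
            if not f.final_merit.degenerate:
                assert np.linalg.norm(f.displacement) < 0.1

    def test_featurelet_count_and_determinism(self):
        vol = textured_volume((20, 20, 10), seed=2)
        other = textured_volume((20, 20, 10), seed=3)
        cfg = RegistrationConfig(featurelet_size=(10, 10, 5), search_size=(14, 14, 8),
                                 max_iterations=100)
        feats1 = run_registration(vol, other, cfg)
        feats2 = run_registration(vol, other, cfg)
        assert len(feats1) == 8
        for f1, f2 in zip(feats1, feats2):
            assert f1.displacement == f2.displacement  # bit-identical
            assert f1.final_merit.value == f2.final_merit.value

    def test_displacement_respects_search_clamp(self):
        moving = textured_volume((20, 20, 20), seed=4)
        fixed = textured_volume((20, 20, 20), seed=5)
        cfg = RegistrationConfig(featurelet_size=(6, 6, 6), search_size=(12, 12, 12),
                                 max_iterations=300)
        for f in run_registration(moving, fixed, cfg):
            bound = (12 - 6) / 2 + 1
            assert np.all(np.abs(f.displacement) <= bound)

    def test_geometry_mismatch_rejected(self):
        a = textured_volume((12, 12, 12))
        b = textured_volume((12, 12, 10))
        with pytest.raises(ValueError):
            run_registration(a, b, RegistrationConfig(featurelet_size=(6, 6, 6),
                                                      search_size=(8, 8, 8)))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"search_size": (10, 10, 10), "featurelet_size": (15, 15, 15)},
            {"min_step": 0.0},
            {"min_step": 0.1, "max_step": 0.05},
            {"max_iterations": 0},
            {"relaxation": 1.5},
            {"mi_bins": 1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RegistrationConfig(**kwargs)

    def test_documented_defaults(self):
        cfg = RegistrationConfig()
        assert cfg.featurelet_size == (15, 15, 15)
        assert cfg.search_size == (30, 30, 30)
        assert cfg.max_step == 0.05 and cfg.min_step == 0.001
        assert cfg.max_iterations == 2000


def test_global_prealign_recovers_coarse_shift():
    vol = textured_volume((24, 24, 24), seed=9, smooth=3.0)
    shifted = ImageVolume(np.roll(vol.data, (4, -2, 0), axis=(0, 1, 2)))
    assert global_prealign(vol, shifted, max_shift=6, coarsening=2) == (4, -2, 0)
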