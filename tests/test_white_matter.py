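import numpy as np
import pytest

from strokect.phantom import PhantomSpec, make_brain_phantom
from strokect.white_matter import (
    ball_footprint,
    segment_fibers,
    wall_thickness,
    white_top_hat,
)
from .oracles import wall_thickness_bruteforce, white_top_hat_bruteforce


class TestWhiteTopHat:
    def test_constant_volume_gives_zero(self):
        assert white_top_hat(np.full((10, 10, 10), 5.0), 3).max() == 0

    def test_single_bright_voxel_recovered(self):
        vol = np.zeros((9, 9, 9))
        vol[4, 4, 4] = 100.0
        th = white_top_hat(vol, 3)
        assert th[4, 4, 4] == 100.0
        th[4, 4, 4] = 0
        assert th.max() == 0

    def test_thick_slab_interior_suppressed(self):
        vol = np.zeros((30, 30, 30))
        vol[4:26] = 50.0  # 22-voxel slab, thicker than the SE
        th = white_top_hat(vol, 19)
        assert th[15, 15, 15] == 0

    @pytest.mark.parametrize("diameter", [3, 7])
    def test_matches_bruteforce_on_random_volumes(self, diameter, rng):
        vol = rng.random((24, 24, 24)) * 100
        expected = white_top_hat_bruteforce(vol, diameter)
        np.testing.assert_allclose(white_top_hat(vol, diameter), expected, atol=1e-9)

    def test_anti_extensive_and_non_negative(self, rng):
        vol = rng.random((16, 16, 16)) * 10
        th = white_top_hat(vol, 5)
        assert (th >= -1e-12).all()
        assert (th <= vol + 1e-12).all()

    def test_even_diameter_rejected(self):
        with pytest.raises(ValueError):
            ball_footprint(4)


class TestWallThickness:
    def test_digital_ball_center_diameter(self):
        zz, yy, xx = np.mgrid[:23, :23, :23]
        ball = (zz - 11) ** 2 + (yy - 11) ** 2 + (xx - 11) ** 2 <= 9**2
        thick, hist = wall_thickness(ball, voxel_size_um=1)
        assert thick[11, 11, 11] == pytest.approx(18, abs=1)
        oracle = wall_thickness_bruteforce(ball)
        inside = ball
        assert np.abs(thick[inside] - oracle[inside]).max() <= 1.0

    def test_slab_thickness_everywhere(self):
        slab = np.zeros((16, 12, 12), dtype=bool)
        slab[5:10] = True  # 5-voxel slab, full in-plane extent
        thick, _ = wall_thickness(slab, voxel_size_um=1)
        np.testing.assert_allclose(thick[slab], 5.0, atol=1)
        oracle = wall_thickness_bruteforce(slab)
        assert np.abs(thick[slab] - oracle[slab]).max() <= 1.0

    def test_thickness_at_least_twice_edt_minus_one(self, rng):
        from scipy.ndimage import distance_transform_edt

        mask = rng.random((20, 20, 20)) > 0.6
        if not mask.any():
            mask[10, 10, 10] = True
        thick, _ = wall_thickness(mask, voxel_size_um=1)
        edt = distance_transform_edt(mask)
        assert (thick[mask] >= 2 * edt[mask] - 1 - 1e-9).all()

    def test_histogram_sums_to_mask_volume(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:8, 2:8, 2:8] = True
        _, hist = wall_thickness(mask, voxel_size_um=10)
        assert sum(hist.values()) == pytest.approx(mask.sum() * (10 / 1000) ** 3)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            wall_thickness(np.zeros((4, 4, 4), dtype=bool))


@pytest.fixture(scope="module")
def fiber_phantom():
    spec = PhantomSpec(
        shape=(24, 64, 96),
        fiber_target_fraction=0.2,
        fiber_count=10,
        fiber_intensity_gain=1.6,
        seed=11,
    )
    return spec, *make_brain_phantom(spec)


class TestSegmentFibers:
    def test_recovers_truth_volume_fraction(self, fiber_phantom):
        spec, vol, truth = fiber_phantom
        cpu_l, cpu_r = truth.striatum_masks
        res = segment_fibers(vol, cpu_l, cpu_r, ball_diameter_vox=7)
        true_frac = (truth.fiber_mask & cpu_l).sum() / cpu_l.sum()
        assert res.contralateral.volume_fraction == pytest.approx(
            true_frac, abs=0.03
        )

    def test_threshold_above_max_gives_empty(self, fiber_phantom):
        spec, vol, truth = fiber_phantom
        cpu_l, cpu_r = truth.striatum_masks
        res = segment_fibers(vol, cpu_l, cpu_r, 7, threshold=1e9)
        assert res.contralateral.volume_fraction == 0
        assert not res.ipsilateral.wm_mask.any()

    def test_label_exchange_swaps_outputs(self, fiber_phantom):
        spec, vol, truth = fiber_phantom
        cpu_l, cpu_r = truth.striatum_masks
        a = segment_fibers(vol, cpu_l, cpu_r, 7, threshold=10.0)
        b = segment_fibers(vol, cpu_r, cpu_l, 7, threshold=10.0)
        np.testing.assert_array_equal(
            a.contralateral.wm_mask, b.ipsilateral.wm_mask
        )

    def test_thinned_ipsilateral_lowers_ratio(self):
        spec = PhantomSpec(
            shape=(24, 64, 96),
            fiber_target_fraction=0.2,
            fiber_count=10,
            fiber_intensity_gain=1.6,
            ipsi_fiber_radius_scale=0.8,
            seed=11,
        )
        vol, truth = make_brain_phantom(spec)
        cpu_l, cpu_r = truth.striatum_masks
        res = segment_fibers(vol, cpu_l, cpu_r, 7)
        assert res.ipsi_contra_ratio < 1.0

    def test_empty_roi_errors(self, fiber_phantom):
        spec, vol, truth = fiber_phantom
        with pytest.raises(ValueError):
            segment_fibers(vol, np.zeros(spec.shape, bool), truth.striatum_masks[1], 7)
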