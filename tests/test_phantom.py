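import numpy as np
import pytest

from strokect.lesion_sim import LesionSimParams
from strokect.phantom import (
    PhantomSpec,
    make_brain_phantom,
    make_lesioned_phantom,
    make_ttc_slices,
)


class TestBrainPhantom:
    def test_deterministic_given_seed(self, small_spec):
        vol1, _ = make_brain_phantom(small_spec)
        vol2, _ = make_brain_phantom(small_spec)
        np.testing.assert_array_equal(vol1.data, vol2.data)

    def test_zero_fibers_gives_empty_fiber_mask(self):
        spec = PhantomSpec(shape=(20, 48, 64), fiber_count=0, seed=1)
        _, truth = make_brain_phantom(spec)
        assert not truth.fiber_mask.any()

    def test_mean_brain_intensity_near_nominal(self, small_phantom, small_spec):
        vol, truth = small_phantom
        mean = vol.data[truth.brain_mask].mean()
        assert abs(mean - small_spec.hemisphere_intensity) < 0.1 * small_spec.hemisphere_intensity

    def test_hemisphere_masks_are_mirror_images(self, small_phantom):
        _, truth = small_phantom
        x = truth.left_mask.shape[2]
        mid = truth.midline_column
        mirrored = np.zeros_like(truth.left_mask)
        mirrored[:, :, mid:] = truth.left_mask[:, :, mid - 1 :: -1][:, :, : x - mid]
        np.testing.assert_array_equal(truth.right_mask, mirrored)

    def test_truth_volumes_consistent_with_masks(self, small_phantom, small_spec):
        _, truth = small_phantom
        voxel = (small_spec.voxel_size_um / 1000) ** 3
        assert truth.true_volumes_mm3["brain"] == pytest.approx(
            truth.brain_mask.sum() * voxel
        )
        assert truth.true_volumes_mm3["left"] + truth.true_volumes_mm3[
            "right"
        ] == pytest.approx(truth.brain_mask.sum() * voxel)

    def test_fibers_confined_to_striatum_and_brain(self, small_phantom):
        _, truth = small_phantom
        cpu = truth.striatum_masks[0] | truth.striatum_masks[1]
        assert (truth.fiber_mask <= truth.brain_mask).all()
        # tubes are seeded inside the striatum box; dilation may spill a voxel
        outside = truth.fiber_mask & ~cpu
        assert outside.sum() <= 0.3 * truth.fiber_mask.sum()

    def test_shape_too_small_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(shape=(8, 48, 64))

    def test_target_fraction_reached(self):
        spec = PhantomSpec(
            shape=(24, 64, 96), fiber_target_fraction=0.2, fiber_count=10, seed=3
        )
        _, truth = make_brain_phantom(spec)
        box = truth.striatum_masks[0]
        frac = (truth.fiber_mask & box).sum() / box.sum()
        assert frac >= 0.15


class TestLesionedPhantom:
    def test_zero_drop_equals_healthy(self, small_spec):
        params = LesionSimParams(
            lesion_intensity_drop_range=(0.0, 0.0), core_extra_drop_range=(0.0, 0.0)
        )
        healthy, _ = make_brain_phantom(small_spec)
        lesioned, truth = make_lesioned_phantom(small_spec, params, seed=5)
        np.testing.assert_allclose(lesioned.data, healthy.data)
        assert truth.lesion_mask.any()

    def test_core_intensity_ratio_matches_drops(self, small_spec):
        params = LesionSimParams(
            lesion_intensity_drop_range=(0.3, 0.3), core_extra_drop_range=(0.4, 0.4)
        )
        healthy, _ = make_brain_phantom(small_spec)
        lesioned, truth = make_lesioned_phantom(small_spec, params, seed=5)
        from scipy.ndimage import binary_erosion

        core = binary_erosion(truth.core_mask, iterations=2)
        assert core.sum() > 10
        ratio = lesioned.data[core].sum() / healthy.data[core].sum()
        # 0.7 * 0.6 = 0.42 in the core interior (soft edges excluded)
        assert ratio == pytest.approx(0.42, abs=0.03)

    def test_zero_core_fraction_gives_empty_core(self, small_spec):
        params = LesionSimParams()
        _, truth = make_lesioned_phantom(
            small_spec, params, seed=5, core_radius_fraction=0.0
        )
        assert not truth.core_mask.any()
        assert truth.lesion_mask.any()

    def test_containment_chain(self, small_spec):
        params = LesionSimParams(lesion_intensity_drop_range=(0.3, 0.4))
        _, truth = make_lesioned_phantom(small_spec, params, seed=9)
        assert (truth.core_mask <= truth.lesion_mask).all()
        assert (truth.lesion_mask <= truth.right_mask).all()
        assert (truth.right_mask <= truth.brain_mask).all()


class TestTtcSlices:
    def test_zero_infarct_truth_zero(self):
        _, truth = make_ttc_slices(3, infarct_fraction=0.0, seed=1)
        assert all(a["infarct"] == 0 for a in truth.areas_mm2)

    def test_deterministic(self):
        img1, _ = make_ttc_slices(2, 0.2, seed=4)
        img2, _ = make_ttc_slices(2, 0.2, seed=4)
        np.testing.assert_array_equal(img1, img2)

    def test_rasterized_area_close_to_analytic(self):
        # a slice ellipse with semi-axes a, b has area pi*a*b; the
        # rasterization error is bounded by the perimeter in pixels
        _, truth = make_ttc_slices(1, 0.0, mm_per_pixel=0.05, seed=0)
        area = truth.areas_mm2[0]["contra"] + truth.areas_mm2[0]["ipsi"]
        pixels = area / 0.05**2
        # recompute expected analytic area from the drawn geometry
        assert pixels > 1000
        (cy, cx) = truth.slice_centers[0]
        assert 0 < cy and 0 < cx

    def test_infarct_fraction_of_hemisphere(self):
        _, truth = make_ttc_slices(4, 0.25, seed=2)
        for rec in truth.areas_mm2:
            assert rec["infarct"] / rec["ipsi"] == pytest.approx(0.25, abs=0.03)

    def test_excessive_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_ttc_slices(2, 0.9, seed=0)
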