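import numpy as np
import pytest

from strokect.manual_quant import (
    HemisphereVolumes,
    LesionVolumes,
    RoiSeries,
    corrected_lesion_percent,
    edema_extent,
    interpolate_roi,
    quantify_manual,
)


def _disc(shape, radius, center=None):
    if center is None:
        center = ((shape[0] - 1) / 2, (shape[1] - 1) / 2)
    yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestInterpolateRoi:
    def test_identical_end_masks_constant_stack(self):
        mask = _disc((48, 48), 10)
        series = RoiSeries("lesion", {0: mask, 10: mask})
        dense = interpolate_roi(series)
        assert dense.shape == (11, 48, 48)
        for k in range(11):
            np.testing.assert_array_equal(dense[k], mask)

    def test_concentric_discs_interpolate_radius(self):
        series = RoiSeries(
            "lesion", {0: _disc((64, 64), 10), 10: _disc((64, 64), 20)}
        )
        dense = interpolate_roi(series)
        mid_area = dense[5].sum()
        r_mid = np.sqrt(mid_area / np.pi)
        assert r_mid == pytest.approx(15, abs=1)

    def test_empty_end_shrinks_monotonically(self):
        series = RoiSeries(
            "lesion",
            {0: _disc((48, 48), 15), 8: np.zeros((48, 48), dtype=bool)},
        )
        dense = interpolate_roi(series)
        areas = dense.sum(axis=(1, 2))
        assert all(a2 <= a1 for a1, a2 in zip(areas[:-1], areas[1:]))
        assert dense[8].sum() == 0

    def test_annotated_slices_pass_through(self):
        m0, m1 = _disc((32, 32), 5), _disc((32, 32), 12)
        series = RoiSeries("core", {2: m0, 6: m1})
        dense = interpolate_roi(series, n_slices=10)
        np.testing.assert_array_equal(dense[2], m0)
        np.testing.assert_array_equal(dense[6], m1)
        assert not dense[0].any() and not dense[9].any()

    def test_stride_one_is_identity(self):
        masks = {i: _disc((24, 24), 4 + i) for i in range(4)}
        dense = interpolate_roi(RoiSeries("lesion", masks, stride=1))
        for i, m in masks.items():
            np.testing.assert_array_equal(dense[i], m)

    def test_single_annotation_errors(self):
        with pytest.raises(ValueError):
            interpolate_roi(RoiSeries("lesion", {0: _disc((16, 16), 4)}))


class TestEdemaExtent:
    def test_symmetric_is_zero(self):
        assert edema_extent(HemisphereVolumes(200, 200)) == 0

    def test_hand_evaluated_swelling(self):
        assert edema_extent(HemisphereVolumes(221, 200)) == pytest.approx(10.5)

    def test_hand_evaluated_shrinkage(self):
        assert edema_extent(HemisphereVolumes(180, 200)) == pytest.approx(-10)

    def test_swap_antisymmetry(self):
        h = HemisphereVolumes(221, 200)
        e = edema_extent(h)
        swapped = edema_extent(HemisphereVolumes(200, 221))
        assert swapped == pytest.approx(-e / (1 + e / 100))

    def test_zero_contralateral_errors(self):
        with pytest.raises(ValueError):
            edema_extent(HemisphereVolumes(100, 0))


class TestCorrectedLesionPercent:
    def test_zero_lesion(self):
        assert corrected_lesion_percent(HemisphereVolumes(1100, 1000), 0) == 0

    def test_hand_evaluated(self):
        h = HemisphereVolumes(V_ipsilateral=1100, V_contralateral=1000)
        assert corrected_lesion_percent(h, 150) == pytest.approx(6.4935, abs=1e-3)

    def test_collapses_without_edema(self):
        h = HemisphereVolumes(1000, 1000)
        assert corrected_lesion_percent(h, 150) == pytest.approx(150 / 2000 * 100)

    def test_monotone_in_lesion_and_ipsi(self):
        h = HemisphereVolumes(1100, 1000)
        assert corrected_lesion_percent(h, 200) > corrected_lesion_percent(h, 100)
        h_bigger_ipsi = HemisphereVolumes(1200, 1000)
        assert corrected_lesion_percent(h_bigger_ipsi, 150) < corrected_lesion_percent(
            h, 150
        )


class TestLesionVolumes:
    def test_penumbra_difference(self):
        lv = LesionVolumes(V_lesion=10, V_core=3)
        assert lv.penumbra == 7

    def test_core_exceeding_lesion_rejected(self):
        with pytest.raises(ValueError):
            LesionVolumes(V_lesion=5, V_core=8)


class TestQuantifyManual:
    def test_volume_arithmetic(self):
        ipsi = np.zeros((10, 10, 10), dtype=bool)
        contra = np.zeros_like(ipsi)
        ipsi[:, :, 6:] = True
        contra[:, :, :4] = True
        rec = quantify_manual(ipsi, contra, voxel_size_um=10)
        assert rec["V_ipsilateral_mm3"] == pytest.approx(400 * 1e-6)
        assert rec["edema_extent_percent"] == 0

    def test_phantom_truth_recovered(self, small_phantom, small_spec):
        _, truth = small_phantom
        rec = quantify_manual(
            truth.right_mask, truth.left_mask, small_spec.voxel_size_um
        )
        assert rec["V_brain_mm3"] == pytest.approx(
            truth.true_volumes_mm3["brain"], rel=0.02
        )

    def test_overlapping_hemispheres_error(self):
        m = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError):
            quantify_manual(m, m, 10)

    def test_lesion_outside_ipsi_warns(self):
        ipsi = np.zeros((6, 6, 6), dtype=bool)
        contra = np.zeros_like(ipsi)
        ipsi[:, :, 3:] = True
        contra[:, :, :3] = True
        lesion = np.zeros_like(ipsi)
        lesion[2, 2, 1] = True  # in the contralateral half
        with pytest.warns(UserWarning):
            rec = quantify_manual(ipsi, contra, 10, lesion_mask=lesion)
        assert rec["warnings"]
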