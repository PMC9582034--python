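import numpy as np
import pytest

from strokect.phantom import make_ttc_slices
from strokect.ttc_quant import (
    calibrate,
    huang_threshold,
    isolate_slices,
    measure_slice,
    tissue_mask,
    ttc_volumes,
    TtcSliceRecord,
)
from .oracles import huang_exhaustive


class TestCalibrate:
    def test_definition(self):
        assert calibrate(10, 200) == pytest.approx(0.05)

    def test_area_scaling(self):
        mpp = calibrate(10, 200)
        assert 12000 * mpp**2 == pytest.approx(30.0)

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError):
            calibrate(10, 0)


class TestHuangThreshold:
    def test_bimodal_between_modes_and_matches_bruteforce(self):
        values = np.array([20] * 400 + [220] * 400)
        t = huang_threshold(values)
        assert 20 <= t < 220
        levels = np.arange(20, 221)
        hist = np.zeros(levels.size)
        hist[0] = 400
        hist[-1] = 400
        assert t == huang_exhaustive(levels, hist)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_on_random_8bit_histograms(self, seed):
        rng = np.random.default_rng(seed)
        values = np.concatenate(
            [
                rng.normal(60, 15, 500).clip(0, 255),
                rng.normal(190, 20, 300).clip(0, 255),
            ]
        ).round()
        t = huang_threshold(values)
        levels = np.arange(values.min(), values.max() + 1)
        hist = np.array([(values == g).sum() for g in levels], dtype=float)
        assert t == huang_exhaustive(levels, hist)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        values = np.concatenate(
            [rng.normal(50, 10, 400), rng.normal(150, 10, 400)]
        ).round()
        t1 = huang_threshold(values)
        t2 = huang_threshold(values + 30)
        assert t2 == pytest.approx(t1 + 30, abs=1)

    def test_constant_errors(self):
        with pytest.raises(ValueError):
            huang_threshold(np.full(100, 9.0))


class TestIsolateSlices:
    def test_finds_all_slices_near_truth_centroids(self):
        img, truth = make_ttc_slices(4, 0.2, seed=3)
        crops, centroids, origins = isolate_slices(img, 4)
        assert len(crops) == 4
        for (cy, cx), (ty, tx) in zip(centroids, truth.slice_centers):
            assert abs(cy - ty) <= 5 and abs(cx - tx) <= 5

    def test_single_slice_full_width_window(self):
        img, _ = make_ttc_slices(1, 0.0, seed=1)
        crops, _, _ = isolate_slices(img, 1)
        assert crops[0].shape[1] == img.shape[1]
        assert crops[0].shape[0] == img.shape[0]

    def test_blank_image_errors(self):
        blank = np.full((200, 100, 3), 240, dtype=np.uint8)
        with pytest.raises(ValueError, match="no slices found"):
            isolate_slices(blank, 2)


class TestMeasureSlice:
    def _crop_and_truth(self, n=1, infarct=0.0, seed=5):
        img, truth = make_ttc_slices(n, infarct, seed=seed)
        crops, _, origins = isolate_slices(img, n)
        return img, truth, crops, origins

    def test_symmetric_slice_equal_hemispheres(self):
        _, truth, crops, origins = self._crop_and_truth()
        midline = truth.midlines[0] - [0, origins[0][0]]
        rec = measure_slice(crops[0], midline, None, truth.mm_per_pixel)
        assert rec.area_infarct_mm2 == 0
        assert rec.area_contra_mm2 == pytest.approx(rec.area_ipsi_mm2, rel=0.02)

    def test_annotated_polygon_area(self):
        _, truth, crops, origins = self._crop_and_truth(infarct=0.2)
        midline = truth.midlines[0] - [0, origins[0][0]]
        poly = truth.infarct_polygons[0] - [0, origins[0][0]]
        rec = measure_slice(crops[0], midline, poly, truth.mm_per_pixel)
        assert rec.area_infarct_mm2 == pytest.approx(
            truth.areas_mm2[0]["infarct"], rel=0.05
        )

    def test_midline_missing_tissue_errors(self):
        _, truth, crops, origins = self._crop_and_truth()
        off_line = np.array([[1.0, 0.0], [1.0, crops[0].shape[0] - 1.0]])
        with pytest.raises(ValueError):
            measure_slice(crops[0], off_line, None, truth.mm_per_pixel)


class TestTtcVolumes:
    def _rec(self, label, contra, ipsi, infarct):
        return TtcSliceRecord(label, contra, ipsi, infarct, 0.05)

    def test_slab_summation(self):
        recs = [
            self._rec(f"s{i}", 30, 30, inf) for i, inf in enumerate([0, 5, 7, 0])
        ]
        out = ttc_volumes(recs, slab_mm=1.0)
        assert out["V_infarct_mm3"] == pytest.approx(12.0)

    def test_symmetric_slices_zero_edema(self):
        recs = [self._rec("a", 30, 30, 0), self._rec("b", 25, 25, 0)]
        assert ttc_volumes(recs)["edema_extent_percent"] == 0

    def test_permutation_invariance(self):
        recs = [self._rec("a", 30, 32, 2), self._rec("b", 25, 28, 3)]
        out1 = ttc_volumes(recs)
        out2 = ttc_volumes(recs[::-1])
        assert out1 == out2

    def test_area_scaling_with_calibration(self):
        # doubling mm-per-pixel quadruples pixel-derived areas; the
        # derived percentages are calibration-invariant
        img, truth = make_ttc_slices(2, 0.2, seed=8)
        crops, _, origins = isolate_slices(img, 2)
        recs = []
        for factor in (1.0, 2.0):
            rs = []
            for i, crop in enumerate(crops):
                midline = truth.midlines[i] - [0, origins[i][0]]
                poly = truth.infarct_polygons[i] - [0, origins[i][0]]
                rs.append(
                    measure_slice(
                        crop, midline, poly, truth.mm_per_pixel * factor,
                        slice_label=f"s{i}",
                    )
                )
            recs.append(ttc_volumes(rs))
        assert recs[1]["V_infarct_mm3"] == pytest.approx(
            4 * recs[0]["V_infarct_mm3"], rel=1e-6
        )
        assert recs[1]["corrected_lesion_percent"] == pytest.approx(
            recs[0]["corrected_lesion_percent"], rel=1e-6
        )

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            ttc_volumes([])


class TestTissueMask:
    def test_infarct_interior_filled(self):
        img, truth = make_ttc_slices(1, 0.25, seed=2)
        mask = tissue_mask(img)
        poly = truth.infarct_polygons[0]
        cx, cy = poly.mean(axis=0)
        assert mask[int(cy), int(cx)]
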