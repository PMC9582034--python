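"""TTC-stained slice photograph quantification.

Re-implements the semi-automated macro used on photographs of
2,3,5-triphenyltetrazolium-chloride (TTC) stained 1-mm brain slabs:
live tissue stains red, infarcted tissue stays white.  The pipeline is
millimetric calibration, slice isolation (red color gate -> Gaussian
blur sigma 10 -> Huang threshold -> fill holes -> dilation -> centroid
crops), per-slice hemisphere/infarct areas split by a manually drawn
midline, and 1-mm-slab volume summation with the same edema-correction
formulas as the 3-D workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .manual_quant import HemisphereVolumes, corrected_lesion_percent, edema_extent

__all__ = [
    "TtcSliceRecord",
    "calibrate",
    "tissue_confidence",
    "tissue_mask",
    "isolate_slices",
    "huang_threshold",
    "measure_slice",
    "ttc_volumes",
]

# red gate in HSV: hue within this distance of 0 (wrap-around) and
# saturation above the floor counts as stained tissue
RED_HUE_HALF_WIDTH = 0.10
SATURATION_FLOOR = 0.25


@dataclass
class TtcSliceRecord:
    """Calibrated areas for one TTC slice."""

    slice_label: str
    area_contra_mm2: float
    area_ipsi_mm2: float
    area_infarct_mm2: float
    mm_per_pixel: float

    def __post_init__(self) -> None:
        if min(self.area_contra_mm2, self.area_ipsi_mm2, self.area_infarct_mm2) < 0:
            raise ValueError("areas must be non-negative")
        if not self.mm_per_pixel > 0:
            raise ValueError("calibration must be positive")
        if self.area_infarct_mm2 > self.area_ipsi_mm2:
            import warnings

            warnings.warn(
                f"{self.slice_label}: infarct area exceeds ipsilateral area",
                stacklevel=2,
            )


def calibrate(reference_length_mm: float, reference_pixels: float) -> float:
    """mm-per-pixel from a millimetric reference captured in the photo."""
    if not (reference_length_mm > 0 and reference_pixels > 0):
        raise ValueError("reference length and pixel span must be positive")
    return reference_length_mm / reference_pixels


def tissue_confidence(image: np.ndarray) -> np.ndarray:
    """Red-tissue confidence in [0, 1] from an RGB image (HSV gate)."""
    from skimage.color import rgb2hsv

    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("expected an RGB image")
    hsv = rgb2hsv(image[..., :3])
    hue, sat = hsv[..., 0], hsv[..., 1]
    red = (hue <= RED_HUE_HALF_WIDTH) | (hue >= 1 - RED_HUE_HALF_WIDTH)
    return np.where(red & (sat >= SATURATION_FLOOR), sat, 0.0)


def huang_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Threshold minimizing Huang's fuzziness measure over the histogram.

    For each candidate threshold t the below/above class means define a
    membership u(g) = 1 / (1 + |g - mu_class| / C) with C the gray
    range; the Shannon entropy of u, histogram-weighted, is the measure
    of fuzziness, and the minimizing t is returned (as a gray level /
    bin center).
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < 2 or np.unique(values).size < 2:
        raise ValueError("huang_threshold needs at least 2 distinct values")
    if np.all(values == np.round(values)) and values.max() - values.min() < n_bins:
        levels = np.arange(int(values.min()), int(values.max()) + 1, dtype=np.float64)
        hist = np.bincount(
            (values - values.min()).astype(int), minlength=levels.size
        ).astype(np.float64)
    else:
        hist, edges = np.histogram(values, bins=n_bins)
        levels = 0.5 * (edges[:-1] + edges[1:])
        hist = hist.astype(np.float64)

    c = levels[-1] - levels[0]
    w = np.cumsum(hist)
    m = np.cumsum(hist * levels)
    w_tot, m_tot = w[-1], m[-1]

    best_t, best_e = levels[0], np.inf
    for k in range(levels.size - 1):  # threshold after bin k
        w0, w1 = w[k], w_tot - w[k]
        if w0 == 0 or w1 == 0:
            continue
        mu0 = m[k] / w0
        mu1 = (m_tot - m[k]) / w1
        mu = np.where(levels <= levels[k], mu0, mu1)
        u = 1.0 / (1.0 + np.abs(levels - mu) / c)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        entropy = -(u * np.log(u) + (1 - u) * np.log(1 - u))
        e = float(np.sum(hist * entropy))
        if e < best_e:
            best_e, best_t = e, levels[k]
    return float(best_t)


def tissue_mask(image: np.ndarray, gaussian_sigma: float = 10.0) -> np.ndarray:
    """Binary tissue mask: color gate, blur, Huang threshold, fill, dilate."""
    conf = tissue_confidence(image)
    blurred = ndimage.gaussian_filter(conf, gaussian_sigma)
    if np.unique(blurred).size < 2:
        return np.zeros(conf.shape, dtype=bool)
    t = huang_threshold(blurred)
    mask = blurred > t
    mask = ndimage.binary_fill_holes(mask)
    return ndimage.binary_dilation(mask, structure=np.ones((3, 3), dtype=bool))


def isolate_slices(
    image: np.ndarray, n_slices: int, gaussian_sigma: float = 10.0
) -> tuple[list[np.ndarray], list[tuple[float, float]], list[tuple[int, int]]]:
    """Find the slices of a composite photo and crop a window around each.

    Returns ``(crops, centroids, origins)``: the ``n_slices`` largest
    tissue components' centroids sorted by vertical position, crops of
    size ``(full width, height // n_slices)`` centered at each centroid
    and clamped to the image bounds, and each crop's (row, col) origin
    in the composite.
    """
    image = np.asarray(image)
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    mask = tissue_mask(image, gaussian_sigma)
    labels, n_found = ndimage.label(mask)
    if n_found < n_slices:
        raise ValueError(
            f"no slices found: expected {n_slices}, detected {n_found} components"
        )
    sizes = ndimage.sum_labels(
        np.ones_like(labels), labels, index=np.arange(1, n_found + 1)
    )
    keep = np.argsort(sizes)[-n_slices:] + 1
    centroids = ndimage.center_of_mass(mask, labels, index=keep)
    centroids = sorted(centroids, key=lambda c: c[0])

    h, w = image.shape[:2]
    crop_h = h // n_slices
    crops, origins = [], []
    for cy, _cx in centroids:
        top = int(round(cy - crop_h / 2))
        top = min(max(top, 0), h - crop_h)
        crops.append(image[top : top + crop_h, 0:w])
        origins.append((top, 0))
    return crops, centroids, origins


def _polyline_side(points: np.ndarray, midline: np.ndarray) -> np.ndarray:
    """Signed side of each point w.r.t. its nearest midline segment.

    Positive = right of the downward-directed polyline.  Points exactly
    on the line get sign 0.
    """
    midline = np.asarray(midline, dtype=np.float64)  # (m, 2) as (x, y)
    if midline.ndim != 2 or midline.shape[0] < 2:
        raise ValueError("midline must be a polyline of >= 2 (x, y) points")
    p = points.astype(np.float64)  # (n, 2) as (x, y)
    best_d2 = np.full(len(p), np.inf)
    best_side = np.zeros(len(p))
    for a, b in zip(midline[:-1], midline[1:]):
        ab = b - a
        denom = ab @ ab
        if denom == 0:
            continue
        t = np.clip(((p - a) @ ab) / denom, 0, 1)
        proj = a + t[:, None] * ab
        d2 = ((p - proj) ** 2).sum(axis=1)
        cross = ab[0] * (p[:, 1] - a[1]) - ab[1] * (p[:, 0] - a[0])
        closer = d2 < best_d2
        best_d2 = np.where(closer, d2, best_d2)
        best_side = np.where(closer, -cross, best_side)
    return best_side


def measure_slice(
    crop: np.ndarray,
    midline: np.ndarray,
    infarct_roi: np.ndarray | None,
    mm_per_pixel: float,
    gaussian_sigma: float = 10.0,
    ipsilateral_side: str = "right",
    slice_label: str = "slice",
) -> TtcSliceRecord:
    """Hemisphere and infarct areas of one cropped slice.

    ``midline`` is a polyline of (x, y) points ordered top to bottom;
    tissue pixels are assigned to a hemisphere by the signed side of the
    nearest segment (pixels exactly on the line count as contralateral).
    ``infarct_roi`` is a polygon of (x, y) vertices, or None for no
    infarct.
    """
    mask = tissue_mask(crop, gaussian_sigma)
    if not mask.any():
        raise ValueError("no tissue found in crop")
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([cols, rows])  # (x, y)
    side = _polyline_side(pts, midline)
    n_right = int((side > 0).sum())
    n_left = int((side <= 0).sum())
    if n_right == 0 or n_left == 0:
        raise ValueError("midline does not bisect the tissue mask")
    if ipsilateral_side == "right":
        n_ipsi, n_contra = n_right, n_left
    else:
        n_ipsi, n_contra = n_left, n_right

    area_infarct = 0.0
    if infarct_roi is not None:
        from skimage.draw import polygon

        poly = np.asarray(infarct_roi, dtype=np.float64)
        rr, cc = polygon(poly[:, 1], poly[:, 0], shape=mask.shape)
        area_infarct = len(rr) * mm_per_pixel**2

    return TtcSliceRecord(
        slice_label=slice_label,
        area_contra_mm2=n_contra * mm_per_pixel**2,
        area_ipsi_mm2=n_ipsi * mm_per_pixel**2,
        area_infarct_mm2=area_infarct,
        mm_per_pixel=mm_per_pixel,
    )


def ttc_volumes(records: list[TtcSliceRecord], slab_mm: float = 1.0) -> dict:
    """Slab volumes and edema-corrected infarct metrics from slice records.

    Each slice represents a ``slab_mm``-thick slab; volumes are the sum
    of areas times the slab thickness.  Edema extent and the corrected
    lesion percentage reuse the 3-D formulas with these volumes.
    """
    if not records:
        raise ValueError("no slice records")
    v_contra = sum(r.area_contra_mm2 for r in records) * slab_mm
    v_ipsi = sum(r.area_ipsi_mm2 for r in records) * slab_mm
    v_infarct = sum(r.area_infarct_mm2 for r in records) * slab_mm
    h = HemisphereVolumes(V_ipsilateral=v_ipsi, V_contralateral=v_contra)
    return {
        "V_contralateral_mm3": v_contra,
        "V_ipsilateral_mm3": v_ipsi,
        "V_infarct_mm3": v_infarct,
        "edema_extent_percent": edema_extent(h),
        "corrected_lesion_percent": corrected_lesion_percent(h, v_infarct),
    }
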