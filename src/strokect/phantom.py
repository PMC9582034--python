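"""Synthetic brain phantoms and TTC slice photographs with ground truth.

Every downstream module is testable without any scan data: the phantom
emulates the salient features of a contrast-stained mouse brain in
micro-CT — two roughly symmetric bright hemispheres on a dark
background, smooth multiplicative tissue texture, bright curvilinear
fiber bundles confined to a striatum-like box, and (optionally) a
darker lesion region with a still-darker core.

Ground-truth lesions are 3-D Gaussian-smoothed random blobs, *not* the
2-D concentric-disc shapes the training simulator uses, so pipeline
validation is not circular.  All generators are pure functions of
(spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .lesion_sim import LesionSimParams
from .volume_io import IntensityVolume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "TtcTruth",
    "make_brain_phantom",
    "make_lesioned_phantom",
    "make_ttc_slices",
]

BACKGROUND_FRACTION = 0.02  # air + wrapping film, ~2% of tissue intensity


@dataclass
class PhantomSpec:
    """Geometry, intensity and texture parameters of the brain phantom."""

    shape: tuple[int, int, int] = (32, 96, 128)
    voxel_size_um: float = 30.0
    hemisphere_intensity: float = 200.0
    texture_sigma: float = 3.0
    texture_amplitude: float = 0.04
    striatum_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] | None = None
    fiber_count: int = 12
    fiber_intensity_gain: float = 1.5
    fiber_radius_vox: float = 1.5
    fiber_target_fraction: float | None = None
    ipsi_fiber_radius_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 16:
            raise ValueError("each phantom axis must be >= 16")
        if self.fiber_intensity_gain < 1:
            raise ValueError("fiber_intensity_gain must be >= 1")


@dataclass
class PhantomTruth:
    """Ground-truth masks and volumes accompanying a phantom."""

    brain_mask: np.ndarray
    left_mask: np.ndarray
    right_mask: np.ndarray
    striatum_masks: tuple[np.ndarray, np.ndarray]
    fiber_mask: np.ndarray
    lesion_mask: np.ndarray
    core_mask: np.ndarray
    true_volumes_mm3: dict[str, float] = field(default_factory=dict)
    midline_column: int = 0


def _hemisphere_masks(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Two mirrored half-ellipsoids separated by a 2-voxel fissure."""
    z, y, x = shape
    mid = x // 2
    zz, yy, xx = np.ogrid[:z, :y, :x]
    cz, cy = (z - 1) / 2, (y - 1) / 2
    az, ay, ax = 0.42 * z, 0.42 * y, 0.46 * x
    ellipsoid = (
        ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - (mid - 0.5)) / ax) ** 2
    ) <= 1.0
    left = ellipsoid & (xx <= mid - 2)
    right = np.zeros_like(left)
    right[:, :, mid:] = left[:, :, mid - 1 :: -1][:, :, : x - mid]
    return left, right


def _default_striatum_box(shape, left_mask):
    """Axis-aligned box well inside the left hemisphere."""
    z, y, x = shape
    mid = x // 2
    return (
        (int(0.30 * z), int(0.70 * z)),
        (int(0.32 * y), int(0.68 * y)),
        (int(mid * 0.30), int(mid * 0.75)),
    )


def _random_fiber_curve(rng, box, n_control=4, n_samples=200):
    """Dense polyline through random control points inside the box."""
    ctrl = np.stack(
        [rng.uniform(lo + 1, hi - 1, n_control) for (lo, hi) in box], axis=1
    )
    # midpoint-refine twice for a smoother path than raw segments
    for _ in range(2):
        mids = 0.5 * (ctrl[:-1] + ctrl[1:])
        out = np.empty((ctrl.shape[0] + mids.shape[0], 3))
        out[0::2] = ctrl
        out[1::2] = mids
        ctrl = out
    t = np.linspace(0, 1, n_samples)
    seg = np.linspace(0, 1, ctrl.shape[0])
    return np.stack([np.interp(t, seg, ctrl[:, d]) for d in range(3)], axis=1)


def _paint_tube(mask: np.ndarray, curve: np.ndarray, radius: float) -> None:
    shape = np.array(mask.shape)
    r = int(np.ceil(radius))
    for p in curve:
        c = np.round(p).astype(int)
        lo = np.maximum(c - r, 0)
        hi = np.minimum(c + r + 1, shape)
        if (lo >= hi).any():
            continue
        sub = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))
        grid = np.ogrid[sub]
        dist2 = sum((g - pi) ** 2 for g, pi in zip(grid, p))
        mask[sub] |= dist2 <= radius**2


def _make_fibers(spec: PhantomSpec, rng, box, mid: int):
    """Fiber tube masks for both hemispheres.

    The right hemisphere carries the mirror image of the left-side
    curves; with ``ipsi_fiber_radius_scale < 1`` its tubes are painted
    at a reduced radius (fiber thinning on the stroke side).
    """
    shape = spec.shape
    left_f = np.zeros(shape, dtype=bool)
    right_f = np.zeros(shape, dtype=bool)
    if spec.fiber_count == 0:
        return left_f, right_f
    box_vol = np.prod([hi - lo for lo, hi in box])
    target = spec.fiber_target_fraction
    max_fibers = spec.fiber_count if target is None else max(spec.fiber_count, 200)
    right_radius = spec.fiber_radius_vox * spec.ipsi_fiber_radius_scale
    for _ in range(max_fibers):
        if target is not None and left_f.sum() / box_vol >= target:
            break
        curve = _random_fiber_curve(rng, box)
        _paint_tube(left_f, curve, spec.fiber_radius_vox)
        mirrored = curve.copy()
        mirrored[:, 2] = 2 * mid - 1 - curve[:, 2]
        _paint_tube(right_f, mirrored, right_radius)
    return left_f, right_f


def make_brain_phantom(spec: PhantomSpec) -> tuple[IntensityVolume, PhantomTruth]:
    """Healthy two-hemisphere phantom with texture and striatal fibers."""
    rng = np.random.default_rng(spec.seed)
    z, y, x = spec.shape
    mid = x // 2
    left, right = _hemisphere_masks(spec.shape)
    brain = left | right

    box = spec.striatum_box or _default_striatum_box(spec.shape, left)
    left_f, right_f = _make_fibers(spec, rng, box, mid)
    fiber_mask = (left_f | right_f) & brain

    striatum_left = np.zeros(spec.shape, dtype=bool)
    striatum_left[
        box[0][0] : box[0][1], box[1][0] : box[1][1], box[2][0] : box[2][1]
    ] = True
    striatum_left &= left
    striatum_right = np.zeros_like(striatum_left)
    striatum_right[:, :, mid:] = striatum_left[:, :, mid - 1 :: -1][:, :, : x - mid]

    # smooth multiplicative texture, mirror-symmetric about the midline
    noise = rng.standard_normal((z, y, mid))
    noise = ndimage.gaussian_filter(noise, spec.texture_sigma)
    noise /= max(noise.std(), 1e-9)
    texture_half = 1.0 + spec.texture_amplitude * noise
    texture = np.empty((z, y, x))
    texture[:, :, :mid] = texture_half
    texture[:, :, mid:] = texture_half[:, :, ::-1][:, :, : x - mid]

    vol = np.full(spec.shape, BACKGROUND_FRACTION * spec.hemisphere_intensity)
    vol += rng.normal(0, 0.005 * spec.hemisphere_intensity, spec.shape)
    vol = np.clip(vol, 0, None)
    vol[brain] = spec.hemisphere_intensity * texture[brain]
    vol[fiber_mask] *= spec.fiber_intensity_gain

    voxel_mm3 = (spec.voxel_size_um / 1000.0) ** 3
    truth = PhantomTruth(
        brain_mask=brain,
        left_mask=left,
        right_mask=right,
        striatum_masks=(striatum_left, striatum_right),
        fiber_mask=fiber_mask,
        lesion_mask=np.zeros(spec.shape, dtype=bool),
        core_mask=np.zeros(spec.shape, dtype=bool),
        true_volumes_mm3={
            "brain": brain.sum() * voxel_mm3,
            "left": left.sum() * voxel_mm3,
            "right": right.sum() * voxel_mm3,
            "striatum_left": striatum_left.sum() * voxel_mm3,
            "striatum_right": striatum_right.sum() * voxel_mm3,
            "fibers": fiber_mask.sum() * voxel_mm3,
            "fibers_left": (fiber_mask & left).sum() * voxel_mm3,
            "fibers_right": (fiber_mask & right).sum() * voxel_mm3,
            "lesion": 0.0,
            "core": 0.0,
        },
        midline_column=mid,
    )
    return IntensityVolume(vol, spec.voxel_size_um, provenance="phantom"), truth


def _random_blob(
    shape, center, radius, rng, roughness=0.35, smooth_sigma=3.0
) -> np.ndarray:
    """Gaussian-smoothed random blob: a noisy level set around a sphere."""
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    dist = np.sqrt(
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    )
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_sigma)
    noise /= max(noise.std(), 1e-9)
    level = radius - dist + roughness * radius * noise
    return level > 0


def make_lesioned_phantom(
    spec: PhantomSpec,
    lesion: LesionSimParams,
    seed: int,
    lesion_radius_fraction: float = 0.7,
    core_radius_fraction: float = 0.5,
) -> tuple[IntensityVolume, PhantomTruth]:
    """Healthy phantom with a ground-truth blob lesion in the right hemisphere.

    The darkening follows the training simulator's intensity model —
    multiplicative drops drawn from ``lesion``'s ranges, core on top of
    lesion — but the *shape* is an independently parameterized 3-D
    smoothed random blob, so validating the segmentation against this
    phantom does not test the simulator against itself.
    ``core_radius_fraction=0`` produces an empty core.
    """
    healthy_vol, truth = make_brain_phantom(spec)
    rng = np.random.default_rng(seed)

    z, y, x = spec.shape
    mid = x // 2
    right = truth.right_mask
    # place the blob around the right hemisphere's center of mass
    center = np.array(ndimage.center_of_mass(right))
    half_width = (x - mid) / 2
    radius = lesion_radius_fraction * min(z / 2, y / 2, half_width)
    center = center + rng.uniform(-0.15, 0.15, 3) * np.array([z, y, half_width])

    lesion_mask = _random_blob(spec.shape, center, radius, rng) & right
    if core_radius_fraction > 0:
        core_mask = (
            _random_blob(spec.shape, center, radius * core_radius_fraction, rng)
            & lesion_mask
        )
    else:
        core_mask = np.zeros(spec.shape, dtype=bool)
    if not lesion_mask.any():
        raise ValueError("lesion does not fit in the hemisphere")

    d_l = rng.uniform(*lesion.lesion_intensity_drop_range)
    d_c = rng.uniform(*lesion.core_extra_drop_range)
    # darken exactly the truth masks: the blob boundary is already
    # irregular, and any soft shell outside the mask would be genuinely
    # darkened tissue that the truth bookkeeping refuses to count
    data = healthy_vol.data * (1 - d_l * lesion_mask) * (1 - d_c * core_mask)

    voxel_mm3 = (spec.voxel_size_um / 1000.0) ** 3
    truth.lesion_mask = lesion_mask
    truth.core_mask = core_mask
    truth.true_volumes_mm3["lesion"] = lesion_mask.sum() * voxel_mm3
    truth.true_volumes_mm3["core"] = core_mask.sum() * voxel_mm3
    truth.true_volumes_mm3["lesion_drop"] = float(d_l)
    truth.true_volumes_mm3["core_extra_drop"] = float(d_c)
    return (
        IntensityVolume(data, spec.voxel_size_um, provenance="phantom-lesioned"),
        truth,
    )


@dataclass
class TtcTruth:
    """Ground truth for a synthetic TTC composite photograph."""

    mm_per_pixel: float
    slice_centers: list[tuple[float, float]]
    midlines: list[np.ndarray]
    infarct_polygons: list[np.ndarray | None]
    areas_mm2: list[dict[str, float]]
    ruler_span_px: float
    ruler_span_mm: float


def _ellipse_mask(shape, center, a, b):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((xx - center[0]) / a) ** 2 + ((yy - center[1]) / b) ** 2 <= 1.0


def make_ttc_slices(
    n_slices: int,
    infarct_fraction: float,
    mm_per_pixel: float = 0.05,
    seed: int = 0,
    slice_height_px: int = 160,
    width_px: int = 220,
) -> tuple[np.ndarray, TtcTruth]:
    """Composite photo of red elliptical slices with a pale infarct.

    ``infarct_fraction`` is the infarct's share of the ipsilateral
    (right) hemisphere area on each slice.  A millimetric ruler band is
    printed at the bottom.  Truth areas are rasterized pixel counts
    times ``mm_per_pixel**2``.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if not 0 <= infarct_fraction <= 0.6:
        raise ValueError("infarct_fraction exceeds hemisphere area capacity")
    rng = np.random.default_rng(seed)
    h, w = n_slices * slice_height_px, width_px
    img = np.full((h, w, 3), 240, dtype=np.uint8)
    img += rng.integers(0, 3, img.shape, dtype=np.uint8)

    tissue_rgb = np.array([185, 40, 45], dtype=np.uint8)
    infarct_rgb = np.array([236, 226, 214], dtype=np.uint8)

    centers, midlines, polys, areas = [], [], [], []
    for s in range(n_slices):
        cy = (s + 0.5) * slice_height_px
        cx = w / 2 + rng.uniform(-3, 3)
        a = 0.36 * w * rng.uniform(0.92, 1.0)
        b = 0.38 * slice_height_px * rng.uniform(0.92, 1.0)
        tissue = _ellipse_mask((h, w), (cx, cy), a, b)

        infarct = np.zeros((h, w), dtype=bool)
        poly = None
        if infarct_fraction > 0:
            half_area = np.pi * a * b / 2
            ai0, bi0 = 0.40 * a, 0.62 * b
            scale = np.sqrt(infarct_fraction * half_area / (np.pi * ai0 * bi0))
            ai, bi = ai0 * scale, bi0 * scale
            icx = cx + 0.45 * a
            if icx + ai > cx + a or bi > b:
                raise ValueError("infarct_fraction exceeds hemisphere area capacity")
            infarct = _ellipse_mask((h, w), (icx, cy), ai, bi) & tissue
            theta = np.linspace(0, 2 * np.pi, 120, endpoint=False)
            poly = np.column_stack(
                [icx + ai * np.cos(theta), cy + bi * np.sin(theta)]
            )

        img[tissue] = tissue_rgb
        img[infarct] = infarct_rgb

        left = tissue & (np.arange(w)[None, :] < cx)
        right = tissue & ~left
        areas.append(
            {
                "contra": float(left.sum()) * mm_per_pixel**2,
                "ipsi": float(right.sum()) * mm_per_pixel**2,
                "infarct": float(infarct.sum()) * mm_per_pixel**2,
            }
        )
        centers.append((cy, cx))
        midlines.append(
            np.array([[cx, cy - b - 4], [cx, cy + b + 4]], dtype=np.float64)
        )
        polys.append(poly)

    # ruler band: 10 mm of 1-mm black ticks on white, bottom-left corner
    ruler_mm = 10.0
    px_per_mm = 1.0 / mm_per_pixel
    band_h = max(6, int(0.04 * slice_height_px))
    y0 = h - band_h
    x1 = int(ruler_mm * px_per_mm) + 8
    img[y0:, :x1] = 250
    for k in range(int(ruler_mm) + 1):
        xt = int(4 + k * px_per_mm)
        if xt < w:
            img[y0:, xt : xt + 1] = 10

    truth = TtcTruth(
        mm_per_pixel=mm_per_pixel,
        slice_centers=centers,
        midlines=midlines,
        infarct_polygons=polys,
        areas_mm2=areas,
        ruler_span_px=ruler_mm * px_per_mm,
        ruler_span_mm=ruler_mm,
    )
    return img, truth
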