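"""From restored slices to 3-D lesion/core masks and volumes.

Subtracting each lesioned cross-section from its restoration yields a
lesion probability map.  The map is thresholded in the whole 3-D volume
with Li's minimum-cross-entropy method; the core uses a threshold 1.5x
larger (T_core = 3/2 T_lesion).  The largest 26-connected component is
kept for each mask, masks are upsampled in-plane by bicubic
interpolation of the indicator (re-binarized at 0.5), and volumes are
reported in mm^3 at the native scan voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SegmentationThresholds",
    "SegmentationResult",
    "probability_map",
    "li_threshold",
    "segment",
    "dice",
]

CORE_THRESHOLD_FACTOR = 1.5  # T_core = (3/2) T_lesion


@dataclass
class SegmentationThresholds:
    T_lesion: float
    T_core: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.T_lesion) and np.isfinite(self.T_core)):
            raise ValueError("thresholds must be finite")


@dataclass
class SegmentationResult:
    lesion_mask: np.ndarray
    core_mask: np.ndarray
    thresholds: SegmentationThresholds
    lesion_volume_mm3: float
    core_volume_mm3: float


def probability_map(restored: np.ndarray, lesioned: np.ndarray) -> np.ndarray:
    """Voxelwise (restored - lesioned), clamped below at zero.

    Both inputs are stacks of matched 2-D grids (or equal-shaped 3-D
    arrays); the result is stacked along z.
    """
    restored = np.asarray(restored, dtype=np.float64)
    lesioned = np.asarray(lesioned, dtype=np.float64)
    if restored.shape != lesioned.shape:
        raise ValueError("restored and lesioned shapes must match")
    return np.clip(restored - lesioned, 0.0, None)


def _cross_entropy(values: np.ndarray, t: float) -> float:
    below = values[values <= t]
    above = values[values > t]
    if below.size == 0 or above.size == 0:
        return np.inf
    return -(
        below.sum() * np.log(below.mean()) + above.sum() * np.log(above.mean())
    )


def li_threshold(values: np.ndarray, tol: float = 1e-6, max_iter: int = 200) -> float:
    """Minimum-cross-entropy threshold (Li & Lee fixed-point iteration).

    Iterates ``t <- (mu_below - mu_above) / (ln mu_below - ln mu_above)``
    where the class means are taken over values <= t and > t, starting
    from the mean, until the update is below ``tol``.  The converged
    value is then snapped to the best of the nearby inter-value cut
    points: the continuous fixed point can sit one bin away from the
    discrete criterion minimum.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    uniq = np.unique(values)
    if values.size < 2 or uniq.size < 2:
        raise ValueError("li_threshold needs at least 2 distinct values")
    t = values.mean()
    for _ in range(max_iter):
        below = values[values <= t]
        above = values[values > t]
        if below.size == 0 or above.size == 0:
            break
        mu_b = below.mean()
        mu_a = above.mean()
        if mu_b <= 0:
            # cross entropy is undefined for a zero-mean class; nudge
            mu_b = np.finfo(float).tiny
        t_new = (mu_b - mu_a) / (np.log(mu_b) - np.log(mu_a))
        if abs(t_new - t) < tol:
            t = t_new
            break
        t = t_new
    # local discrete refinement around the fixed point
    cuts = 0.5 * (uniq[:-1] + uniq[1:])
    idx = int(np.searchsorted(cuts, t))
    window = cuts[max(0, idx - 3) : idx + 3]
    candidates = np.append(window, t)
    scores = [_cross_entropy(values, c) for c in candidates]
    return float(candidates[int(np.argmin(scores))])


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 26-connected component of a 3-D boolean mask."""
    if not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n == 1:
        return labels == 1
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _upsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """In-plane bicubic upsampling of the {0,1} indicator, cut at 0.5."""
    if factor == 1:
        return mask.astype(bool)
    field = ndimage.zoom(
        mask.astype(np.float64), (1, factor, factor), order=3, grid_mode=True,
        mode="grid-constant",
    )
    return field >= 0.5


def segment(
    prob: np.ndarray,
    upsample_factor: int = 1,
    voxel_size_um: float = 3.0,
) -> SegmentationResult:
    """Threshold a 3-D probability map into lesion and core masks.

    ``T_lesion`` is the Li threshold of the map's strictly positive
    values; ``T_core = 1.5 T_lesion``.  Each candidate mask keeps only
    its largest 26-connected component, is upsampled in-plane by
    ``upsample_factor``, and volumes use the native (pre-downsampling)
    voxel size, in mm^3.  An empty lesion yields an empty result with
    zero volumes (a signal, not an error).
    """
    prob = np.asarray(prob, dtype=np.float64)
    if prob.ndim != 3:
        raise ValueError("probability map must be 3-D")
    if upsample_factor < 1:
        raise ValueError("upsample_factor must be >= 1")
    positives = prob[prob > 0]
    if positives.size < 2 or np.unique(positives).size < 2:
        t_lesion = np.inf  # nothing to segment
    else:
        t_lesion = li_threshold(positives)
    t_core = CORE_THRESHOLD_FACTOR * t_lesion

    lesion = _largest_component(prob >= t_lesion)
    core = _largest_component(prob >= t_core)
    if core.any() and not (core <= lesion).all():
        import warnings

        warnings.warn(
            "largest core component is not contained in the lesion component",
            stacklevel=2,
        )

    lesion_up = _upsample_mask(lesion, upsample_factor)
    core_up = _upsample_mask(core, upsample_factor)
    voxel_mm3 = (voxel_size_um / 1000.0) ** 3
    if not np.isfinite(t_lesion):
        thresholds = SegmentationThresholds(0.0, 0.0)
    else:
        thresholds = SegmentationThresholds(float(t_lesion), float(t_core))
    return SegmentationResult(
        lesion_mask=lesion_up,
        core_mask=core_up,
        thresholds=thresholds,
        lesion_volume_mm3=float(lesion_up.sum() * voxel_mm3),
        core_volume_mm3=float(core_up.sum() * voxel_mm3),
    )


def segment_brain(
    vol,
    model,
    midline_column: int,
    crop_shape: tuple[int, int],
    downsample_factor: int = 1,
    ipsilateral: str = "right",
):
    """Run the full automatic pipeline on a whole-brain volume.

    Splits the brain at the midline, normalizes the ipsilateral
    hemisphere stack, restores every cross-section with the trained
    model, forms the probability map and segments it.  Returns
    ``(SegmentationResult, prob_map, HemispherePair)``; the masks live
    in the (downsampled, mirrored) ipsilateral hemisphere frame and the
    volumes are reported at the native voxel size after in-plane
    upsampling by ``downsample_factor``.
    """
    from .restoration_net import normalize_stack, restore
    from .volume_io import split_hemispheres

    pair = split_hemispheres(
        vol, midline_column, crop_shape, downsample_factor, ipsilateral=ipsilateral
    )
    stack = normalize_stack(pair.ipsilateral.data)
    restored = np.stack([restore(model, s) for s in stack])
    prob = probability_map(restored, stack)
    result = segment(
        prob,
        upsample_factor=downsample_factor,
        voxel_size_um=vol.voxel_size_um,
    )
    return result, prob, pair


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks (1.0 when both are empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
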