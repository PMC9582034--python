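"""Stroke-lesion simulation on healthy hemisphere cross-sections.

The unsupervised segmentation model is trained without any annotated
lesions: instead, lesion-like darkenings are synthesised on healthy 2-D
cross-sections.  A lesion is two concentric discs — the outer disc is the
whole lesion, the inner disc the core — warped by an elastic transform,
softened by a Gaussian blur of the disc masks, and applied as a
multiplicative intensity drop: random 0–50% inside the lesion and a
further 0–50% inside the core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

__all__ = ["LesionSimParams", "elastic_deform", "simulate_lesion"]


@dataclass
class LesionSimParams:
    """Randomisation ranges of the lesion simulator.

    Defaults follow the training recipe: outer radius 20–80 px, inner
    radius 0–50% of the outer, intensity drop 0–50% in the lesion and a
    further 0–50% in the core, blur sigma 5–20 px, elastic transform with
    alpha 120 and sigma 5.
    """

    outer_radius_range: tuple[int, int] = (20, 80)
    inner_radius_fraction_range: tuple[float, float] = (0.0, 0.5)
    lesion_intensity_drop_range: tuple[float, float] = (0.0, 0.5)
    core_extra_drop_range: tuple[float, float] = (0.0, 0.5)
    blur_sigma_range: tuple[float, float] = (5.0, 20.0)
    elastic_alpha: float = 120.0
    elastic_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "outer_radius_range",
            "inner_radius_fraction_range",
            "lesion_intensity_drop_range",
            "core_extra_drop_range",
            "blur_sigma_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy min <= max")

    def scaled(self, factor: float) -> "LesionSimParams":
        """Rescale pixel-valued ranges for smaller working resolutions."""
        return LesionSimParams(
            outer_radius_range=(
                max(1, round(self.outer_radius_range[0] * factor)),
                max(1, round(self.outer_radius_range[1] * factor)),
            ),
            inner_radius_fraction_range=self.inner_radius_fraction_range,
            lesion_intensity_drop_range=self.lesion_intensity_drop_range,
            core_extra_drop_range=self.core_extra_drop_range,
            blur_sigma_range=(
                max(0.5, self.blur_sigma_range[0] * factor),
                max(0.5, self.blur_sigma_range[1] * factor),
            ),
            elastic_alpha=self.elastic_alpha * factor,
            elastic_sigma=max(1.0, self.elastic_sigma * factor),
            seed=self.seed,
        )


def _displacement_field(
    shape: tuple[int, int], alpha: float, sigma: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis i.i.d. uniform(-1,1) fields, Gaussian-smoothed and scaled."""
    dy = gaussian_filter(rng.uniform(-1, 1, shape), sigma, mode="reflect") * alpha
    dx = gaussian_filter(rng.uniform(-1, 1, shape), sigma, mode="reflect") * alpha
    return dy, dx


def elastic_deform(
    image: np.ndarray,
    alpha: float,
    sigma: float,
    rng: np.random.Generator,
    displacement: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Warp a 2-D image with a random smooth displacement field.

    A uniform(-1, 1) displacement is drawn independently per axis,
    convolved with a Gaussian of standard deviation ``sigma``, scaled by
    ``alpha``, and the image is resampled at the displaced coordinates by
    bilinear interpolation with edge clamping.  A precomputed
    ``displacement`` may be supplied so that several masks share one warp.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D grid")
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if displacement is None:
        displacement = _displacement_field(image.shape, alpha, sigma, rng)
    dy, dx = displacement
    yy, xx = np.meshgrid(
        np.arange(image.shape[0]), np.arange(image.shape[1]), indexing="ij"
    )
    coords = np.stack([yy + dy, xx + dx])
    return map_coordinates(image, coords, order=1, mode="nearest")


def _disc(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), indexing="ij"
    )
    return ((yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2).astype(
        np.float64
    )


def simulate_lesion(
    image: np.ndarray,
    params: LesionSimParams,
    rng: np.random.Generator,
    *,
    force_drops: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Darken a healthy cross-section with a simulated lesion and core.

    Draws a center uniformly in the image, an outer radius, an inner
    radius as a fraction of the outer, rasterises both discs, warps both
    with one shared elastic field, blurs both with one shared Gaussian
    sigma into soft weights ``w_lesion, w_core in [0, 1]``, then applies

    ``out = image * (1 - d_l * w_lesion) * (1 - d_c * w_core)``

    with drops ``d_l, d_c`` drawn from the configured ranges
    (overridable through ``force_drops`` for controlled experiments).

    Returns ``(lesioned, w_lesion, w_core)``.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    shape = image.shape

    center = (rng.uniform(0, shape[0] - 1), rng.uniform(0, shape[1] - 1))
    r_out = rng.uniform(*params.outer_radius_range)
    r_in = r_out * rng.uniform(*params.inner_radius_fraction_range)
    blur_sigma = rng.uniform(*params.blur_sigma_range)
    if force_drops is None:
        d_l = rng.uniform(*params.lesion_intensity_drop_range)
        d_c = rng.uniform(*params.core_extra_drop_range)
    else:
        d_l, d_c = force_drops

    outer = _disc(shape, center, r_out)
    inner = _disc(shape, center, r_in)
    # one elastic field for both discs keeps the core inside the lesion
    displacement = _displacement_field(
        shape, params.elastic_alpha, params.elastic_sigma, rng
    )
    outer = elastic_deform(outer, params.elastic_alpha, params.elastic_sigma, rng,
                           displacement=displacement)
    inner = elastic_deform(inner, params.elastic_alpha, params.elastic_sigma, rng,
                           displacement=displacement)
    w_lesion = np.clip(gaussian_filter(outer, blur_sigma, mode="constant"), 0, 1)
    w_core = np.clip(gaussian_filter(inner, blur_sigma, mode="constant"), 0, 1)

    lesioned = image * (1 - d_l * w_lesion) * (1 - d_c * w_core)
    return lesioned, w_lesion, w_core
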