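"""Manual-ROI volumetry: interpolation, edema extent, corrected lesion.

Hemispheres, total lesion and core are delineated on every k-th
transaxial slice (k = 10 in the reference workflow); intermediate slices
are densified by shape-based interpolation of signed distance fields.
Volumes then feed two formulas:

``edema extent (%) = (V_ipsi - V_contra) / V_contra * 100``

``corrected lesion (% of brain) = V_lesion * (V_contra / V_ipsi) / V_brain * 100``

with ``V_brain = V_contra + V_ipsi``.  The edema correction rescales the
swollen ipsilateral side by the contra/ipsi ratio so swelling does not
inflate the lesion percentage; with no edema it collapses to the plain
lesion fraction.  The same formula applied to the core gives the core
percentage; penumbra = lesion - core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "RoiSeries",
    "HemisphereVolumes",
    "LesionVolumes",
    "interpolate_roi",
    "edema_extent",
    "corrected_lesion_percent",
    "quantify_manual",
]

REGION_NAMES = (
    "hemisphere-ipsi",
    "hemisphere-contra",
    "lesion",
    "core",
    "caudate-putamen",
)


@dataclass
class RoiSeries:
    """Sparse per-slice binary annotations for one region."""

    region_name: str
    annotations: dict[int, np.ndarray]
    stride: int = 10
    dense_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        indices = sorted(self.annotations)
        if indices != list(self.annotations):
            self.annotations = {i: self.annotations[i] for i in indices}
        shapes = {np.asarray(m).shape for m in self.annotations.values()}
        if len(shapes) > 1:
            raise ValueError("all annotated masks must share in-plane shape")
        self.annotations = {
            i: np.asarray(m, dtype=bool) for i, m in self.annotations.items()
        }


@dataclass
class HemisphereVolumes:
    """Hemisphere volumes in um^3; V_brain is their sum."""

    V_ipsilateral: float
    V_contralateral: float

    @property
    def V_brain(self) -> float:
        return self.V_ipsilateral + self.V_contralateral


@dataclass
class LesionVolumes:
    """Lesion/core volumes in um^3; penumbra = lesion - core."""

    V_lesion: float
    V_core: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.V_core <= self.V_lesion:
            raise ValueError("require 0 <= V_core <= V_lesion")

    @property
    def penumbra(self) -> float:
        return self.V_lesion - self.V_core


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance, positive inside the mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.full(mask.shape, -float(max(mask.shape)))
    if mask.all():
        return np.full(mask.shape, float(max(mask.shape)))
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def interpolate_roi(series: RoiSeries, n_slices: int | None = None) -> np.ndarray:
    """Densify sparse annotations into a 3-D mask by shape interpolation.

    Between consecutive annotated slices i and j, slice k is the
    superlevel set (>= 0) of the linear blend of the two signed distance
    fields.  Annotated slices pass through unchanged; slices outside the
    annotated range are empty.
    """
    indices = list(series.annotations)
    if len(indices) < 2:
        raise ValueError("interpolate_roi needs at least 2 annotated slices")
    plane_shape = next(iter(series.annotations.values())).shape
    if n_slices is None:
        n_slices = indices[-1] + 1
    dense = np.zeros((n_slices, *plane_shape), dtype=bool)
    distances = {i: _signed_distance(m) for i, m in series.annotations.items()}
    for i, j in zip(indices[:-1], indices[1:]):
        d_i, d_j = distances[i], distances[j]
        for k in range(i, min(j + 1, n_slices)):
            w = (k - i) / (j - i)
            dense[k] = ((1 - w) * d_i + w * d_j) >= 0
    for i in indices:  # annotated slices are authoritative
        if i < n_slices:
            dense[i] = series.annotations[i]
    series.dense_mask = dense
    return dense


def edema_extent(h: HemisphereVolumes) -> float:
    """Edema extent as percent of the contralateral hemisphere.

    May be negative (shrinkage, e.g. after dehydrating stains).
    """
    if not h.V_contralateral > 0:
        raise ValueError("contralateral volume must be positive")
    return (h.V_ipsilateral - h.V_contralateral) / h.V_contralateral * 100.0


def corrected_lesion_percent(h: HemisphereVolumes, lesion_volume: float) -> float:
    """Edema-corrected lesion volume as percent of total brain volume."""
    if not (h.V_ipsilateral > 0 and h.V_contralateral > 0):
        raise ValueError("hemisphere volumes must be positive")
    if lesion_volume < 0:
        raise ValueError("lesion volume must be non-negative")
    return lesion_volume * (h.V_contralateral / h.V_ipsilateral) / h.V_brain * 100.0


def quantify_manual(
    ipsi_mask: np.ndarray,
    contra_mask: np.ndarray,
    voxel_size_um: float,
    lesion_mask: np.ndarray | None = None,
    core_mask: np.ndarray | None = None,
) -> dict:
    """Volumes and edema/lesion percentages from dense masks.

    Returns a record with raw volumes in mm^3, edema extent and the
    edema-corrected lesion/core/penumbra percentages.  Overlapping
    hemisphere masks are an error; a lesion leaking outside the
    ipsilateral hemisphere is recorded as a warning flag.
    """
    ipsi_mask = np.asarray(ipsi_mask, dtype=bool)
    contra_mask = np.asarray(contra_mask, dtype=bool)
    if np.logical_and(ipsi_mask, contra_mask).any():
        raise ValueError("hemisphere masks overlap")
    voxel_um3 = float(voxel_size_um) ** 3
    voxel_mm3 = (voxel_size_um / 1000.0) ** 3

    h = HemisphereVolumes(
        V_ipsilateral=float(ipsi_mask.sum()) * voxel_um3,
        V_contralateral=float(contra_mask.sum()) * voxel_um3,
    )
    record = {
        "V_ipsilateral_mm3": ipsi_mask.sum() * voxel_mm3,
        "V_contralateral_mm3": contra_mask.sum() * voxel_mm3,
        "V_brain_mm3": (ipsi_mask.sum() + contra_mask.sum()) * voxel_mm3,
        "edema_extent_percent": edema_extent(h),
        "warnings": [],
    }
    lesion_count = 0 if lesion_mask is None else int(np.asarray(lesion_mask).sum())
    core_count = 0 if core_mask is None else int(np.asarray(core_mask).sum())
    if lesion_mask is not None and not (
        np.asarray(lesion_mask, dtype=bool) <= ipsi_mask
    ).all():
        msg = "lesion mask extends outside the ipsilateral hemisphere"
        record["warnings"].append(msg)
        warnings.warn(msg, stacklevel=2)
    record["V_lesion_mm3"] = lesion_count * voxel_mm3
    record["V_core_mm3"] = core_count * voxel_mm3
    lesion_pct = corrected_lesion_percent(h, lesion_count * voxel_um3)
    core_pct = corrected_lesion_percent(h, core_count * voxel_um3)
    record["lesion_percent"] = lesion_pct
    record["core_percent"] = core_pct
    record["penumbra_percent"] = lesion_pct - core_pct
    return record
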