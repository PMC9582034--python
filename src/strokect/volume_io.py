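"""Volume input/output and hemisphere splitting.

Micro-CT reconstructions arrive either as a multipage TIFF stack, a NIfTI
file, or a directory of per-slice 2-D images written by the scanner
reconstruction software.  All of them are loaded into a single
:class:`IntensityVolume` with axis order ``(z, y, x)`` — a transaxial slice
is a fixed ``z`` — and an isotropic voxel edge length in micrometres.

The hemisphere split mirrors the preprocessing of the automatic lesion
pipeline: the brain is cut along a user-supplied midline column, each half
is brought to a unified in-plane size, block-averaged down, and the two
halves are oriented identically so that a model trained on healthy
hemispheres sees a single anatomical orientation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "IntensityVolume",
    "HemispherePair",
    "read_volume",
    "write_volume",
    "split_hemispheres",
]

_SLICE_EXTENSIONS = {".png", ".bmp", ".tif", ".tiff", ".jpg", ".jpeg"}


@dataclass
class IntensityVolume:
    """A 3-D grid of non-negative intensities with isotropic voxel size.

    Parameters
    ----------
    data
        Array of shape ``(z, y, x)``; transaxial slices are indexed by ``z``.
    voxel_size_um
        Isotropic voxel edge length in micrometres (e.g. 4 for the
        osmium protocol, 3 for iodine).
    provenance
        Free-text origin label, e.g. ``"phantom"`` or ``"scanner"``.
    """

    data: np.ndarray
    voxel_size_um: float
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume must be 3-D with all dimensions >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3: ``(voxel_size_um / 1000) ** 3``."""
        return (self.voxel_size_um / 1000.0) ** 3


@dataclass
class HemispherePair:
    """Two hemisphere subvolumes in a shared anatomical orientation."""

    contralateral: IntensityVolume
    ipsilateral: IntensityVolume
    midline_column: int
    crop_shape: tuple[int, int]
    downsample_factor: int = 1
    ipsilateral_side: str = field(default="right")

    def __post_init__(self) -> None:
        if self.contralateral.voxel_size_um != self.ipsilateral.voxel_size_um:
            raise ValueError("hemispheres must share voxel size")
        if self.contralateral.shape[0] != self.ipsilateral.shape[0]:
            raise ValueError("hemispheres must share slice count")


def _read_slice_dir(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _SLICE_EXTENSIONS
    )
    if not files:
        raise FileNotFoundError(f"no slice images found in {path}")
    slices = []
    for f in files:
        img = np.asarray(iio.imread(f))
        if img.ndim == 3:  # collapse RGB scanner exports to luminance
            img = img.mean(axis=-1)
        slices.append(img)
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent slice shapes: {sorted(shapes)}")
    return np.stack(slices, axis=0)


def read_volume(path: str | os.PathLike, voxel_size_um: float) -> IntensityVolume:
    """Read a volume from TIFF stack, NIfTI file, or slice directory.

    Slices from a directory are stacked in lexicographic filename order.
    Intensities are cast to float without rescaling.
    """
    if not voxel_size_um > 0:
        raise ValueError("voxel_size_um must be positive")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such path: {path}")
    if path.is_dir():
        data = _read_slice_dir(path)
        provenance = "slice-directory"
    elif path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        provenance = "tiff"
    elif path.suffix.lower() in {".nii", ".gz"} or str(path).endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        # NIfTI stores (x, y, z); flip to the (z, y, x) package convention
        data = np.asarray(img.dataobj).T
        provenance = "nifti"
    else:
        raise ValueError(f"unrecognized volume format: {path.suffix}")
    return IntensityVolume(np.asarray(data), voxel_size_um, provenance)


def write_volume(vol: IntensityVolume, path: str | os.PathLike) -> None:
    """Write a volume as multipage TIFF or NIfTI (by extension).

    Integer-valued data round-trips bit-identically through
    :func:`read_volume`.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = vol.data
    if np.all(data == np.round(data)) and data.min() >= 0:
        if data.max() <= 255:
            data = data.astype(np.uint8)
        elif data.max() <= 65535:
            data = data.astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        # grayscale slices; without this, 3-slice stacks are guessed as RGB
        tifffile.imwrite(path, data, photometric="minisblack")
    elif path.suffix.lower() == ".nii" or str(path).endswith(".nii.gz"):
        import nibabel as nib

        img = nib.Nifti1Image(np.asarray(data).T, affine=np.eye(4))
        nib.save(img, str(path))
    else:
        raise ValueError(f"unrecognized volume format: {path.suffix}")


def _background_mode(data: np.ndarray) -> float:
    """Most frequent intensity, used as padding value (mimics air)."""
    values, counts = np.unique(data.round(6), return_counts=True)
    return float(values[np.argmax(counts)])


def _fit_plane(half: np.ndarray, crop_shape: tuple[int, int], pad_value: float) -> np.ndarray:
    """Center-crop or pad each in-plane axis of (z, y, x) data to crop_shape."""
    out = half
    for axis, target in ((1, crop_shape[0]), (2, crop_shape[1])):
        size = out.shape[axis]
        if size > target:
            start = (size - target) // 2
            sl = [slice(None)] * 3
            sl[axis] = slice(start, start + target)
            out = out[tuple(sl)]
        elif size < target:
            before = (target - size) // 2
            after = target - size - before
            pad = [(0, 0)] * 3
            pad[axis] = (before, after)
            out = np.pad(out, pad, mode="constant", constant_values=pad_value)
    return out


def _block_mean(plane_stack: np.ndarray, f: int) -> np.ndarray:
    if f == 1:
        return plane_stack
    z, y, x = plane_stack.shape
    return (
        plane_stack.reshape(z, y // f, f, x // f, f).mean(axis=(2, 4))
    )


def split_hemispheres(
    vol: IntensityVolume,
    midline_column: int,
    crop_shape: tuple[int, int],
    downsample_factor: int = 1,
    ipsilateral: str = "right",
) -> HemispherePair:
    """Split a brain along a midline column into two oriented hemispheres.

    The left part is ``[0, midline_column)`` and the right part
    ``[midline_column, x_dim)`` in x.  Each part is padded (with the
    volume's background mode) or center-cropped in-plane to ``crop_shape``
    (per-hemisphere ``(rows, cols)``), then block-averaged by
    ``downsample_factor`` in both in-plane axes.  The right half is
    mirrored about its midline-facing edge, so both hemispheres share the
    same anatomical orientation; the caller designates which side is
    ipsilateral.
    """
    z, y, x = vol.shape
    if not 0 < midline_column < x:
        raise ValueError("midline_column must lie strictly inside the x-range")
    f = int(downsample_factor)
    if f < 1:
        raise ValueError("downsample_factor must be >= 1")
    rows, cols = crop_shape
    if rows < 2 * f or cols < 2 * f:
        raise ValueError("crop_shape smaller than 2 x downsample_factor")
    if rows % f or cols % f:
        raise ValueError("crop_shape must be divisible by downsample_factor")
    if ipsilateral not in ("left", "right"):
        raise ValueError("ipsilateral must be 'left' or 'right'")

    pad_value = _background_mode(vol.data)
    left = vol.data[:, :, :midline_column]
    right = vol.data[:, :, midline_column:]
    # mirror the right half about its midline-facing edge (x = midline)
    right = right[:, :, ::-1]

    halves = {}
    for name, half in (("left", left), ("right", right)):
        fitted = _fit_plane(half, (rows, cols), pad_value)
        halves[name] = _block_mean(fitted, f)

    def _as_vol(arr: np.ndarray) -> IntensityVolume:
        return IntensityVolume(arr, vol.voxel_size_um, provenance=vol.provenance)

    contra_side = "left" if ipsilateral == "right" else "right"
    return HemispherePair(
        contralateral=_as_vol(halves[contra_side]),
        ipsilateral=_as_vol(halves[ipsilateral]),
        midline_column=midline_column,
        crop_shape=(rows, cols),
        downsample_factor=f,
        ipsilateral_side=ipsilateral,
    )
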