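"""Volume and mask containers, file I/O and intensity preprocessing.

Arrays are indexed ``(x, y, z)`` with the through-plane (slice) axis last;
slice index 0 is the inferior end. Spacing is millimetres per voxel along
each axis. Masks live in voxel space; physical spacing enters only through
distance and volume computations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "SegMask",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "preprocess",
    "PreprocessConfig",
]

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mhd", ".mha")

NORMALIZATIONS = ("none", "zscore", "percentile")


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar intensity grid with anisotropic voxel spacing.

    Parameters
    ----------
    intensities : ndarray, shape (nx, ny, nz)
        Scalar intensities, finite.
    spacing : tuple of 3 floats
        Millimetres per voxel along (x, y, z). Strictly positive.
    slice_axis : int
        Index of the through-plane axis (always 2 in this package).
    provenance : dict
        Processing history (which preprocessing steps ran, with settings).
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    slice_axis: int = 2
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"intensities must be 3D, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class SegMask:
    """A binary 3D mask aligned voxel-for-voxel to an :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    slice_axis: int = 2
    warning: str | None = field(default=None, compare=False)

    def __post_init__(self):
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        arr = (arr > 0.5).astype(np.uint8)
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        object.__setattr__(self, "voxels", arr)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return self.voxel_count == 0

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def check_same_grid(self, other: "SegMask | ImageVolume") -> None:
        oshape = other.shape
        if self.shape != oshape:
            raise ValueError(
                f"grid mismatch: mask shape {self.shape} vs reference shape {oshape}"
            )


def _check_path(path: str) -> None:
    import os

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    low = str(path).lower()
    if not any(low.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise ValueError(
            f"unsupported format for {path!r}; supported: NIfTI (.nii, .nii.gz) "
            "and MetaImage (.mhd, .mha)"
        )


def _sitk_to_array(img: sitk.Image) -> tuple[np.ndarray, tuple[float, float, float]]:
    # SimpleITK arrays come out (z, y, x); transpose to (x, y, z).
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = tuple(float(s) for s in img.GetSpacing())  # already (x, y, z)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive voxel spacing in header: {spacing}")
    return arr, spacing


def read_volume(path: str) -> ImageVolume:
    """Read a NIfTI or MetaImage volume; spacing is taken from the header."""
    _check_path(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise ValueError(f"could not read {path!r} as NIfTI/MetaImage: {exc}") from exc
    arr, spacing = _sitk_to_array(img)
    return ImageVolume(arr.astype(np.float64), spacing)


def read_mask(path: str, reference: ImageVolume | None = None) -> SegMask:
    """Read a mask; any value > 0.5 becomes 1. Grid must match ``reference``."""
    _check_path(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise ValueError(f"could not read {path!r} as NIfTI/MetaImage: {exc}") from exc
    arr, spacing = _sitk_to_array(img)
    if reference is not None and arr.shape != reference.shape:
        raise ValueError(
            f"mask grid {arr.shape} does not match reference grid {reference.shape}"
        )
    if reference is not None:
        spacing = reference.spacing
    return SegMask(arr, spacing)


def _array_to_sitk(arr: np.ndarray, spacing: tuple[float, float, float]) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    return img


def write_volume(volume: ImageVolume, path: str) -> None:
    sitk.WriteImage(_array_to_sitk(volume.intensities, volume.spacing), str(path))


def write_mask(mask: SegMask, path: str) -> None:
    sitk.WriteImage(_array_to_sitk(mask.voxels, mask.spacing), str(path))


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing switches applied in order: bias correction, normalization.

    ``bias_correction`` delegates to SimpleITK's N4 filter when enabled.
    ``normalization`` is one of ``"none"``, ``"zscore"`` (zero mean / unit SD
    over a region), ``"percentile"`` (1st/99th percentile rescale to [0, 1]).
    """

    bias_correction: bool = False
    normalization: str = "none"
    n4_shrink_factor: int = 4

    def __post_init__(self):
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(
                f"unknown normalization {self.normalization!r}; "
                f"options: {', '.join(NORMALIZATIONS)}"
            )


def _n4_correct(volume: ImageVolume, shrink: int) -> np.ndarray:
    img = _array_to_sitk(volume.intensities, volume.spacing)
    img = sitk.Cast(img, sitk.sitkFloat32)
    small = sitk.Shrink(img, [shrink] * 3) if shrink > 1 else img
    corrector = sitk.N4BiasFieldCorrectionImageFilter()
    corrector.Execute(small)
    log_field = corrector.GetLogBiasFieldAsImage(img)
    corrected = img / sitk.Exp(log_field)
    arr, _ = _sitk_to_array(corrected)
    return arr.astype(np.float64)


def preprocess(
    volume: ImageVolume,
    config: PreprocessConfig | None = None,
    region: SegMask | None = None,
) -> ImageVolume:
    """Apply optional N4 bias correction then intensity normalization.

    When ``region`` is given, z-score statistics are computed over a
    3-voxel-dilated copy of it (the gland plus a rim of context); otherwise
    over the full grid. Grid shape and spacing are never altered. The steps
    that ran are recorded in the returned volume's provenance.
    """
    config = config or PreprocessConfig()
    arr = volume.intensities
    steps: list[str] = []
    if config.bias_correction:
        arr = _n4_correct(volume, config.n4_shrink_factor)
        steps.append("n4_bias_correction")
    if config.normalization == "zscore":
        if region is not None and not region.is_empty:
            from scipy import ndimage

            sel = ndimage.binary_dilation(
                region.voxels.astype(bool), iterations=3
            )
        else:
            sel = np.ones(arr.shape, dtype=bool)
        vals = arr[sel]
        sd = vals.std()
        if sd == 0:
            raise ValueError("z-score normalization undefined: zero intensity SD")
        arr = (arr - vals.mean()) / sd
        steps.append("zscore")
    elif config.normalization == "percentile":
        p1, p99 = np.percentile(arr, [1, 99])
        if p99 == p1:
            raise ValueError("percentile rescale undefined: flat intensity histogram")
        arr = (arr - p1) / (p99 - p1)
        steps.append("percentile_rescale")
    prov = dict(volume.provenance)
    prov["preprocessing"] = steps
    return replace(volume, intensities=np.asarray(arr, dtype=np.float64), provenance=prov)


def write_provenance(volume: ImageVolume, path: str) -> None:
    """Write the volume's provenance record as a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(volume.provenance, fh, indent=2)
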