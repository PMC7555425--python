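"""Radiomics feature extraction: 107 features per region, 321 per case.

Per region (whole gland, apex, base — thirds of the automated mask's
slice range) the extractor computes 18 first-order, 14 shape and 75
texture features (24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM).
Intensities are discretized with a fixed bin width (default 64) anchored
at the in-mask minimum. GLCM and GLRLM are built at distance 1 along the
13 unique 3D directions of the 26-neighbourhood and each feature is the
mean of its 13 per-direction values; GLSZM zones use 26-connectivity; GLDM
uses the 26-neighbourhood at distance 1 with similarity tolerance 0.

Feature definitions follow the IBSI-style formulations of the widely used
pyradiomics extractor (v2.2 conventions), including its degenerate-ROI
conventions: zero-variance skewness/kurtosis are 0, features of an empty
texture matrix are 0, so empty apex/base regions cannot crash extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..imaging import ImageVolume, SegMask
from ..regions import REGIONS, partition, restrict

from . import firstorder as _fo
from . import shape as _shape
from . import texture as _tx

__all__ = [
    "FEATURE_CLASSES",
    "CLASS_FEATURE_NAMES",
    "FEATURE_NAMES",
    "ExtractionSettings",
    "DiscretizedROI",
    "FeatureVector",
    "discretize",
    "first_order_features",
    "shape_features",
    "texture_matrices",
    "texture_features",
    "extract_region",
    "extract_case",
]

FEATURE_CLASSES = ("firstorder", "shape", "glcm", "glrlm", "glszm", "gldm", "ngtdm")

CLASS_FEATURE_NAMES: dict[str, tuple[str, ...]] = {
    "firstorder": _fo.FEATURE_NAMES,
    "shape": _shape.FEATURE_NAMES,
    "glcm": _tx.GLCM_FEATURES,
    "glrlm": _tx.GLRLM_FEATURES,
    "glszm": _tx.GLSZM_FEATURES,
    "gldm": _tx.GLDM_FEATURES,
    "ngtdm": _tx.NGTDM_FEATURES,
}

#: the frozen 321-name order: region-major, class order as above,
#: alphabetical within class
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{region}_{cls}_{name}"
    for region in REGIONS
    for cls in FEATURE_CLASSES
    for name in CLASS_FEATURE_NAMES[cls]
)

assert len(FEATURE_NAMES) == 321


@dataclass(frozen=True)
class ExtractionSettings:
    """Extraction settings; the defaults are the package's reference settings."""

    bin_width: float = 64.0
    n_directions: int = 13
    connectivity: int = 26

    @property
    def fingerprint(self) -> str:
        return (
            f"binwidth={self.bin_width:g};directions={self.n_directions};"
            f"connectivity={self.connectivity}"
        )


@dataclass(frozen=True)
class DiscretizedROI:
    """Fixed-bin-width gray-level labels of the in-mask voxels.

    ``labels`` is a full-grid int array, 0 outside the mask and
    ``floor((x - min_in_mask) / bin_width) + 1`` inside.
    """

    labels: np.ndarray
    mask: np.ndarray
    bin_width: float
    n_bins: int


@dataclass(frozen=True)
class FeatureVector:
    """Ordered, named 321-feature vector for one case."""

    values: dict[str, float]
    fingerprint: str
    degenerate_regions: tuple[str, ...] = ()

    def __post_init__(self):
        if tuple(self.values) != FEATURE_NAMES:
            raise ValueError(
                f"feature vector must have exactly the {len(FEATURE_NAMES)} "
                "canonical names in canonical order"
            )
        arr = np.array(list(self.values.values()), dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = [n for n, v in self.values.items() if not np.isfinite(v)]
            raise ValueError(f"non-finite feature values: {bad[:5]}")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES], dtype=float)

    def as_series(self):
        import pandas as pd

        return pd.Series(self.values)


def discretize(
    volume: ImageVolume, mask: SegMask, bin_width: float = 64.0
) -> DiscretizedROI:
    """Fixed-bin-width discretization anchored at the in-mask minimum."""
    if mask.is_empty:
        raise ValueError("cannot discretize an empty mask")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    m = mask.voxels.astype(bool)
    vals = volume.intensities[m]
    labels = np.zeros(volume.shape, dtype=np.int64)
    labels[m] = np.floor((vals - vals.min()) / bin_width).astype(np.int64) + 1
    return DiscretizedROI(labels, m, float(bin_width), int(labels.max()))


def first_order_features(
    volume: ImageVolume, mask: SegMask, bin_width: float = 64.0
) -> dict[str, float]:
    """The 18 first-order statistics of the in-mask intensities."""
    if mask.is_empty:
        raise ValueError("first-order features of an empty mask are undefined")
    disc = discretize(volume, mask, bin_width)
    return _fo.compute(
        volume.intensities[mask.voxels.astype(bool)],
        disc.labels[disc.mask],
        volume.voxel_volume,
    )


def shape_features(mask: SegMask) -> dict[str, float]:
    """The 14 3D shape descriptors of the binary mask, in physical units."""
    if mask.is_empty:
        raise ValueError("shape features of an empty mask are undefined")
    return _shape.compute(mask.voxels.astype(bool), mask.spacing)


def texture_matrices(disc: DiscretizedROI) -> _tx.TextureMatrices:
    """All five texture-matrix families for a discretized ROI."""
    return _tx.build_matrices(disc.labels, disc.mask, disc.n_bins)


def texture_features(matrices: _tx.TextureMatrices) -> dict[str, float]:
    """The 75 texture features; GLCM/GLRLM features are direction-averaged."""
    return _tx.compute_features(matrices)


def _zero_features(cls: str) -> dict[str, float]:
    return {name: 0.0 for name in CLASS_FEATURE_NAMES[cls]}


def extract_region(
    volume: ImageVolume, mask: SegMask, settings: ExtractionSettings
) -> tuple[dict[str, float], bool]:
    """107 features for one region; returns (features, degenerate_flag).

    An empty or single-voxel region yields the degenerate convention
    (all-zero features except what is still well-defined) with the flag set.
    """
    out: dict[str, float] = {}
    degenerate = mask.voxel_count < 2
    if mask.is_empty:
        for cls in FEATURE_CLASSES:
            out.update({f"{cls}_{k}": v for k, v in _zero_features(cls).items()})
        return out, True
    fo = first_order_features(volume, mask, settings.bin_width)
    sh = shape_features(mask)
    disc = discretize(volume, mask, settings.bin_width)
    tx = texture_features(texture_matrices(disc))
    for cls, feats in (("firstorder", fo), ("shape", sh)):
        out.update({f"{cls}_{k}": feats[k] for k in CLASS_FEATURE_NAMES[cls]})
    for cls in ("glcm", "glrlm", "glszm", "gldm", "ngtdm"):
        out.update({f"{cls}_{k}": tx[f"{cls}_{k}"] for k in CLASS_FEATURE_NAMES[cls]})
    return out, degenerate


def extract_case(
    volume: ImageVolume,
    auto_mask: SegMask,
    settings: ExtractionSettings | None = None,
) -> FeatureVector:
    """Extract the full 321-feature vector for one case.

    The apex/base partition is computed from the automated mask itself —
    at prediction time no reference mask exists. Each region is an
    independent ROI and is re-discretized on its own intensity range.
    """
    settings = settings or ExtractionSettings()
    if auto_mask.is_empty:
        raise ValueError("cannot extract features from an empty segmentation")
    part = partition(auto_mask)
    values: dict[str, float] = {}
    degenerate: list[str] = []
    for region in REGIONS:
        rmask = restrict(auto_mask, region, part)
        feats, flag = extract_region(volume, rmask, settings)
        if flag:
            degenerate.append(region)
        values.update({f"{region}_{k}": v for k, v in feats.items()})
    values = {name: values[name] for name in FEATURE_NAMES}
    return FeatureVector(values, settings.fingerprint, tuple(degenerate))
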