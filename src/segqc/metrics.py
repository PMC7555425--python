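"""Region-wise segmentation metrics: DSC, aRVD, 95% Hausdorff and ASD.

Surface voxels are mask voxels with at least one 6-connected neighbour
outside the mask (the grid boundary counts as outside); distances are
Euclidean millimetre distances between voxel centres. The 95% Hausdorff
distance is the maximum of the two directed 95th percentiles (linear
interpolation between order statistics) and the ASD is the mean of the two
directed distance lists pooled together, following the PROMISE12 challenge
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .imaging import SegMask
from .regions import REGIONS, partition, restrict

__all__ = [
    "METRICS",
    "MetricPanel",
    "dice",
    "arvd",
    "surface_voxels",
    "hd95",
    "asd",
    "metric_panel",
]

METRICS = ("DSC", "aRVD", "HD95", "ASD")

#: metric value assumed when a cell cannot be computed (consumed by scoring
#: as the floor score); DSC/aRVD keep their defined worst-case values.
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class MetricPanel:
    """The 12 raw metric values (4 metrics x whole/apex/base) for one pair.

    ``values[(region, metric)]`` is the raw metric; ``valid[(region, metric)]``
    is False for degenerate cells (e.g. a distance metric with an empty mask
    region), in which case the value is NaN.
    """

    values: dict[tuple[str, str], float]
    valid: dict[tuple[str, str], bool]

    def __post_init__(self):
        cells = [(r, m) for r in REGIONS for m in METRICS]
        if sorted(self.values) != sorted(cells) or sorted(self.valid) != sorted(cells):
            raise ValueError("panel must have exactly the 12 region x metric cells")

    @property
    def is_fully_valid(self) -> bool:
        return all(self.valid.values())

    def as_series(self):
        """Panel as a pandas Series with names like ``whole_DSC``."""
        import pandas as pd

        return pd.Series(
            {f"{r}_{m}": self.values[(r, m)] for r in REGIONS for m in METRICS}
        )


def dice(a: SegMask, b: SegMask) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|); both empty -> 1."""
    a.check_same_grid(b)
    na, nb = a.voxel_count, b.voxel_count
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    return 2.0 * inter / (na + nb)


def arvd(a: SegMask, b_reference: SegMask) -> float:
    """Absolute relative volume difference |V_a / V_ref - 1| * 100 (percent)."""
    a.check_same_grid(b_reference)
    v_ref = b_reference.voxel_count
    if v_ref == 0:
        raise ValueError("aRVD undefined for an empty reference mask")
    return abs(a.voxel_count / v_ref - 1.0) * 100.0


def surface_voxels(m: SegMask) -> np.ndarray:
    """Coordinates (n, 3) of mask voxels with a 6-connected outside neighbour."""
    if m.is_empty:
        raise ValueError("surface of an empty mask is undefined")
    fg = m.voxels.astype(bool)
    interior = ndimage.binary_erosion(fg, structure=_STRUCT6, border_value=0)
    return np.argwhere(fg & ~interior)


def _directed_distances(a: SegMask, b: SegMask) -> tuple[np.ndarray, np.ndarray]:
    """Both directed surface-distance lists (a->b, b->a) in mm."""
    sp = np.asarray(a.spacing)
    pa = surface_voxels(a) * sp
    pb = surface_voxels(b) * sp
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    return d_ab, d_ba


def hd95(a: SegMask, b: SegMask) -> float:
    """95% Hausdorff distance in mm: max of the two directed 95th percentiles."""
    a.check_same_grid(b)
    if a.is_empty or b.is_empty:
        raise ValueError("hd95 undefined for empty masks")
    d_ab, d_ba = _directed_distances(a, b)
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def asd(a: SegMask, b: SegMask) -> float:
    """Average symmetric surface distance in mm (pooled mean of both directions)."""
    a.check_same_grid(b)
    if a.is_empty or b.is_empty:
        raise ValueError("asd undefined for empty masks")
    d_ab, d_ba = _directed_distances(a, b)
    return float(np.concatenate([d_ab, d_ba]).mean())


def metric_panel(auto: SegMask, reference: SegMask) -> MetricPanel:
    """All 12 region-wise metrics for one (automated, reference) mask pair.

    The apex/base partition is computed from the reference mask and applied
    to both masks, so the two are compared in a common anatomical frame. If
    a region of either mask is empty, its distance metrics are flagged
    invalid (DSC and aRVD are still defined: 0 and 100).
    """
    auto.check_same_grid(reference)
    if reference.is_empty:
        raise ValueError("metric panel requires a nonempty reference mask")
    part = partition(reference)
    values: dict[tuple[str, str], float] = {}
    valid: dict[tuple[str, str], bool] = {}
    for region in REGIONS:
        a = restrict(auto, region, part)
        r = restrict(reference, region, part)
        ref_empty, auto_empty = r.is_empty, a.is_empty
        values[(region, "DSC")] = dice(a, r)
        valid[(region, "DSC")] = True
        if ref_empty:
            values[(region, "aRVD")] = float("nan")
            valid[(region, "aRVD")] = False
        else:
            values[(region, "aRVD")] = arvd(a, r)
            valid[(region, "aRVD")] = True
        if ref_empty or auto_empty:
            for m in ("HD95", "ASD"):
                values[(region, m)] = float("nan")
                valid[(region, m)] = False
        else:
            values[(region, "HD95")] = hd95(a, r)
            values[(region, "ASD")] = asd(a, r)
            valid[(region, "HD95")] = True
            valid[(region, "ASD")] = True
    return MetricPanel(values, valid)
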