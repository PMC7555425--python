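"""Apex / middle / base partition of a prostate mask along the slice axis.

The apex is the inferior third of the mask-containing slices and the base
the superior third; with ``n`` mask-containing slices, apex and base each
get ``floor(n / 3)`` slices and the middle keeps the remainder. "Apex" and
"base" here are slice-count thirds, not zonal anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .imaging import SegMask

__all__ = ["RegionPartition", "partition", "restrict", "REGIONS"]

REGIONS = ("whole", "apex", "base")


@dataclass(frozen=True)
class RegionPartition:
    """Half-open absolute slice-index ranges for apex, middle and base.

    The ranges are disjoint, ordered apex < mid < base (inferior to
    superior) and together cover the span of mask-containing slices.
    """

    apex_slices: tuple[int, int]
    mid_slices: tuple[int, int]
    base_slices: tuple[int, int]

    def range_for(self, region: str) -> tuple[int, int]:
        try:
            return {
                "apex": self.apex_slices,
                "mid": self.mid_slices,
                "base": self.base_slices,
            }[region]
        except KeyError:
            raise ValueError(
                f"invalid region {region!r}; options: whole, apex, mid, base"
            ) from None


def partition(mask: SegMask) -> RegionPartition:
    """Split the mask-containing slices into inferior/middle/superior thirds."""
    if mask.is_empty:
        raise ValueError("cannot partition an empty mask")
    containing = np.flatnonzero(mask.voxels.any(axis=(0, 1)))
    n = len(containing)
    third = n // 3
    apex_idx = containing[:third]
    base_idx = containing[n - third :] if third > 0 else containing[:0]
    mid_idx = containing[third : n - third]
    lo, hi = int(containing[0]), int(containing[-1]) + 1

    def _rng(idx, fallback):
        if len(idx) == 0:
            return (fallback, fallback)
        return (int(idx[0]), int(idx[-1]) + 1)

    apex = _rng(apex_idx, lo)
    mid = _rng(mid_idx, apex[1])
    base = _rng(base_idx, hi)
    # close gaps so the three half-open ranges tile [lo, hi) exactly
    apex = (lo, mid[0])
    base = (mid[1], hi)
    return RegionPartition(apex, mid, base)


def restrict(mask: SegMask, region: str, part: RegionPartition | None = None) -> SegMask:
    """Zero out voxels outside the region's slice range.

    ``region='whole'`` returns the mask unchanged. The partition defaults to
    one computed from ``mask`` itself; pass the reference mask's partition
    when both masks must share an anatomical frame.
    """
    if region == "whole":
        return mask
    if part is None:
        part = partition(mask)
    lo, hi = part.range_for(region)
    out = np.zeros_like(mask.voxels)
    out[:, :, lo:hi] = mask.voxels[:, :, lo:hi]
    return replace(mask, voxels=out)
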