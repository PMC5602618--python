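"""Cup-to-disc ratio metrics computed from binary disc and cup masks.

The horizontal (vertical) cup-to-disc ratio is the ratio of the cup's to the
disc's extent along the column (row) axis, where an extent is the inclusive
pixel distance between the furthest two member pixels on that axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RegionParams, ValidationError


@dataclass(frozen=True)
class ExtentPair:
    """Furthest two member pixels of a mask along one axis (0-based, inclusive)."""

    min_index: int
    max_index: int

    @property
    def extent(self) -> int:
        return self.max_index - self.min_index + 1


def _axis_extent(mask: np.ndarray, axis: int) -> ExtentPair:
    mask = np.asarray(mask, dtype=bool)
    proj = mask.any(axis=1 - axis)
    idx = np.flatnonzero(proj)
    if idx.size == 0:
        raise ValidationError("extent of an empty mask is undefined")
    return ExtentPair(int(idx[0]), int(idx[-1]))


def horizontal_extent(mask: np.ndarray) -> ExtentPair:
    """Min/max column index of any true pixel."""
    return _axis_extent(mask, axis=1)


def vertical_extent(mask: np.ndarray) -> ExtentPair:
    """Min/max row index of any true pixel."""
    return _axis_extent(mask, axis=0)


def hcdr(disc: np.ndarray, cup: np.ndarray) -> float:
    """Horizontal cup-to-disc ratio from extents; not clipped at 1.

    A cup wider than the disc yields a ratio above 1 and is surfaced to the
    evaluation stage rather than silently truncated — such cases are exactly
    the segmentation failures the filtering protocol is meant to catch.
    """
    return horizontal_extent(cup).extent / horizontal_extent(disc).extent


def vcdr(disc: np.ndarray, cup: np.ndarray) -> float:
    """Vertical cup-to-disc ratio from extents; not clipped at 1."""
    return vertical_extent(cup).extent / vertical_extent(disc).extent


def mask_area(mask: np.ndarray) -> int:
    return int(np.count_nonzero(mask))


def mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValidationError("centroid of an empty mask is undefined")
    return float(rows.mean()), float(cols.mean())


def region_params(disc: np.ndarray, cup: np.ndarray) -> RegionParams:
    """Assemble the six per-image parameters from disc and cup masks.

    With an empty cup, areas/centroids are still reported (cup centroid falls
    back to the disc centroid) and the two ratios are flagged absent.
    """
    disc = np.asarray(disc, dtype=bool)
    cup = np.asarray(cup, dtype=bool)
    if not disc.any():
        raise ValidationError("disc mask is empty")
    disc_c = mask_centroid(disc)
    if cup.any():
        return RegionParams(
            disc_area=mask_area(disc),
            disc_centroid=disc_c,
            cup_area=mask_area(cup),
            cup_centroid=mask_centroid(cup),
            hcdr=hcdr(disc, cup),
            vcdr=vcdr(disc, cup),
        )
    return RegionParams(
        disc_area=mask_area(disc),
        disc_centroid=disc_c,
        cup_area=0,
        cup_centroid=disc_c,
        hcdr=None,
        vcdr=None,
    )
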