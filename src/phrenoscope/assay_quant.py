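"""Quantifiers for the paired-image and per-cell effector assays.

* RNAscope-style surface ratios: an intensity threshold computed on the
  sum-projection of one (reference) side is applied identically to both
  sides, the supra-threshold surface is normalised to the ROI area, and the
  log2 right/left surface ratio is reported.
* In situ zymography: percentage of marker-positive cells (e.g. Islet1/2+)
  showing enzymatic (gelatinase) activity, per side, with the right/left
  fold.
* Western blots: replicate (left, right) band intensities rescaled so every
  replicate has the same left+right sum (the grand mean of the raw sums),
  which aligns replicates without touching any within-replicate R/L ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask
from skimage.filters import threshold_otsu

from .errors import EmptyROI, NoMarkerCells, ZeroSum, ZeroSurface

__all__ = [
    "BlotReplicate",
    "RnascopeResult",
    "ZymographyResult",
    "sum_projection",
    "roi_mask_from_polygon",
    "rnascope_lr_ratio",
    "zymography_fraction",
    "normalize_blot_pairs",
]


@dataclass(frozen=True)
class BlotReplicate:
    """One western-blot replicate: lane-normalised left and right intensities."""

    replicate: object
    left: float
    right: float

    def __post_init__(self):
        if self.left < 0 or self.right < 0:
            raise ValueError("band intensities must be >= 0")

    @property
    def rl_ratio(self) -> float:
        return self.right / self.left


@dataclass(frozen=True)
class RnascopeResult:
    threshold: float
    left_fraction: float
    right_fraction: float
    log2_rl_ratio: float


@dataclass(frozen=True)
class ZymographyResult:
    left_percent: float
    right_percent: float
    rl_fold: float
    n_left: int  # marker-positive cells per side
    n_right: int


def sum_projection(stack: np.ndarray) -> np.ndarray:
    """Sum of a Z-stack along the first axis (2D images pass through)."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        return stack
    if stack.ndim == 3:
        return stack.sum(axis=0)
    raise ValueError("stack must be a 2D image or a 3D z-stack")


def roi_mask_from_polygon(
    shape: tuple[int, int], vertices_xy: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Rasterise an (x, y) ROI polygon into a boolean mask."""
    v = np.asarray(vertices_xy, dtype=float)
    mask = polygon2mask(shape, np.column_stack([v[:, 1], v[:, 0]]))
    if not mask.any():
        raise EmptyROI("ROI polygon encloses no pixels")
    return mask


def rnascope_lr_ratio(
    left_stack: np.ndarray,
    left_roi: np.ndarray,
    right_stack: np.ndarray,
    right_roi: np.ndarray,
    reference: str = "left",
    threshold: Optional[float] = None,
) -> RnascopeResult:
    """log2 right/left supra-threshold surface ratio of a paired acquisition.

    The threshold is computed by Otsu's method on the sum-projection of the
    reference side restricted to its ROI (or fixed via ``threshold``) and
    applied to both sides; each side's surface is the supra-threshold area
    divided by its ROI area.  A zero surface on either side makes the log2
    ratio infinite: this is raised as :class:`ZeroSurface` carrying the
    signed infinity rather than returned silently.
    """
    if reference not in ("left", "right"):
        raise ValueError("reference must be 'left' or 'right'")
    projections = {
        "left": sum_projection(left_stack),
        "right": sum_projection(right_stack),
    }
    rois = {"left": np.asarray(left_roi, dtype=bool), "right": np.asarray(right_roi, dtype=bool)}
    for side in ("left", "right"):
        if not rois[side].any():
            raise EmptyROI(f"{side} ROI is empty")
    if threshold is None:
        ref_pixels = projections[reference][rois[reference]]
        threshold = float(threshold_otsu(ref_pixels))
    fractions = {
        side: float(((projections[side] > threshold) & rois[side]).sum())
        / float(rois[side].sum())
        for side in ("left", "right")
    }
    if fractions["left"] == 0 or fractions["right"] == 0:
        sentinel = np.inf if fractions["left"] == 0 else -np.inf
        raise ZeroSurface(
            "zero supra-threshold surface on one side; log2 ratio is infinite",
            sentinel,
        )
    log2_ratio = float(np.log2(fractions["right"] / fractions["left"]))
    return RnascopeResult(threshold, fractions["left"], fractions["right"], log2_ratio)


def zymography_fraction(table: pd.DataFrame) -> ZymographyResult:
    """Per-side percentage of marker-positive cells with enzymatic activity.

    ``table`` has one row per cell with columns ``side`` ("left"/"right"),
    ``marker_positive`` and ``activity_positive``.  Cells that are not
    marker-positive are ignored entirely.
    """
    percents = {}
    ns = {}
    for side in ("left", "right"):
        cells = table[(table["side"] == side) & table["marker_positive"].astype(bool)]
        if len(cells) == 0:
            raise NoMarkerCells(f"no marker-positive cells on the {side} side")
        active = cells["activity_positive"].astype(bool).sum()
        percents[side] = 100.0 * active / len(cells)
        ns[side] = len(cells)
    fold = (
        percents["right"] / percents["left"] if percents["left"] > 0 else float("nan")
    )
    return ZymographyResult(
        percents["left"], percents["right"], float(fold), ns["left"], ns["right"]
    )


def normalize_blot_pairs(replicates: Sequence[BlotReplicate]) -> list[BlotReplicate]:
    """Rescale replicates so each left+right sum equals the grand mean of sums.

    The per-replicate scaling leaves every within-replicate R/L ratio
    unchanged; it only removes between-replicate loading differences.
    """
    replicates = list(replicates)
    if not replicates:
        raise ValueError("no replicates supplied")
    sums = np.array([r.left + r.right for r in replicates], dtype=float)
    if (sums <= 0).any():
        raise ZeroSum("every replicate needs left + right > 0")
    target = float(sums.mean())
    return [
        BlotReplicate(r.replicate, r.left * target / s, r.right * target / s)
        for r, s in zip(replicates, sums)
    ]
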