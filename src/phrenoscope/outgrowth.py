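"""Ring-based quantification of axon outgrowth from spinal-cord explants.

Motor axons grow radially out of a cultured ventral spinal-cord explant.
Concentric rings at a fixed spacing (default 25 pixels) around the explant
border partition the image into iso-distance annuli; the labeled (e.g.
GFP-positive) surface per ring gives the total outgrowth area and the
maximal growth distance, and the total fascicle width measured along a
proximal and a distal ring contour gives a proximal/distal defasciculation
index: tight proximal bundles that stay bundled give an index near 1, while
distal widening lowers it and distal thinning raises it.

Ring k contains the pixels whose Euclidean distance to the explant border
lies in ((k-1)*spacing, k*spacing]; pixels inside the explant have distance
0 and belong to no ring, so ring areas plus the explant interior tile the
image exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import shapely.geometry as sgeom
from scipy import ndimage
from skimage.draw import polygon2mask
from skimage.measure import find_contours

from .errors import InvalidPolygon, NoDistalSignal

__all__ = [
    "RingProfile",
    "OutgrowthRecord",
    "build_rings",
    "outgrowth_area",
    "ring_fascicle_widths",
    "defasciculation_index",
]


@dataclass
class RingProfile:
    """Concentric iso-distance rings around an explant border (geometry only)."""

    inside: np.ndarray  # bool, explant interior (incl. border)
    distance: np.ndarray  # float, Euclidean distance to the explant
    ring_index: np.ndarray  # int, 0 inside the explant, k for ring k
    spacing: float
    n_rings: int

    def ring_mask(self, k: int) -> np.ndarray:
        return self.ring_index == k

    def outer_offset(self, k: int) -> float:
        return k * self.spacing

    def ring_areas(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Pixel area per ring (1-based ring k at index k-1).

        With ``mask`` given, counts only foreground pixels of that mask.
        """
        sel = self.ring_index if mask is None else np.where(mask, self.ring_index, 0)
        counts = np.bincount(sel.ravel(), minlength=self.n_rings + 1)
        return counts[1 : self.n_rings + 1].astype(float)


@dataclass(frozen=True)
class OutgrowthRecord:
    side: str
    total_area: float  # px² of labeled signal outside the explant
    max_distance: float  # px, outer offset of the farthest occupied ring
    defasciculation_index: Optional[float]  # proximal/distal width ratio


def build_rings(
    border_xy: Sequence[tuple[float, float]],
    image_shape: tuple[int, int],
    spacing: float = 25.0,
) -> RingProfile:
    """Build concentric ring ROIs around an explant border polygon.

    ``border_xy`` is a simple polygon as (x, y) pixel vertices.  Rings cover
    the whole image outside the explant, clipped at the image edge.
    """
    poly = sgeom.Polygon(border_xy)
    if not poly.is_valid or poly.area == 0:
        raise InvalidPolygon("border must be a simple polygon with nonzero area")
    v = np.asarray(border_xy, dtype=float)
    inside = polygon2mask(image_shape, np.column_stack([v[:, 1], v[:, 0]]))
    if not inside.any():
        raise InvalidPolygon("border polygon encloses no pixels of the image")
    distance = ndimage.distance_transform_edt(~inside)
    ring_index = np.ceil(distance / spacing).astype(int)
    ring_index[inside] = 0
    return RingProfile(inside, distance, ring_index, float(spacing), int(ring_index.max()))


def outgrowth_area(
    mask: np.ndarray, profile: RingProfile
) -> tuple[float, float]:
    """Total labeled area outside the explant and the maximal growth distance.

    The total is the sum of per-ring labeled surfaces (equivalently, all
    foreground outside the border); the maximal distance is the outer offset
    of the farthest ring containing foreground.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != profile.ring_index.shape:
        raise ValueError("mask shape does not match the ring profile")
    outside_fg = mask & ~profile.inside
    total = float(outside_fg.sum())
    if total == 0:
        return 0.0, 0.0
    k_max = int(profile.ring_index[outside_fg].max())
    return total, profile.outer_offset(k_max)


def ring_fascicle_widths(
    mask: np.ndarray, profile: RingProfile, ring: int
) -> list[float]:
    """Fascicle widths (px) along the mid-offset contour of one ring.

    The iso-distance contour at ``(ring - 0.5) * spacing`` is extracted from
    the distance map and walked; maximal runs of foreground along it are the
    fascicles, and each run's arc length is its width.  Runs wrapping around
    a closed contour are merged.
    """
    mask = np.asarray(mask, dtype=bool)
    level = (ring - 0.5) * profile.spacing
    step = 0.25  # px; dense resampling keeps run-end quantisation well below 1 px
    widths: list[float] = []
    for contour in find_contours(profile.distance, level):
        seg = np.hypot(np.diff(contour[:, 0]), np.diff(contour[:, 1]))
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        if arc[-1] <= 0:
            continue
        s = np.arange(0.0, arc[-1], step)
        rr = np.clip(
            np.round(np.interp(s, arc, contour[:, 0])).astype(int), 0, mask.shape[0] - 1
        )
        cc = np.clip(
            np.round(np.interp(s, arc, contour[:, 1])).astype(int), 0, mask.shape[1] - 1
        )
        fg = mask[rr, cc]
        # run lengths of foreground along the resampled contour
        changes = np.flatnonzero(np.diff(fg.astype(np.int8)))
        bounds = np.concatenate([[-1], changes, [len(fg) - 1]])
        runs = []
        run_is_fg = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            runs.append((b - a) * step)
            run_is_fg.append(bool(fg[a + 1]))
        closed = np.allclose(contour[0], contour[-1])
        if closed and len(runs) >= 2 and run_is_fg[0] and run_is_fg[-1]:
            # the run across the start point was split in two
            runs[0] += runs.pop()
            run_is_fg.pop()
        widths.extend(w for w, is_fg in zip(runs, run_is_fg) if is_fg and w > 0)
    return widths


def defasciculation_index(
    mask: np.ndarray,
    profile: RingProfile,
    proximal_ring: int = 2,
    distal_fraction: float = 0.3,
) -> float:
    """Proximal/distal fascicle-width ratio.

    Total fascicle width is measured in the proximal ring (default the
    second) and in the distal ring, the first ring whose outer offset
    exceeds ``distal_fraction`` of the maximal growth distance; the index is
    the proximal total divided by the distal total.
    """
    total, max_distance = outgrowth_area(mask, profile)
    if total == 0:
        raise NoDistalSignal("no labeled signal outside the explant")
    distal_ring = int(np.floor(distal_fraction * max_distance / profile.spacing)) + 1
    proximal = ring_fascicle_widths(mask, profile, proximal_ring)
    distal = ring_fascicle_widths(mask, profile, distal_ring)
    if not distal or sum(distal) == 0:
        raise NoDistalSignal(f"distal ring {distal_ring} contains no signal")
    if not proximal or sum(proximal) == 0:
        raise NoDistalSignal(f"proximal ring {proximal_ring} contains no signal")
    return float(sum(proximal) / sum(distal))


def quantify_explant(
    mask: np.ndarray,
    border_xy: Sequence[tuple[float, float]],
    side: str,
    spacing: float = 25.0,
    proximal_ring: int = 2,
    distal_fraction: float = 0.3,
) -> OutgrowthRecord:
    """Area, maximal distance and defasciculation index of one explant image."""
    profile = build_rings(border_xy, np.asarray(mask).shape, spacing=spacing)
    total, max_distance = outgrowth_area(mask, profile)
    try:
        index = defasciculation_index(
            mask, profile, proximal_ring=proximal_ring, distal_fraction=distal_fraction
        )
    except NoDistalSignal:
        index = None
    return OutgrowthRecord(side, total, max_distance, index)
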