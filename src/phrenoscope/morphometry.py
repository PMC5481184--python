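"""Geometric morphometry of phrenic nerve branching patterns.

One hemidiaphragm is summarised by four measures taken from a traced nerve
skeleton (a rooted tree of 2D points in micrometres) and the binary mask of
the alpha-bungarotoxin-labeled motor endplate band:

* **defasciculation distance** — perpendicular distance from the nerve entry
  point to the straight line tangential to the endplate band (fitted here as
  the band's major principal axis through its centroid);
* **secondary branch count** — number of fascicles of the requested branch
  orders that cross a counting line parallel to the tangent, placed at a
  configurable fraction (default 0.8) of the defasciculation distance from
  the entry point, restricted to the span between the two primary branches;
* **split angle** — angle between the two primary branch directions at the
  split point;
* **endplate thickness** — mean perpendicular extent of the band over equal
  bins (default 30) along its major axis.

Left hemidiaphragms show a short, "T"-like pattern and right ones a longer,
"V"-like pattern; right/left ratio summaries quantify that asymmetry.

Coordinates are Cartesian micrometres.  Raster masks are 0-based with pixel
centres at integer coordinates; pixel (row, col) maps to
``(x, y) = origin + (col, row) * scale``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import networkx as nx
from scipy import ndimage
from skimage.draw import polygon2mask

from . import stats as _stats
from .errors import (
    DegenerateShape,
    EmptyMask,
    InvalidTree,
    NoPrimarySplit,
)

__all__ = [
    "Line2D",
    "EndplateBand",
    "NervePattern",
    "PatternRaster",
    "MorphometryRecord",
    "fit_endplate_axis",
    "defasciculation_distance",
    "branch_crossings",
    "branch_crossings_raster",
    "split_angle",
    "split_angle_raster",
    "endplate_thickness",
    "quantify_hemidiaphragm",
    "lr_ratio_summary",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


@dataclass(frozen=True)
class Line2D:
    """A straight line given by a point on it and a unit direction."""

    point: tuple[float, float]
    direction: tuple[float, float]

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector (|d| = 1 within 1e-9)")

    @property
    def normal(self) -> np.ndarray:
        dx, dy = self.direction
        return np.array([-dy, dx])


@dataclass
class PatternRaster:
    """Rasterised rendering of a nerve pattern, in the same µm frame."""

    mask: np.ndarray  # bool
    scale: float = 1.0  # µm per pixel
    origin: tuple[float, float] = (0.0, 0.0)  # µm of pixel (0, 0)
    order_labels: Optional[np.ndarray] = None  # int, 0 = background


@dataclass
class EndplateBand:
    """Binary mask of the acetylcholine-receptor (endplate) band."""

    mask: np.ndarray
    scale: float = 1.0  # µm per pixel
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2D image")

    @classmethod
    def from_polygon(
        cls,
        vertices_um: Sequence[tuple[float, float]],
        scale: float = 1.0,
        pad: int = 2,
    ) -> "EndplateBand":
        """Rasterise an outline polygon ((x, y) µm vertices) into a band mask."""
        v = np.asarray(vertices_um, dtype=float)
        xmin, ymin = v.min(axis=0) - pad * scale
        xmax, ymax = v.max(axis=0) + pad * scale
        shape = (
            int(np.ceil((ymax - ymin) / scale)) + 1,
            int(np.ceil((xmax - xmin) / scale)) + 1,
        )
        rc = np.column_stack([(v[:, 1] - ymin) / scale, (v[:, 0] - xmin) / scale])
        mask = polygon2mask(shape, rc)
        return cls(mask, scale=scale, origin=(float(xmin), float(ymin)))

    def coords_um(self) -> np.ndarray:
        """Foreground pixel centres as (n, 2) array of (x, y) in µm."""
        rc = np.argwhere(self.mask)
        xy = np.empty((len(rc), 2))
        xy[:, 0] = self.origin[0] + rc[:, 1] * self.scale
        xy[:, 1] = self.origin[1] + rc[:, 0] * self.scale
        return xy


@dataclass
class NervePattern:
    """Rooted tree of 2D points describing one hemidiaphragm's phrenic nerve.

    ``nodes`` maps node id to (x, y) in µm; ``edges`` are
    (parent, child, branch_order) with order 1 = primary, 2 = secondary,
    3 = tertiary.  The graph must be a single tree rooted at ``entry`` and a
    child edge's order may never be lower than its parent edge's.
    """

    nodes: dict[int, tuple[float, float]]
    edges: list[tuple[int, int, int]]
    entry: int
    side: str  # "left" | "right"
    raster: Optional[PatternRaster] = None

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((p, c) for p, c, _ in self.edges)
        if self.entry not in self.nodes:
            raise InvalidTree("entry node is not among the nodes")
        if g.number_of_nodes() > 1:
            if not nx.is_arborescence(g):
                raise InvalidTree(
                    "edges must form a single tree with one parent per node"
                )
            roots = [n for n in g.nodes if g.in_degree(n) == 0]
            if roots != [self.entry]:
                raise InvalidTree("tree must be rooted at the entry node")
        for x, y in self.nodes.values():
            if not (np.isfinite(x) and np.isfinite(y)):
                raise InvalidTree("all coordinates must be finite")
        parent_edge = {c: (p, o) for p, c, o in self.edges}
        for p, c, o in self.edges:
            if p in parent_edge and o < parent_edge[p][1]:
                raise InvalidTree("branch order may not decrease along the tree")
        self._children: dict[int, list[tuple[int, int]]] = {}
        for p, c, o in self.edges:
            self._children.setdefault(p, []).append((c, o))
        self._parent_edge = parent_edge

    # -- tree helpers -------------------------------------------------------

    def xy(self, node: int) -> np.ndarray:
        return np.asarray(self.nodes[node], dtype=float)

    def split_node(self) -> int:
        """First node, walking from the entry, with two or more children."""
        node = self.entry
        seen = set()
        while True:
            kids = self._children.get(node, [])
            if len(kids) >= 2:
                primary = [c for c, o in kids if o == 1]
                if len(primary) != 2:
                    raise NoPrimarySplit(
                        "exactly 2 order-1 branches must leave the split point"
                    )
                return node
            if len(kids) == 0:
                raise NoPrimarySplit("pattern has no split point")
            if node in seen:  # pragma: no cover - guarded by tree invariant
                raise InvalidTree("cycle while searching for split point")
            seen.add(node)
            node = kids[0][0]

    def primary_paths(self) -> list[list[int]]:
        """The two primary branches as node paths starting at the split node."""
        split = self.split_node()
        paths = []
        for child, order in self._children.get(split, []):
            if order != 1:
                continue
            path = [split, child]
            node = child
            while True:
                cont = [c for c, o in self._children.get(node, []) if o == 1]
                if len(cont) != 1:
                    break
                node = cont[0]
                path.append(node)
            paths.append(path)
        return paths

    def branch_ids(self) -> dict[tuple[int, int], int]:
        """Assign each edge to a fascicle (maximal same-order chain).

        An edge continues its parent edge's branch iff it has the same order
        and is the unique child of that order; otherwise it starts a new
        branch.  Each fascicle is counted once at the counting line no matter
        how many of its segments cross.
        """
        ids: dict[tuple[int, int], int] = {}
        next_id = 0
        for p, c, o in self._edges_bfs():
            pe = self._parent_edge.get(p)  # (grandparent, order)
            same_order_sibs = [cc for cc, oo in self._children.get(p, []) if oo == o]
            if pe is not None and pe[1] == o and len(same_order_sibs) == 1:
                ids[(p, c)] = ids[(pe[0], p)]
            else:
                ids[(p, c)] = next_id
                next_id += 1
        return ids

    def _edges_bfs(self) -> Iterable[tuple[int, int, int]]:
        order_of = {(p, c): o for p, c, o in self.edges}
        queue = [self.entry]
        while queue:
            node = queue.pop(0)
            for child, o in self._children.get(node, []):
                yield node, child, o
                queue.append(child)

    def mirrored(self) -> "NervePattern":
        """Reflection across the body midline (x -> -x), side label flipped."""
        side = "right" if self.side == "left" else "left"
        nodes = {i: (-x, y) for i, (x, y) in self.nodes.items()}
        return NervePattern(nodes, list(self.edges), self.entry, side)


@dataclass(frozen=True)
class MorphometryRecord:
    side: str
    defasciculation_distance: float  # µm
    secondary_branch_count: int
    split_angle: float  # degrees in (0, 180]
    endplate_thickness: float  # µm


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def fit_endplate_axis(band: EndplateBand, min_axis_ratio: float = 1.2) -> Line2D:
    """Total-least-squares tangent of the endplate band.

    The tangential straight line is the major principal axis of the band's
    foreground pixel coordinates, passing through the centroid.  Raises
    :class:`DegenerateShape` when the major/minor axis ratio is <= 1.2 (no
    meaningful tangent direction).
    """
    coords = band.coords_um()
    if len(coords) == 0:
        raise EmptyMask("endplate mask contains no foreground pixels")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / max(len(coords) - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    minor, major = float(eigvals[0]), float(eigvals[1])
    ratio = np.inf if minor <= 0 else np.sqrt(major / minor)
    if ratio <= min_axis_ratio:
        raise DegenerateShape(
            f"major/minor axis ratio {ratio:.3f} <= {min_axis_ratio}; "
            "no meaningful tangent"
        )
    direction = _unit(eigvecs[:, 1])
    return Line2D(tuple(centroid), tuple(direction))


def defasciculation_distance(
    entry: Sequence[float], tangent: Line2D
) -> float:
    """Perpendicular distance (µm) from the nerve entry point to the tangent."""
    e = np.asarray(entry, dtype=float)
    p = np.asarray(tangent.point, dtype=float)
    d = np.asarray(tangent.direction, dtype=float)
    rel = e - p
    return float(abs(d[0] * rel[1] - d[1] * rel[0]))


def _counting_frame(entry: np.ndarray, tangent: Line2D):
    """Unit normal pointing from the entry toward the endplate, and distance."""
    n0 = tangent.normal
    s_line = float(n0 @ (np.asarray(tangent.point) - entry))
    if s_line == 0:
        raise ValueError("entry point lies on the tangent; distance is zero")
    n = n0 if s_line > 0 else -n0
    return n, abs(s_line)


def branch_crossings(
    pattern: NervePattern,
    tangent: Line2D,
    fraction: float = 0.8,
    orders: Iterable[int] = (2, 3),
    merge_gap: float = 0.0,
) -> int:
    """Number of fascicles of the given orders crossing the counting line.

    The counting line is parallel to the endplate tangent at
    ``fraction * defasciculation_distance`` from the entry point, measured
    toward the endplate.  Only crossings within the span between the two
    primary-branch extremes are counted, and a fascicle whose polyline
    crosses several times is counted once.  Crossings closer than
    ``merge_gap`` (µm, along the line) are merged into one.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    orders = set(orders)
    entry = pattern.xy(pattern.entry)
    n, dist = _counting_frame(entry, tangent)
    c = fraction * dist
    t_dir = np.asarray(tangent.direction, dtype=float)

    primaries = pattern.primary_paths()  # raises NoPrimarySplit if malformed
    t_primary = [
        float(t_dir @ (pattern.xy(node) - entry)) for path in primaries for node in path
    ]
    t_lo, t_hi = min(t_primary), max(t_primary)

    ids = pattern.branch_ids()
    crossing_ts: dict[int, float] = {}
    for p, ch, o in pattern.edges:
        if o not in orders:
            continue
        a, b = pattern.xy(p), pattern.xy(ch)
        sa, sb = float(n @ (a - entry)), float(n @ (b - entry))
        lo, hi = min(sa, sb), max(sa, sb)
        if not (lo <= c < hi or (hi == c and lo < c)):
            continue
        frac = 0.0 if sb == sa else (c - sa) / (sb - sa)
        t_cross = float(t_dir @ ((a + frac * (b - a)) - entry))
        eps = 1e-9 * max(1.0, abs(t_hi - t_lo))
        if t_lo - eps <= t_cross <= t_hi + eps:
            bid = ids[(p, ch)]
            crossing_ts.setdefault(bid, t_cross)
    if merge_gap <= 0:
        return len(crossing_ts)
    ts = sorted(crossing_ts.values())
    count = 0
    prev = None
    for t in ts:
        if prev is None or t - prev > merge_gap:
            count += 1
        prev = t
    return count


def branch_crossings_raster(
    raster: PatternRaster,
    entry_um: Sequence[float],
    tangent: Line2D,
    fraction: float = 0.8,
    orders: Iterable[int] = (2, 3),
    span: Optional[tuple[float, float]] = None,
    band_px: float = 1.0,
) -> int:
    """Fascicle crossings counted on a rasterised pattern.

    Counts 8-connected foreground components within a ``band_px``-pixel-wide
    band centred on the counting line.  When the raster carries an order
    label image, pixels are restricted to the requested branch orders;
    ``span`` optionally restricts to a (t_min, t_max) interval of positions
    along the tangent direction, relative to the entry point.
    """
    entry = np.asarray(entry_um, dtype=float)
    n, dist = _counting_frame(entry, tangent)
    c = fraction * dist
    t_dir = np.asarray(tangent.direction, dtype=float)

    if raster.order_labels is not None:
        sel_img = np.isin(raster.order_labels, list(set(orders)))
    else:
        sel_img = np.asarray(raster.mask, dtype=bool)
    rc = np.argwhere(sel_img)
    if len(rc) == 0:
        return 0
    xy = np.empty((len(rc), 2))
    xy[:, 0] = raster.origin[0] + rc[:, 1] * raster.scale
    xy[:, 1] = raster.origin[1] + rc[:, 0] * raster.scale
    s = (xy - entry) @ n
    keep = np.abs(s - c) <= band_px * raster.scale / 2.0
    if span is not None:
        t = (xy - entry) @ t_dir
        keep &= (t >= span[0]) & (t <= span[1])
    band = np.zeros_like(sel_img, dtype=bool)
    band[rc[keep, 0], rc[keep, 1]] = True
    _, n_components = ndimage.label(band, structure=np.ones((3, 3), dtype=int))
    return int(n_components)


def split_angle(pattern: NervePattern, n_edges: int = 3) -> float:
    """Angle (degrees, in (0, 180]) between the two primary branch directions.

    Each primary direction is the mean unit vector of its first ``n_edges``
    edges leaving the split point.
    """
    primaries = pattern.primary_paths()
    if len(primaries) != 2:
        raise NoPrimarySplit("pattern lacks two primary branches")
    dirs = []
    for path in primaries:
        vecs = []
        for a, b in zip(path[:-1], path[1:]):
            vecs.append(_unit(pattern.xy(b) - pattern.xy(a)))
            if len(vecs) == n_edges:
                break
        dirs.append(_unit(np.mean(vecs, axis=0)))
    cosang = float(np.clip(dirs[0] @ dirs[1], -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def split_angle_raster(
    raster: PatternRaster,
    entry_um: Sequence[float],
    radius_px: tuple[float, float] = (5.0, 15.0),
) -> float:
    """Split angle estimated from a rasterised pattern.

    Foreground pixels in an annulus around the entry point (which contains
    only the two primary branches when the annulus is narrower than the
    innermost secondary branch) are clustered into two arcs by cutting the
    sorted pixel bearings at their two largest circular gaps; the angle
    between the two mean directions is returned.
    """
    entry = np.asarray(entry_um, dtype=float)
    rc = np.argwhere(raster.mask)
    if len(rc) == 0:
        raise EmptyMask("pattern raster contains no foreground pixels")
    xy = np.empty((len(rc), 2))
    xy[:, 0] = raster.origin[0] + rc[:, 1] * raster.scale
    xy[:, 1] = raster.origin[1] + rc[:, 0] * raster.scale
    rel = xy - entry
    rho = np.hypot(rel[:, 0], rel[:, 1]) / raster.scale
    sel = (rho >= radius_px[0]) & (rho <= radius_px[1])
    if sel.sum() < 4:
        raise NoPrimarySplit("too few pixels around the entry point")
    ang = np.arctan2(rel[sel, 1], rel[sel, 0])
    order = np.argsort(ang)
    ang_sorted = ang[order]
    gaps = np.diff(np.append(ang_sorted, ang_sorted[0] + 2 * np.pi))
    cut1, cut2 = np.sort(np.argsort(gaps)[-2:])
    cluster_a = order[cut1 + 1 : cut2 + 1]
    cluster_b = np.concatenate([order[cut2 + 1 :], order[: cut1 + 1]])
    dirs = []
    for cluster in (cluster_a, cluster_b):
        if len(cluster) == 0:
            raise NoPrimarySplit("could not separate two primary branches")
        dirs.append(_unit(rel[sel][cluster].mean(axis=0)))
    cosang = float(np.clip(dirs[0] @ dirs[1], -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def endplate_thickness(band: EndplateBand, n_bins: int = 30) -> float:
    """Mean width (µm) of the endplate band over bins along its major axis.

    The outlined band is divided into ``n_bins`` equal-length bins along the
    fitted tangent; each bin's width is the extent of the band perpendicular
    to the axis (plus one pixel footprint), and the mean width is returned.
    """
    axis = fit_endplate_axis(band)
    coords = band.coords_um()
    centroid = np.asarray(axis.point)
    d = np.asarray(axis.direction)
    n = axis.normal
    t = (coords - centroid) @ d
    p = (coords - centroid) @ n
    edges = np.linspace(t.min(), t.max(), n_bins + 1)
    idx = np.clip(np.digitize(t, edges) - 1, 0, n_bins - 1)
    widths = []
    for k in range(n_bins):
        pk = p[idx == k]
        if pk.size:
            widths.append(pk.max() - pk.min() + band.scale)
    return float(np.mean(widths))


def quantify_hemidiaphragm(
    pattern: NervePattern,
    band: EndplateBand,
    fraction: float = 0.8,
    orders: Iterable[int] = (2, 3),
) -> MorphometryRecord:
    """All four morphometric measures of one hemidiaphragm."""
    tangent = fit_endplate_axis(band)
    entry = pattern.xy(pattern.entry)
    dist = defasciculation_distance(entry, tangent)
    count = branch_crossings(pattern, tangent, fraction=fraction, orders=orders)
    angle = split_angle(pattern)
    thickness = endplate_thickness(band)
    return MorphometryRecord(pattern.side, dist, count, angle, thickness)


def lr_ratio_summary(pairs, method: str = "per_pair", test: bool = False):
    """Right/left ratio summary of paired measurements (see :mod:`.stats`)."""
    return _stats.lr_ratio_summary(pairs, method=method, test=test)
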