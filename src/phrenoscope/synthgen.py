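"""Synthetic inputs with known ground truth for every analysis module.

The generators emulate the study conditions of the left/right diaphragm
innervation experiments so that each quantification can be validated against
planted parameters without any imaging or array data:

* nerve patterns — a "T"-like left / "V"-like right phrenic skeleton with a
  straight endplate band at a stated perpendicular distance, two primary
  branches at a stated split angle and a stated number of secondary
  branches running from the primaries to the band, plus a rasterised
  rendering so graph and raster quantifications can be compared;
* explant images — radial axon fascicles growing out of a circular explant
  border, with controllable bifurcation and width profiles;
* expression datasets — paired L/R samples of a few embryos (default 3)
  with a planted minority of lateralized transcripts over a log-normal
  baseline and multiplicative log-normal noise;
* per-cell assay tables and western-blot replicates with planted rates.

All randomness comes from one ``numpy.random.default_rng(seed)`` per call;
the seed and every generating parameter are echoed in a :class:`SimTruth`
serialised alongside each artifact.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely.geometry as sgeom
from skimage.draw import line as draw_line
from skimage.draw import polygon2mask
from skimage.morphology import dilation, disk

from .assay_quant import BlotReplicate
from .errors import InvalidParams
from .lateralization import ExpressionMatrix
from .morphometry import EndplateBand, NervePattern, PatternRaster

__all__ = [
    "PatternParams",
    "SimTruth",
    "PRESETS",
    "make_nerve_pattern",
    "make_explant_image",
    "make_expression_dataset",
    "make_cell_assay",
    "make_blot_replicates",
]


@dataclass(frozen=True)
class SimTruth:
    """Generating parameters echoed verbatim alongside a synthetic artifact."""

    generator: str
    seed: int
    params: dict
    derived: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# Nerve patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternParams:
    """Ground-truth geometry of one synthetic hemidiaphragm."""

    side: str
    defasciculation_distance: float  # µm
    n_secondary: int
    split_angle: float  # degrees in (0, 180]
    endplate_length: float = 2000.0  # µm
    endplate_thickness: float = 254.9  # µm
    jitter: float = 0.0  # positional noise sigma, µm
    seed: int = 0
    scale: float = 1.0  # µm per pixel for rasterisation

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise InvalidParams("side must be 'left' or 'right'")
        if not (
            self.defasciculation_distance > 0
            and self.endplate_length > 0
            and self.endplate_thickness > 0
        ):
            raise InvalidParams("distance, length and thickness must be > 0")
        if self.n_secondary < 0:
            raise InvalidParams("n_secondary must be >= 0")
        if not 0 < self.split_angle <= 180:
            raise InvalidParams("split angle must lie in (0, 180] degrees")
        if self.jitter < 0 or self.scale <= 0:
            raise InvalidParams("jitter must be >= 0 and scale > 0")


#: Group-mean presets for the synthetic cohorts.  Distances and branch counts
#: are the published stage means; split angles were only measured around the
#: time of the primary split and the same pair is used for every stage.
#: Endplate thickness was only measured at E15.5; earlier stages carry
#: nominal values scaled with diaphragm growth (see docs/methods.md).
PRESETS: dict[str, PatternParams] = {
    "E15.5-left": PatternParams("left", 77.16, 6, 166.0, endplate_thickness=254.9),
    "E15.5-right": PatternParams("right", 188.51, 11, 132.0, endplate_thickness=529.3),
    "E14.5-left": PatternParams("left", 42.56, 8, 166.0, endplate_thickness=160.0),
    "E14.5-right": PatternParams("right", 135.71, 11, 132.0, endplate_thickness=330.0),
    "E13.5-left": PatternParams("left", 32.76, 6, 166.0, endplate_thickness=100.0),
    "E13.5-right": PatternParams("right", 94.82, 9, 132.0, endplate_thickness=210.0),
}


def _secondary_positions(n: int, halfspan: float) -> np.ndarray:
    """Evenly spaced attachment abscissae, symmetric and avoiding x = 0."""
    if n == 0:
        return np.empty(0)
    if n == 1:
        return np.array([halfspan / 2.0])
    if n % 2 == 0:
        return np.linspace(-halfspan, halfspan, n)
    return np.linspace(-halfspan, halfspan, n + 1)[:-1]


def make_nerve_pattern(
    params: PatternParams,
) -> tuple[NervePattern, EndplateBand, SimTruth]:
    """Synthetic nerve pattern + endplate band with planted morphometry.

    The entry point sits at the planted perpendicular distance below a
    straight endplate band (a rectangle whose major principal axis is the
    tangent).  Two primary branches leave the entry at the planted split
    angle; the planted number of secondary branches run from the primaries
    straight to the tangent line, attached at evenly spaced abscissae chosen
    so that every secondary crosses the counting line at 80% of the
    distance.  Deterministic for a fixed seed; with ``jitter`` 0 the seed is
    unused.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    theta = math.radians(p.split_angle)
    phi = theta / 2.0
    d = p.defasciculation_distance
    half = p.endplate_length / 2.0

    nodes: dict[int, tuple[float, float]] = {0: (0.0, 0.0)}
    edges: list[tuple[int, int, int]] = []
    next_id = 1

    # attachment abscissae stay within 0.56*d*tan(phi) so every secondary
    # attaches below 0.56*d, safely under the counting line at 0.8*d
    if math.tan(phi) > 0:
        s_att = min(0.45 * p.endplate_length, 0.56 * d * math.tan(phi))
    else:  # pragma: no cover - phi in (0, 90] keeps tan > 0
        s_att = 0.45 * p.endplate_length
    xs = _secondary_positions(p.n_secondary, s_att)

    sin_phi, cos_phi = math.sin(phi), math.cos(phi)
    primary_len = half / sin_phi
    base_ts = list(np.linspace(0.0, primary_len, 7)[1:])

    for sign in (-1.0, 1.0):
        attach_ts = sorted(abs(x) / sin_phi for x in xs if math.copysign(1, x) == sign)
        ts: list[float] = []
        for t in sorted(base_ts + attach_ts):
            if not ts or t - ts[-1] > 1e-9:
                ts.append(t)
        attach_nodes: dict[float, int] = {}
        prev = 0
        for t in ts:
            xy = (sign * sin_phi * t, cos_phi * t)
            nodes[next_id] = xy
            edges.append((prev, next_id, 1))
            for ta in attach_ts:
                if abs(ta - t) <= 1e-9:
                    attach_nodes[ta] = next_id
            prev = next_id
            next_id += 1
        # secondary branches: straight to the tangent line, 3 edges each
        for x in xs:
            if math.copysign(1, x) != sign:
                continue
            ta = abs(x) / sin_phi
            start = attach_nodes[min(attach_nodes, key=lambda v: abs(v - ta))]
            x0, y0 = nodes[start]
            prev_node = start
            for frac in (1 / 3, 2 / 3, 1.0):
                xy = (x0, y0 + (d - y0) * frac)
                nodes[next_id] = xy
                edges.append((prev_node, next_id, 2))
                prev_node = next_id
                next_id += 1

    if p.jitter > 0:
        for nid in nodes:
            if nid == 0:
                continue
            dx, dy = rng.normal(0.0, p.jitter, size=2)
            x, y = nodes[nid]
            nodes[nid] = (x + dx, y + dy)

    if p.side == "right":
        nodes = {nid: (-x, y) for nid, (x, y) in nodes.items()}

    band_poly = [
        (-half, d - p.endplate_thickness / 2.0),
        (half, d - p.endplate_thickness / 2.0),
        (half, d + p.endplate_thickness / 2.0),
        (-half, d + p.endplate_thickness / 2.0),
    ]
    band = EndplateBand.from_polygon(band_poly, scale=p.scale)

    raster = _rasterize_pattern(nodes, edges, p.scale)
    pattern = NervePattern(nodes, edges, entry=0, side=p.side, raster=raster)

    truth = SimTruth(
        generator="make_nerve_pattern",
        seed=p.seed,
        params=dataclasses.asdict(p),
        derived={
            "entry_um": [0.0, 0.0],
            "attach_halfspan_um": float(s_att),
            "primary_halfspan_um": float(half),
        },
    )
    return pattern, band, truth


def _rasterize_pattern(
    nodes: dict[int, tuple[float, float]],
    edges: list[tuple[int, int, int]],
    scale: float,
    pad_px: int = 10,
    line_dilation_px: int = 1,
) -> PatternRaster:
    """Draw branches as 1-px polylines dilated to ~3 px width, per order."""
    pts = np.array(list(nodes.values()))
    xmin, ymin = pts.min(axis=0) - pad_px * scale
    xmax, ymax = pts.max(axis=0) + pad_px * scale
    shape = (
        int(np.ceil((ymax - ymin) / scale)) + 1,
        int(np.ceil((xmax - xmin) / scale)) + 1,
    )

    def to_px(xy):
        return (
            int(round((xy[1] - ymin) / scale)),
            int(round((xy[0] - xmin) / scale)),
        )

    orders = sorted({o for _, _, o in edges})
    masks = {}
    for order in orders:
        m = np.zeros(shape, dtype=bool)
        for a, b, o in edges:
            if o != order:
                continue
            r0, c0 = to_px(nodes[a])
            r1, c1 = to_px(nodes[b])
            rr, cc = draw_line(r0, c0, r1, c1)
            m[rr, cc] = True
        masks[order] = dilation(m, disk(line_dilation_px))
    labels = np.zeros(shape, dtype=np.int8)
    for order in sorted(orders, reverse=True):  # lower orders win at overlaps
        labels[masks[order]] = order
    return PatternRaster(
        mask=labels > 0,
        scale=scale,
        origin=(float(xmin), float(ymin)),
        order_labels=labels,
    )


# ---------------------------------------------------------------------------
# Explant images
# ---------------------------------------------------------------------------

def make_explant_image(
    n_fascicles: int = 12,
    fascicle_width: float = 10.0,
    split_fraction: float = 0.0,
    max_extent: float = 180.0,
    seed: int = 0,
    *,
    radius: float = 50.0,
    split_at: float = 0.5,
    conserve_width: bool = True,
    outer_width_factor: float = 1.0,
    split_angle_deg: float = 30.0,
    shape: tuple[int, int] = (512, 512),
) -> tuple[np.ndarray, list[tuple[float, float]], SimTruth]:
    """Synthetic explant outgrowth image: radial fascicles from a circle.

    ``split_fraction`` of the fascicles bifurcate at ``split_at`` of the
    extent; with ``conserve_width`` each child carries half the parent
    width (total conserved), otherwise each child keeps the full width.
    ``outer_width_factor`` scales all widths beyond the split radius, which
    lets a planted proximal/distal total-width ratio be dialled directly.
    Returns (mask, border polygon as (x, y) vertices, truth).
    """
    if n_fascicles < 1:
        raise InvalidParams("n_fascicles must be >= 1")
    if not 0 <= split_fraction <= 1:
        raise InvalidParams("split_fraction must lie in [0, 1]")
    if fascicle_width <= 0 or max_extent <= 0 or radius <= 0:
        raise InvalidParams("width, extent and radius must be > 0")
    if not 0 < split_at < 1:
        raise InvalidParams("split_at must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    cy, cx = shape[0] / 2.0, shape[1] / 2.0
    n_split = int(round(split_fraction * n_fascicles))
    split_ids = set(rng.choice(n_fascicles, size=n_split, replace=False).tolist())

    mask = np.zeros(shape, dtype=bool)

    def draw(poly: sgeom.Polygon):
        coords = np.asarray(poly.exterior.coords)
        mask[:] |= polygon2mask(shape, np.column_stack([coords[:, 1], coords[:, 0]]))

    r_mid = radius + split_at * max_extent
    r_out = radius + max_extent
    w = fascicle_width
    dev = math.radians(split_angle_deg) / 2.0
    for i in range(n_fascicles):
        alpha = 2 * math.pi * i / n_fascicles + 0.25
        u = np.array([math.cos(alpha), math.sin(alpha)])
        start = np.array([cx, cy]) + (radius - 2.0) * u
        mid = np.array([cx, cy]) + r_mid * u
        draw(sgeom.LineString([start, mid]).buffer(w / 2.0, cap_style=2))
        if i in split_ids:
            child_w = (w / 2.0 if conserve_width else w) * outer_width_factor
            for s in (-1.0, 1.0):
                v = np.array([math.cos(alpha + s * dev), math.sin(alpha + s * dev)])
                end = mid + (r_out - r_mid) * v
                draw(sgeom.LineString([mid, end]).buffer(child_w / 2.0, cap_style=2))
        else:
            end = np.array([cx, cy]) + r_out * u
            draw(
                sgeom.LineString([mid, end]).buffer(
                    w * outer_width_factor / 2.0, cap_style=2
                )
            )

    t = np.linspace(0, 2 * math.pi, 97)[:-1]
    border = [(cx + radius * math.cos(a), cy + radius * math.sin(a)) for a in t]

    inner_total = n_fascicles * w
    outer_total = 0.0
    for i in range(n_fascicles):
        if i in split_ids:
            outer_total += 2 * (w / 2.0 if conserve_width else w) * outer_width_factor
        else:
            outer_total += w * outer_width_factor
    truth = SimTruth(
        generator="make_explant_image",
        seed=seed,
        params=dict(
            n_fascicles=n_fascicles,
            fascicle_width=fascicle_width,
            split_fraction=split_fraction,
            max_extent=max_extent,
            radius=radius,
            split_at=split_at,
            conserve_width=conserve_width,
            outer_width_factor=outer_width_factor,
            split_angle_deg=split_angle_deg,
            shape=list(shape),
        ),
        derived=dict(
            split_ids=sorted(split_ids),
            inner_total_width=float(inner_total),
            outer_total_width=float(outer_total),
        ),
    )
    return mask, border, truth


# ---------------------------------------------------------------------------
# Expression datasets
# ---------------------------------------------------------------------------

def make_expression_dataset(
    n_probes: int = 20000,
    n_left_enriched: int = 146,
    n_right_enriched: int = 194,
    fold: float = 2.0,
    noise_sigma_log2: float = 0.1,
    n_embryos: int = 3,
    seed: int = 0,
    *,
    baseline_median: float = 1000.0,
    baseline_sigma_log2: float = 1.0,
    planted_floor: float = 300.0,
    call_floor: float = 50.0,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Paired L/R expression matrix with planted lateralized transcripts.

    Baseline intensities are log-normal around ``baseline_median``
    (quantised to even integers, as array summaries effectively are, so
    that exact fold relations stay exact in floating point); planted probes
    are multiplied by ``fold`` on their enriched side in every embryo;
    i.i.d. normal noise of sigma ``noise_sigma_log2`` is added in log2.
    Calls are present unless the intensity falls below ``call_floor``.
    Planted baselines are floored at ``planted_floor`` so the planted truth
    is not hidden by the expression filter.
    """
    if n_left_enriched + n_right_enriched > n_probes:
        raise InvalidParams("planted counts exceed n_probes")
    if fold <= 1:
        raise InvalidParams("fold must be > 1")
    if noise_sigma_log2 < 0 or n_embryos < 1:
        raise InvalidParams("noise sigma must be >= 0 and n_embryos >= 1")
    rng = np.random.default_rng(seed)
    baseline = baseline_median * 2.0 ** rng.normal(0.0, baseline_sigma_log2, n_probes)
    baseline = np.maximum(2.0 * np.round(baseline / 2.0), 2.0)

    perm = rng.permutation(n_probes)
    left_idx = np.sort(perm[:n_left_enriched])
    right_idx = np.sort(perm[n_left_enriched : n_left_enriched + n_right_enriched])
    if planted_floor:
        planted = np.concatenate([left_idx, right_idx]).astype(int)
        baseline[planted] = np.maximum(
            baseline[planted], 2.0 * np.ceil(planted_floor / 2.0)
        )

    probes = [f"P{i:06d}" for i in range(n_probes)]
    columns = []
    data = {}
    meta_rows = []
    for e in range(1, n_embryos + 1):
        for side in ("L", "R"):
            sample = f"e{e}_{side}"
            columns.append(sample)
            value = baseline.copy()
            if side == "L":
                value[left_idx] = value[left_idx] * fold
            else:
                value[right_idx] = value[right_idx] * fold
            if noise_sigma_log2 > 0:
                value = value * 2.0 ** rng.normal(0.0, noise_sigma_log2, n_probes)
            data[sample] = value
            meta_rows.append({"sample": sample, "embryo": f"e{e}", "side": side})
    values = pd.DataFrame(data, index=probes)
    calls = values >= call_floor
    meta = pd.DataFrame(meta_rows).set_index("sample")
    matrix = ExpressionMatrix(values, calls, meta)
    truth = SimTruth(
        generator="make_expression_dataset",
        seed=seed,
        params=dict(
            n_probes=n_probes,
            n_left_enriched=n_left_enriched,
            n_right_enriched=n_right_enriched,
            fold=fold,
            noise_sigma_log2=noise_sigma_log2,
            n_embryos=n_embryos,
            baseline_median=baseline_median,
            baseline_sigma_log2=baseline_sigma_log2,
            planted_floor=planted_floor,
            call_floor=call_floor,
        ),
        derived=dict(
            left_enriched=[probes[i] for i in left_idx],
            right_enriched=[probes[i] for i in right_idx],
        ),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Cell assays and blots
# ---------------------------------------------------------------------------

def make_cell_assay(
    n_cells_per_side: int = 800,
    p_active_left: float = 0.234,
    p_active_right: float = 0.379,
    p_marker: float = 0.9,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Per-cell marker/activity table with planted activity rates per side."""
    for p in (p_active_left, p_active_right, p_marker):
        if not 0 <= p <= 1:
            raise InvalidParams("probabilities must lie in [0, 1]")
    if n_cells_per_side < 1:
        raise InvalidParams("n_cells_per_side must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for side, p_active in (("left", p_active_left), ("right", p_active_right)):
        marker = rng.random(n_cells_per_side) < p_marker
        active = rng.random(n_cells_per_side) < p_active
        for m, a in zip(marker, active):
            rows.append(
                {"side": side, "marker_positive": bool(m), "activity_positive": bool(a)}
            )
    table = pd.DataFrame(rows)
    truth = SimTruth(
        generator="make_cell_assay",
        seed=seed,
        params=dict(
            n_cells_per_side=n_cells_per_side,
            p_active_left=p_active_left,
            p_active_right=p_active_right,
            p_marker=p_marker,
        ),
    )
    return table, truth


def make_blot_replicates(
    n: int = 5,
    true_ratio: float = 1.22,
    noise_cv: float = 0.0,
    seed: int = 0,
    *,
    sum_spread_log2: float = 0.3,
) -> tuple[list[BlotReplicate], SimTruth]:
    """Western-blot replicates with varying sums and a planted R/L ratio."""
    if true_ratio <= 0:
        raise InvalidParams("true_ratio must be > 0")
    if n < 1 or noise_cv < 0:
        raise InvalidParams("n must be >= 1 and noise_cv >= 0")
    rng = np.random.default_rng(seed)
    reps = []
    for i in range(n):
        loading = 2.0 ** rng.normal(0.0, sum_spread_log2)
        ratio = true_ratio * math.exp(rng.normal(0.0, noise_cv)) if noise_cv > 0 else true_ratio
        reps.append(BlotReplicate(f"blot{i + 1}", loading, loading * ratio))
    truth = SimTruth(
        generator="make_blot_replicates",
        seed=seed,
        params=dict(
            n=n, true_ratio=true_ratio, noise_cv=noise_cv,
            sum_spread_log2=sum_spread_log2,
        ),
    )
    return reps, truth
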