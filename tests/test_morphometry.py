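"""Nerve-pattern morphometry: axes, distances, crossings, angles, widths."""

import math

import numpy as np
import pytest

from _oracles import band_component_crossings
from phrenoscope import morphometry as m
from phrenoscope import synthgen
from phrenoscope.errors import DegenerateShape, EmptyMask, NoPrimarySplit


def rect_band(height, width, scale=1.0):
    mask = np.zeros((height + 20, width + 20), dtype=bool)
    mask[10 : 10 + height, 10 : 10 + width] = True
    return m.EndplateBand(mask, scale=scale)


def simple_pattern(n_secondary=3, distance=100.0, side="left"):
    """Hand-built T-pattern: horizontal primaries, vertical secondaries."""
    nodes = {0: (0.0, 0.0), 1: (-100.0, 5.0), 2: (100.0, 5.0)}
    edges = [(0, 1, 1), (0, 2, 1)]
    nid = 3
    for i in range(n_secondary):
        x = -80.0 + 160.0 * i / max(n_secondary - 1, 1)
        parent = 1 if x < 0 else 2
        nodes[nid] = (x, 5.0)
        edges.append((parent, nid, 2))
        nodes[nid + 1] = (x, distance)
        edges.append((nid, nid + 1, 2))
        nid += 2
    return m.NervePattern(nodes, edges, entry=0, side=side)


class TestEndplateAxis:
    def test_axis_aligned_rectangle(self):
        band = rect_band(50, 300)
        line = m.fit_endplate_axis(band)
        assert abs(line.direction[0]) == pytest.approx(1.0, abs=1e-9)
        coords = band.coords_um()
        assert line.point == pytest.approx(tuple(coords.mean(axis=0)))

    def test_rotated_rectangle_direction_matches_principal_axis_oracle(self):
        # exact pixel coordinate list of a rectangle rotated by 30 degrees
        angle = math.radians(30)
        u = np.array([math.cos(angle), math.sin(angle)])
        v = np.array([-math.sin(angle), math.cos(angle)])
        pts = []
        for t in np.arange(-150, 150.5, 1.0):
            for p in np.arange(-25, 25.5, 1.0):
                pts.append(200 + t * u + p * v)
        pts = np.array(pts)
        mask = np.zeros((400, 400), dtype=bool)
        mask[np.round(pts[:, 1]).astype(int), np.round(pts[:, 0]).astype(int)] = True
        line = m.fit_endplate_axis(m.EndplateBand(mask))
        got = math.degrees(math.atan2(line.direction[1], line.direction[0])) % 180
        assert got == pytest.approx(30.0, abs=0.5)

    def test_square_is_degenerate(self):
        with pytest.raises(DegenerateShape):
            m.fit_endplate_axis(rect_band(50, 50))

    def test_empty_mask(self):
        with pytest.raises(EmptyMask):
            m.fit_endplate_axis(m.EndplateBand(np.zeros((10, 10), dtype=bool)))


class TestDefasciculationDistance:
    def test_point_on_line_is_zero(self):
        line = m.Line2D((0.0, 0.0), (1.0, 0.0))
        assert m.defasciculation_distance((50.0, 0.0), line) == 0.0

    def test_horizontal_line(self):
        line = m.Line2D((0.0, 100.0), (1.0, 0.0))
        assert m.defasciculation_distance((0.0, 0.0), line) == pytest.approx(100.0)

    def test_oblique_line_matches_dense_sampling_oracle(self):
        s = math.sqrt(0.5)
        line = m.Line2D((0.0, 50.0), (s, s))
        got = m.defasciculation_distance((0.0, 0.0), line)
        # oracle: minimum distance over densely sampled points of the line
        ts = np.linspace(-500, 500, 2_000_001)
        pts = np.array([0.0, 50.0]) + ts[:, None] * np.array([s, s])
        oracle = np.hypot(pts[:, 0], pts[:, 1]).min()
        assert got == pytest.approx(35.355, abs=1e-3)
        assert got == pytest.approx(oracle, abs=1e-3)

    def test_rigid_motion_invariance(self, rng):
        entry = rng.normal(size=2) * 50
        point = rng.normal(size=2) * 50
        ang = rng.uniform(0, 2 * math.pi)
        direction = np.array([math.cos(ang), math.sin(ang)])
        d0 = m.defasciculation_distance(entry, m.Line2D(tuple(point), tuple(direction)))
        rot = rng.uniform(0, 2 * math.pi)
        R = np.array([[math.cos(rot), -math.sin(rot)], [math.sin(rot), math.cos(rot)]])
        shift = rng.normal(size=2) * 100
        d1 = m.defasciculation_distance(
            R @ entry + shift, m.Line2D(tuple(R @ point + shift), tuple(R @ direction))
        )
        assert d1 == pytest.approx(d0, rel=1e-9)


class TestBranchCrossings:
    def test_all_secondaries_straddle(self):
        pattern = simple_pattern(n_secondary=7)
        line = m.Line2D((0.0, 100.0), (1.0, 0.0))
        assert m.branch_crossings(pattern, line) == 7

    def test_no_secondaries(self):
        pattern = simple_pattern(n_secondary=0)
        line = m.Line2D((0.0, 100.0), (1.0, 0.0))
        assert m.branch_crossings(pattern, line) == 0

    def test_multi_segment_fascicle_counted_once(self):
        # a secondary whose polyline wiggles across the counting line twice
        nodes = {
            0: (0.0, 0.0), 1: (-100.0, 0.0), 2: (100.0, 0.0),
            3: (10.0, 0.0), 4: (10.0, 85.0), 5: (12.0, 78.0), 6: (12.0, 100.0),
        }
        edges = [(0, 1, 1), (0, 2, 1), (2, 3, 2), (3, 4, 2), (4, 5, 2), (5, 6, 2)]
        pattern = m.NervePattern(nodes, edges, entry=0, side="left")
        line = m.Line2D((0.0, 100.0), (1.0, 0.0))
        assert m.branch_crossings(pattern, line) == 1

    def test_orders_filter_excludes_primaries(self):
        pattern = simple_pattern(n_secondary=4)
        line = m.Line2D((0.0, 100.0), (1.0, 0.0))
        assert m.branch_crossings(pattern, line, orders=(3,)) == 0

    def test_missing_split_raises(self):
        nodes = {0: (0.0, 0.0), 1: (0.0, 10.0)}
        pattern = m.NervePattern(nodes, [(0, 1, 1)], entry=0, side="left")
        line = m.Line2D((0.0, 100.0), (1.0, 0.0))
        with pytest.raises(NoPrimarySplit):
            m.branch_crossings(pattern, line)

    def test_raster_count_matches_band_component_oracle(self, rng):
        """Rasterised crossing counts equal an independently written
        1-pixel-band connected-component oracle on random patterns."""
        for _ in range(30):
            params = synthgen.PatternParams(
                side="left" if rng.random() < 0.5 else "right",
                defasciculation_distance=float(rng.uniform(80, 200)),
                n_secondary=int(rng.integers(0, 13)),
                split_angle=float(rng.uniform(110, 170)),
                endplate_length=600.0,
                endplate_thickness=80.0,
                seed=int(rng.integers(0, 2**31)),
            )
            pattern, band, _ = synthgen.make_nerve_pattern(params)
            tangent = m.fit_endplate_axis(band)
            entry = pattern.xy(pattern.entry)
            oracle, span = band_component_crossings(pattern, tangent)
            got = m.branch_crossings_raster(
                pattern.raster, entry, tangent, span=span
            )
            assert got == oracle
            assert m.branch_crossings(pattern, tangent) == got


class TestSplitAngle:
    def test_collinear_primaries(self):
        nodes = {0: (0.0, 0.0), 1: (-50.0, 0.0), 2: (50.0, 0.0)}
        p = m.NervePattern(nodes, [(0, 1, 1), (0, 2, 1)], entry=0, side="left")
        assert m.split_angle(p) == pytest.approx(180.0)

    def test_perpendicular_primaries(self):
        nodes = {0: (0.0, 0.0), 1: (50.0, 0.0), 2: (0.0, 50.0)}
        p = m.NervePattern(nodes, [(0, 1, 1), (0, 2, 1)], entry=0, side="left")
        assert m.split_angle(p) == pytest.approx(90.0)

    def test_arccos_oracle_at_150_degrees(self):
        a = math.radians(150)
        nodes = {0: (0.0, 0.0), 1: (50.0, 0.0), 2: (50 * math.cos(a), 50 * math.sin(a))}
        p = m.NervePattern(nodes, [(0, 1, 1), (0, 2, 1)], entry=0, side="left")
        v1, v2 = np.array([1.0, 0.0]), np.array([math.cos(a), math.sin(a)])
        oracle = math.degrees(math.acos(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2)))
        assert m.split_angle(p) == pytest.approx(oracle, abs=1e-9)
        assert m.split_angle(p) == pytest.approx(150.0, abs=1e-9)


class TestEndplateThickness:
    def test_rectangle(self):
        assert m.endplate_thickness(rect_band(50, 300)) == pytest.approx(50.0)

    def test_trapezoid_matches_column_extent_oracle(self):
        # perpendicular extent grows linearly from 40 to 60 px along 300 px
        mask = np.zeros((100, 320), dtype=bool)
        widths = np.round(np.linspace(40, 60, 300)).astype(int)
        for i, w in enumerate(widths):
            mask[50 - w // 2 : 50 - w // 2 + w, 10 + i] = True
        got = m.endplate_thickness(m.EndplateBand(mask))
        oracle = float(np.mean([c.sum() for c in mask.T if c.any()]))
        assert got == pytest.approx(50.0, abs=1.0)
        assert got == pytest.approx(oracle, abs=1.0)

    def test_recovers_published_band_widths_within_5_percent(
        self, e155_left, e155_right
    ):
        _, band_l, _ = e155_left
        _, band_r, _ = e155_right
        assert m.endplate_thickness(band_l) == pytest.approx(254.9, rel=0.05)
        assert m.endplate_thickness(band_r) == pytest.approx(529.3, rel=0.05)


class TestQuantifyHemidiaphragm:
    def test_left_preset_recovery(self, e155_left):
        pattern, band, _ = e155_left
        rec = m.quantify_hemidiaphragm(pattern, band)
        assert rec.side == "left"
        assert rec.defasciculation_distance == pytest.approx(77.16, rel=0.02)
        assert rec.secondary_branch_count == 6
        assert rec.split_angle == pytest.approx(166.0, abs=2.0)

    def test_right_preset_recovery(self, e155_right):
        pattern, band, _ = e155_right
        rec = m.quantify_hemidiaphragm(pattern, band)
        assert rec.defasciculation_distance == pytest.approx(188.51, rel=0.02)
        assert rec.secondary_branch_count == 11
        assert rec.split_angle == pytest.approx(132.0, abs=2.0)

    def test_mirrored_pattern_same_record(self, e155_left):
        pattern, band, _ = e155_left
        rec = m.quantify_hemidiaphragm(pattern, band)
        mirrored = pattern.mirrored()
        rec_m = m.quantify_hemidiaphragm(mirrored, band)
        assert rec_m.side == "right"
        assert rec_m.defasciculation_distance == pytest.approx(
            rec.defasciculation_distance, rel=1e-9
        )
        assert rec_m.secondary_branch_count == rec.secondary_branch_count
        assert rec_m.split_angle == pytest.approx(rec.split_angle, rel=1e-9)

    def test_rigid_motion_invariance_graph(self, rng):
        pattern = simple_pattern(n_secondary=5)
        line = m.Line2D((3.0, 100.0), (1.0, 0.0))
        entry = pattern.xy(pattern.entry)
        d0 = m.defasciculation_distance(entry, line)
        c0 = m.branch_crossings(pattern, line)
        a0 = m.split_angle(pattern)
        ang = rng.uniform(0, 2 * math.pi)
        R = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        shift = rng.normal(size=2) * 200
        nodes = {i: tuple(R @ np.array(xy) + shift) for i, xy in pattern.nodes.items()}
        moved = m.NervePattern(nodes, pattern.edges, pattern.entry, pattern.side)
        mline = m.Line2D(
            tuple(R @ np.array([3.0, 100.0]) + shift),
            tuple(R @ np.array([1.0, 0.0])),
        )
        assert m.defasciculation_distance(moved.xy(0), mline) == pytest.approx(d0, rel=1e-9)
        assert m.branch_crossings(moved, mline) == c0
        assert m.split_angle(moved) == pytest.approx(a0, rel=1e-9)

    def test_raster_thickness_rotation_within_2_percent(self):
        from skimage.transform import rotate

        band = rect_band(60, 300)
        t0 = m.endplate_thickness(band)
        rotated = rotate(band.mask.astype(float), 25, resize=True, order=0) > 0.5
        t1 = m.endplate_thickness(m.EndplateBand(rotated))
        assert t1 == pytest.approx(t0, rel=0.02)


class TestLrRatioSummary:
    def test_printed_group_means_give_published_fold(self):
        s = m.lr_ratio_summary([(254.9, 529.3)], method="ratio_of_means")
        assert round(s.mean, 1) == 2.1
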