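"""Paired L/R expression filtering, annotation proportions, qPCR."""

import numpy as np
import pandas as pd
import pytest

from phrenoscope import lateralization as lat
from phrenoscope import synthgen
from phrenoscope.errors import MissingReference, MissingSide


def tiny_matrix(values_by_probe, n_embryos=3):
    """Build an ExpressionMatrix from {probe: [L1, R1, L2, R2, ...]}."""
    columns = []
    meta_rows = []
    for e in range(1, n_embryos + 1):
        for side in ("L", "R"):
            columns.append(f"e{e}_{side}")
            meta_rows.append({"sample": f"e{e}_{side}", "embryo": f"e{e}", "side": side})
    values = pd.DataFrame.from_dict(values_by_probe, orient="index", columns=columns)
    calls = values > 0
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return lat.ExpressionMatrix(values.astype(float), calls, meta)


class TestFilterExpressed:
    def test_present_everywhere_high_intensity_kept(self):
        m = tiny_matrix({"a": [5000, 4000, 5000, 4000, 5000, 4000]})
        assert lat.filter_expressed(m) == ["a"]

    def test_absent_in_one_whole_embryo_removed(self):
        m = tiny_matrix({"a": [500, 400, 0, 0, 500, 400]})
        assert lat.filter_expressed(m) == []

    def test_low_maximal_intensity_removed(self):
        m = tiny_matrix({"a": [150, 199, 120, 150, 180, 199]})
        assert lat.filter_expressed(m) == []
        m2 = tiny_matrix({"a": [150, 200, 120, 150, 180, 199]})
        assert lat.filter_expressed(m2) == ["a"]

    def test_matches_per_probe_loop_oracle(self, rng):
        for _ in range(10):
            n = 100
            vals = {}
            for i in range(n):
                row = rng.integers(0, 800, size=6).astype(float)
                row[rng.random(6) < 0.2] = 0.0
                vals[f"p{i}"] = list(row)
            m = tiny_matrix(vals)
            got = set(lat.filter_expressed(m))
            oracle = set()
            for probe, row in vals.items():
                present = all(
                    row[2 * e] > 0 or row[2 * e + 1] > 0 for e in range(3)
                )
                if present and max(row) >= 200:
                    oracle.add(probe)
            assert got == oracle

    def test_missing_side_rejected_at_construction(self):
        values = pd.DataFrame({"e1_L": [1.0], "e1_R": [1.0], "e2_L": [1.0]}, index=["a"])
        calls = values > 0
        meta = pd.DataFrame(
            {"sample": ["e1_L", "e1_R", "e2_L"], "embryo": ["e1", "e1", "e2"],
             "side": ["L", "R", "L"]}
        ).set_index("sample")
        with pytest.raises(MissingSide):
            lat.ExpressionMatrix(values, calls, meta)


class TestDetectLateralized:
    def test_balanced_probe_not_called(self):
        m = tiny_matrix({"a": [1000, 1000, 900, 900, 1100, 1100]})
        gs = lat.detect_lateralized(m)
        assert gs.left_enriched == [] and gs.right_enriched == []

    def test_mean_rule_uses_mean_of_log2_ratios(self):
        # per-embryo R/L = 1.6, 1.7, 1.2: mean log2 = 0.5689 < log2(1.5),
        # so the probe fails the average rule despite two embryos > 1.5-fold
        m = tiny_matrix({"a": [1000, 1600, 1000, 1700, 1000, 1200]})
        gs = lat.detect_lateralized(m)
        assert gs.right_enriched == []
        # R/L = 1.6, 1.7, 1.3 lifts the mean above the threshold
        m2 = tiny_matrix({"a": [1000, 1600, 1000, 1700, 1000, 1300]})
        gs2 = lat.detect_lateralized(m2)
        assert gs2.right_enriched == ["a"]

    def test_sign_consistency_required(self):
        # two embryos strongly right, one embryo left -> inconsistent
        m = tiny_matrix({"a": [1000, 3000, 1000, 3000, 1000, 900]})
        gs = lat.detect_lateralized(m)
        assert gs.right_enriched == []

    def test_min_embryos_individually_above_fold(self):
        # all right, mean > threshold, but only one embryo > 1.5-fold
        m = tiny_matrix({"a": [1000, 4000, 1000, 1200, 1000, 1200]})
        assert lat.detect_lateralized(m, min_embryos=2).right_enriched == []
        assert lat.detect_lateralized(m, min_embryos=1).right_enriched == ["a"]

    def test_log2_threshold_value(self):
        assert lat.log2_fold_threshold(1.5) == pytest.approx(0.5849, abs=1e-4)

    def test_side_swap_swaps_lists_exactly(self):
        matrix, _ = synthgen.make_expression_dataset(
            n_probes=500, n_left_enriched=10, n_right_enriched=15,
            fold=2.0, noise_sigma_log2=0.2, seed=9,
        )
        gs = lat.detect_lateralized(matrix)
        gs_swapped = lat.detect_lateralized(matrix.swapped_sides())
        assert gs_swapped.left_enriched == gs.right_enriched
        assert gs_swapped.right_enriched == gs.left_enriched

    def test_invariant_to_probe_and_sample_order(self):
        matrix, _ = synthgen.make_expression_dataset(
            n_probes=300, n_left_enriched=8, n_right_enriched=8,
            fold=2.0, noise_sigma_log2=0.2, seed=10,
        )
        gs = lat.detect_lateralized(matrix)
        rng = np.random.default_rng(0)
        probe_perm = rng.permutation(matrix.values.index)
        col_perm = rng.permutation(matrix.values.columns)
        shuffled = lat.ExpressionMatrix(
            matrix.values.loc[probe_perm, col_perm],
            matrix.calls.loc[probe_perm, col_perm],
            matrix.meta,
        )
        gs2 = lat.detect_lateralized(shuffled)
        assert set(gs2.left_enriched) == set(gs.left_enriched)
        assert set(gs2.right_enriched) == set(gs.right_enriched)

    def test_matches_per_probe_loop_oracle(self, rng):
        thr = np.log2(1.5)
        for _ in range(10):
            vals = {}
            for i in range(100):
                base = float(rng.uniform(250, 2000))
                row = base * 2.0 ** rng.normal(0, 0.6, size=6)
                vals[f"p{i}"] = list(row)
            m = tiny_matrix(vals)
            gs = lat.detect_lateralized(m)
            left, right = [], []
            for probe in lat.filter_expressed(m):
                row = vals[probe]
                logr = [np.log2(row[2 * e + 1] / row[2 * e]) for e in range(3)]
                if all(r > 0 for r in logr) and np.mean(logr) > thr + 1e-9 and sum(
                    r > thr + 1e-9 for r in logr
                ) >= 2:
                    right.append(probe)
                if all(r < 0 for r in logr) and -np.mean(logr) > thr + 1e-9 and sum(
                    -r > thr + 1e-9 for r in logr
                ) >= 2:
                    left.append(probe)
            assert gs.left_enriched == left
            assert gs.right_enriched == right


class TestCategoryProportions:
    def test_single_category_is_100_percent(self):
        gs = lat.LateralizedGeneSet(["a"], ["b"], pd.DataFrame(), 1.5, 200, 2)
        ann = pd.DataFrame({"probe": ["a", "b"], "category": ["nucleus", "nucleus"]})
        props = lat.category_proportions(gs, ann)
        assert props.loc["nucleus", "L"] == 100.0
        assert props.loc["nucleus", "R"] == 100.0

    def test_three_one_split(self):
        gs = lat.LateralizedGeneSet(["a", "b", "c", "d"], [], pd.DataFrame(), 1.5, 200, 2)
        ann = pd.DataFrame(
            {"probe": ["a", "b", "c", "d"],
             "category": ["nucleus", "nucleus", "nucleus", "membrane"]}
        )
        props = lat.category_proportions(gs, ann)
        assert props.loc["nucleus", "L"] == 75.0
        assert props.loc["membrane", "L"] == 25.0

    def test_unannotated_fill_and_sum_to_100(self, rng):
        probes = [f"p{i}" for i in range(20)]
        gs = lat.LateralizedGeneSet(probes[:12], probes[12:], pd.DataFrame(), 1.5, 200, 2)
        cats = ["nucleus", "membrane", "cytoplasm"]
        ann = pd.DataFrame(
            {"probe": probes[:15], "category": rng.choice(cats, size=15)}
        )
        props = lat.category_proportions(gs, ann)
        assert props["L"].sum() == pytest.approx(100.0)
        assert props["R"].sum() == pytest.approx(100.0)
        # tally oracle for the left side
        lookup = ann.set_index("probe")["category"]
        counts = {}
        for p in probes[:12]:
            counts[lookup.get(p, "unannotated")] = counts.get(lookup.get(p, "unannotated"), 0) + 1
        for cat, cnt in counts.items():
            assert props.loc[cat, "L"] == pytest.approx(100 * cnt / 12)


class TestQpcrRelative:
    def make_table(self, rows):
        return pd.DataFrame(rows, columns=["embryo", "side", "ct_target", "ct_reference"])

    def test_equal_cts_give_ratio_one(self):
        t = self.make_table([("e1", "L", 25.0, 25.0), ("e1", "R", 28.0, 28.0)])
        out = lat.qpcr_relative(t)
        assert out.loc[0, "rl_ratio"] == pytest.approx(1.0)

    def test_one_cycle_lower_delta_ct_doubles(self):
        t = self.make_table([("e1", "L", 26.0, 24.0), ("e1", "R", 25.0, 24.0)])
        out = lat.qpcr_relative(t)
        assert out.loc[0, "rl_ratio"] == pytest.approx(2.0)

    def test_fractional_delta_ct(self):
        t = self.make_table([("e1", "L", 30.3, 25.0), ("e1", "R", 29.1, 25.0)])
        out = lat.qpcr_relative(t)
        assert out.loc[0, "rl_ratio"] == pytest.approx(2 ** 1.2, rel=1e-9)
        assert out.loc[0, "rl_ratio"] == pytest.approx(2.297, abs=1e-3)

    def test_missing_reference(self):
        t = self.make_table([("e1", "L", 25.0, np.nan), ("e1", "R", 25.0, 24.0)])
        with pytest.raises(MissingReference):
            lat.qpcr_relative(t)
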