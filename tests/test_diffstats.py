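"""Differential regulation: t test, fold changes, classification, Venn."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from phospholfq.diffstats import (
    Comparison,
    classify_regulation,
    comparisons_from_design,
    epsilon_from_matrix,
    heatmap_foldchanges,
    log2_fold_change,
    run_comparison,
    students_t,
    venn_partition,
    volcano_coords,
)
from phospholfq.design import StudyDesign
from phospholfq.xic import QuantMatrix


class TestStudentsT:
    def test_identical_groups_give_t0_p1(self):
        t, p = students_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_worked_example(self):
        t, p = students_t([1, 2, 3, 4], [2, 3, 4, 5])
        assert t == pytest.approx(-1.095445, abs=1e-4)
        assert p == pytest.approx(0.3153, abs=5e-4)

    def test_swap_negates_t_keeps_p(self):
        a, b = [1.0, 2.5, 3.0], [2.0, 4.0, 4.5, 5.0]
        t1, p1 = students_t(a, b)
        t2, p2 = students_t(b, a)
        assert t2 == pytest.approx(-t1, rel=1e-12)
        assert p2 == pytest.approx(p1, rel=1e-12)

    def test_matches_scipy_pooled_t_on_random_instances(self):
        """Independent oracle: scipy's equal-variance two-sample t."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n1, n2 = rng.integers(2, 8, size=2)
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), size=n1)
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), size=n2)
            t_ours, p_ours = students_t(a, b)
            t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
            assert t_ours == pytest.approx(t_ref, abs=1e-10)
            assert p_ours == pytest.approx(p_ref, abs=1e-8)

    def test_zero_variance_unequal_means(self):
        t, p = students_t([1.0, 1.0], [2.0, 2.0])
        assert math.isinf(t) and t < 0
        assert 0 < p < 1e-300

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            students_t([1.0], [1.0, 2.0])


class TestLog2FoldChange:
    def test_fourfold_change(self):
        assert log2_fold_change([100.0] * 3, [400.0] * 3) == pytest.approx(2.0)

    def test_equal_means_give_zero(self):
        assert log2_fold_change([5.0, 7.0], [6.0, 6.0]) == 0.0

    def test_both_zero_is_flagged_zero(self, caplog):
        with caplog.at_level("WARNING"):
            out = log2_fold_change([0.0, 0.0], [0.0, 0.0])
        assert out == 0.0
        assert any("zero" in r.message for r in caplog.records)

    def test_epsilon_keeps_zero_mean_finite(self):
        out = log2_fold_change([0.0, 0.0], [8.0, 8.0], epsilon=2.0)
        assert out == pytest.approx(np.log2(10.0 / 2.0))

    def test_epsilon_from_matrix_is_half_min_positive(self):
        frame = pd.DataFrame({"a": [0.0, 3.0], "b": [8.0, 0.5]})
        assert epsilon_from_matrix(frame) == 0.25
        with pytest.raises(ValueError, match="positive"):
            epsilon_from_matrix(frame * 0.0)


class TestClassifyRegulation:
    @pytest.mark.parametrize(
        "log2fc, p, expected",
        [
            (1.0, 0.005, ("sig_p01", "up")),
            (0.5, 0.001, ("ns", "none")),
            (-0.9, 0.03, ("sig_p05", "down")),
            (0.9, 0.2, ("ns", "none")),
            (-1.5, 0.009, ("sig_p01", "down")),
            (0.8, 0.001, ("ns", "none")),  # gate is strict: |lfc| must exceed 0.8
        ],
    )
    def test_threshold_application(self, log2fc, p, expected):
        assert classify_regulation(log2fc, p) == expected

    @given(
        log2fc=st.floats(-4, 4),
        p=st.floats(1e-12, 1.0),
        dp=st.floats(0, 0.9),
        dfc=st.floats(0, 2),
    )
    def test_monotone_in_evidence(self, log2fc, p, dp, dfc):
        """More extreme fold change or smaller p never demotes a call."""
        order = {"ns": 0, "sig_p05": 1, "sig_p01": 2}
        sig_before, _ = classify_regulation(log2fc, p)
        stronger_fc = log2fc + dfc if log2fc >= 0 else log2fc - dfc
        sig_after, _ = classify_regulation(stronger_fc, max(p * (1 - dp), 1e-15))
        assert order[sig_after] >= order[sig_before]


class TestVolcanoCoords:
    def test_examples(self):
        assert volcano_coords(1.5, 0.01) == pytest.approx((1.5, 2.0))
        assert volcano_coords(0.0, 1.0) == (0.0, 0.0)
        x, y = volcano_coords(-0.8, 0.05)
        assert (x, y) == pytest.approx((-0.8, 1.3010299957))

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError, match="p"):
            volcano_coords(1.0, 0.0)


class TestVennPartition:
    def test_two_set_enumeration(self):
        out = venn_partition({"x": {"A", "B"}, "y": {"B", "C"}})
        counts = dict(zip(out["region"], out["count"]))
        assert counts == {"x": 1, "y": 1, "x&y": 1}

    def test_identical_sets_all_in_intersection(self):
        out = venn_partition({"x": {1, 2}, "y": {1, 2}})
        counts = dict(zip(out["region"], out["count"]))
        assert counts == {"x": 0, "y": 0, "x&y": 2}

    def test_three_disjoint_sets(self):
        out = venn_partition({"a": {1, 2}, "b": {3, 4, 5}, "c": {6, 7, 8, 9}})
        counts = dict(zip(out["region"], out["count"]))
        assert counts["a"] == 2 and counts["b"] == 3 and counts["c"] == 4
        assert all(counts[k] == 0 for k in ("a&b", "a&c", "b&c", "a&b&c"))

    def test_percentages_relative_to_union(self):
        out = venn_partition({"x": {1, 2, 3}, "y": {3, 4}})
        assert out["percent"].sum() == pytest.approx(100.0)

    @given(
        a=st.sets(st.integers(0, 30)),
        b=st.sets(st.integers(0, 30)),
        c=st.sets(st.integers(0, 30)),
    )
    def test_region_counts_sum_to_union(self, a, b, c):
        out = venn_partition({"a": a, "b": b, "c": c})
        assert out["count"].sum() == len(a | b | c)

    def test_set_count_bounds(self):
        with pytest.raises(ValueError, match="2 or 3"):
            venn_partition({"only": {1}})


class TestComparisons:
    def test_groups_must_be_disjoint_and_large_enough(self):
        with pytest.raises(ValueError, match="at least 2"):
            Comparison("c", ("s1",), ("s2", "s3"))
        with pytest.raises(ValueError, match="overlap"):
            Comparison("c", ("s1", "s2"), ("s2", "s3"))

    def test_default_design_yields_three_genotype_contrasts(self):
        comps = comparisons_from_design(StudyDesign().samples())
        assert [c.name for c in comps] == ["vehicle_24h", "oht_24h", "oht_96h"]
        for c in comps:
            assert len(c.group_a) == len(c.group_b) == 4
            assert all(s.startswith("control") for s in c.group_a)
            assert all(s.startswith("mutant") for s in c.group_b)


def _normalized_matrix(data, samples):
    frame = pd.DataFrame(
        data,
        index=pd.Index([f"p{i}" for i in range(len(data))], name="peptide_key"),
        columns=samples,
    )
    return QuantMatrix(frame, level="normalized")


class TestRunComparison:
    def test_result_schema_and_classification(self):
        m = _normalized_matrix(
            [
                [100.0, 110.0, 90.0, 105.0, 420.0, 380.0, 400.0, 410.0],
                [50.0, 55.0, 45.0, 52.0, 50.0, 54.0, 46.0, 51.0],
            ],
            [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
        )
        comp = Comparison("test", tuple(f"a{i}" for i in range(4)),
                          tuple(f"b{i}" for i in range(4)))
        res = run_comparison(m, comp)
        assert list(res.columns) == [
            "peptide_key", "log2fc", "t", "p_value", "sig_class", "direction",
        ]
        assert res.loc[0, "sig_class"] == "sig_p01"
        assert res.loc[0, "direction"] == "up"
        assert res.loc[1, "sig_class"] == "ns"

    def test_missing_sample_rejected(self):
        m = _normalized_matrix([[1.0, 2.0, 3.0, 4.0]], ["a1", "a2", "b1", "b2"])
        comp = Comparison("test", ("a1", "a2"), ("b1", "nope"))
        with pytest.raises(ValueError, match="nope"):
            run_comparison(m, comp)


class TestHeatmapFoldchanges:
    def test_equal_means_give_zero_row(self):
        m = _normalized_matrix(
            [[10.0, 10.0, 10.0, 10.0]], ["a1", "a2", "b1", "b2"]
        )
        comp = Comparison("c", ("a1", "a2"), ("b1", "b2"))
        out = heatmap_foldchanges(m, [comp], ["p0"])
        assert out.loc["p0", "c"] == 0.0
        linear = heatmap_foldchanges(m, [comp], ["p0"], linear=True)
        assert linear.loc["p0", "c"] == 1.0

    def test_unknown_key_rejected(self):
        m = _normalized_matrix([[1.0, 2.0, 3.0, 4.0]], ["a1", "a2", "b1", "b2"])
        comp = Comparison("c", ("a1", "a2"), ("b1", "b2"))
        with pytest.raises(ValueError, match="ghost"):
            heatmap_foldchanges(m, [comp], ["ghost"])

    def test_empty_subset_gives_empty_matrix(self):
        m = _normalized_matrix([[1.0, 2.0, 3.0, 4.0]], ["a1", "a2", "b1", "b2"])
        comp = Comparison("c", ("a1", "a2"), ("b1", "b2"))
        out = heatmap_foldchanges(m, [comp], [])
        assert out.shape == (0, 1)

    def test_injected_effect_recovered(self, small_study):
        """Regulated peptides in the synthetic study show their injected effect."""
        from phospholfq.abundance import (
            average_technical_replicates,
            normalize_total_intensity,
        )
        from phospholfq.xic import collapse_identifications, quantify_all

        design, truth, runs, ids, gt = small_study
        m = quantify_all(runs, collapse_identifications(ids))
        rep = dict(zip(gt.runs["run_id"], gt.runs["sample_id"]))
        norm = normalize_total_intensity(average_technical_replicates(m, rep))
        comps = comparisons_from_design(design.samples())
        regulated = gt.regulated_keys()
        out = heatmap_foldchanges(norm, comps, regulated)
        truth_lfc = gt.peptides.set_index("peptide_key").loc[regulated, "true_log2fc"]
        # n=2 per group and CV 0.2: generous agreement band
        assert np.corrcoef(out.iloc[:, 0], truth_lfc)[0, 1] > 0.9
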