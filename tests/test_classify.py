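import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import oracle_classify, oracle_group_satisfiable
from tissueclass import (
    CATEGORIES,
    ClassifierParams,
    ConfigurationError,
    ExpressionMatrix,
    MatrixValueError,
    classify_gene,
    classify_matrix,
    summarize,
    summary_from_counts,
)

T6 = list("ABCDEF")


def expr(values, genes=None, tissues=None):
    values = np.atleast_2d(np.asarray(values, float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    tissues = tissues or [f"t{i:02d}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=tissues))


class TestSingleGeneRules:
    @pytest.mark.parametrize(
        "values,tissues,category,elevated,n_detected",
        [
            ([0.0] * 6, T6, "not_detected", (), 0),
            ([10.0] * 6, T6, "expressed_in_all", (), 6),
            ([10, 1, 1, 1, 1, 1], T6, "tissue_enriched", ("A",), 6),
            # the fivefold rule is inclusive: exactly 5x the runner-up counts
            ([5.0, 1.0, 0.1, 0.1], list("ABCD"), "tissue_enriched", ("A",), 2),
            ([10, 9, 1, 1, 1, 1], T6, "group_enriched", ("A", "B"), 6),
            # sixfold pair over a 0.1 background: the group rule fires even
            # though only two of six tissues are detected
            ([0.6, 0.6, 0.1, 0.1, 0.1, 0.1], T6, "group_enriched", ("A", "B"), 2),
            # detected in two tissues with every fold rule failing
            ([0.6, 0.6, 0.2, 0.2, 0.2, 0.2], T6, "mixed", (), 2),
            # one high tissue, seven moderate, 24 low: enriched fails (10 < 20),
            # every group of <= 7 leaves a moderate outside, but 10 >= 5 x 1.5625
            (
                [10] + [4] * 7 + [0.5] * 24,
                [f"t{i:02d}" for i in range(32)],
                "enhanced",
                ("t00",),
                32,
            ),
        ],
    )
    def test_worked_examples(self, params, values, tissues, category, elevated, n_detected):
        rec = classify_gene(values, tissues, params)
        assert rec.category == category
        assert rec.elevated_tissues == elevated
        assert rec.n_detected == n_detected

    def test_enriched_fold_score_is_ratio_to_runner_up(self, params):
        rec = classify_gene([10, 1, 1, 1, 1, 1], T6, params)
        assert rec.fold_score == pytest.approx(10.0)

    def test_group_fold_score_is_group_mean_over_outside_max(self, params):
        rec = classify_gene([10, 9, 1, 1, 1, 1], T6, params)
        assert rec.fold_score == pytest.approx(9.5)

    def test_enriched_with_zero_background_uses_guarded_denominator(self, params):
        rec = classify_gene([3.0, 0.0, 0.0, 0.0], list("ABCD"), params)
        assert rec.category == "tissue_enriched"
        # denominator guarded at cutoff / fold = 0.1
        assert rec.fold_score == pytest.approx(30.0)

    def test_boundary_is_inclusive_for_enhanced(self, params):
        # 5 + 7*3 + 24*0.25 = 32, so the overall mean is exactly 1.0 and the
        # high tissue sits exactly at fold x mean; "at least fivefold" is >=
        values = [5.0] + [3.0] * 7 + [0.25] * 24
        rec = classify_gene(values, [f"t{i:02d}" for i in range(32)], params)
        assert rec.category == "enhanced"
        assert rec.elevated_tissues == ("t00",)
        assert rec.fold_score == pytest.approx(5.0)

    def test_fewer_than_two_tissues_rejected(self, params):
        with pytest.raises(ConfigurationError):
            classify_gene([1.0], ["A"], params)

    def test_negative_value_rejected(self, params):
        with pytest.raises(MatrixValueError):
            classify_gene([1.0, -0.1], ["A", "B"], params)

    def test_tied_values_classify_identically_under_permutation(self, params):
        rec = classify_gene([1, 10, 10, 1, 1, 0.2], T6, params)
        assert rec.category == "group_enriched"
        assert rec.elevated_tissues == ("B", "C")
        perm = classify_gene([10, 1, 1, 10, 1, 0.2], ["C", "A", "D", "B", "E", "F"], params)
        assert perm.elevated_tissues == ("B", "C")


class TestAgainstOracle:
    def test_random_matrix_matches_straight_line_reimplementation(self, params):
        rng = np.random.default_rng(42)
        from conftest import random_profiles

        values = random_profiles(rng, 500, 12)
        m = expr(values)
        recs = classify_matrix(m, params)
        seen = set()
        for i, rec in enumerate(recs):
            expected, _ = oracle_classify(values[i])
            assert rec.category == expected, f"gene {i}"
            seen.add(rec.category)
        assert seen == set(CATEGORIES)  # the fixture exercises every rule

    def test_top_k_group_search_equals_exhaustive_enumeration(self, params):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(4, 11))
            v = np.round(rng.lognormal(0, 2, n), 3)
            rec = classify_gene(v, [f"t{i}" for i in range(n)], params)
            for k in range(2, min(7, n - 1) + 1):
                brute = oracle_group_satisfiable(list(v), k)
                if brute and rec.category in ("tissue_enriched",):
                    continue  # enriched takes precedence over any group
                if rec.category == "group_enriched" and len(rec.elevated_tissues) == k:
                    assert brute
                    break
                assert not brute, f"missed satisfiable group of size {k} for {v}"


class TestProperties:
    def test_permutation_invariance(self, params):
        rng = np.random.default_rng(3)
        values = rng.lognormal(0, 2, size=(50, 10))
        m = expr(values)
        perm = list(rng.permutation(10))
        m2 = ExpressionMatrix(m.values.iloc[:, perm])
        for r1, r2 in zip(classify_matrix(m, params), classify_matrix(m2, params)):
            assert r1.category == r2.category
            assert r1.elevated_tissues == r2.elevated_tissues

    def test_partition_every_gene_gets_one_category(self, small_atlas_classified):
        _, classes, _ = small_atlas_classified
        summary = summarize(classes)
        assert sum(summary.counts.values()) == summary.total == len(classes)

    def test_total_elevated_non_increasing_in_fold(self, small_atlas_classified):
        expr_m, _, _ = small_atlas_classified
        elevated = []
        for fold in (2.0, 5.0, 10.0, 100.0):
            p = ClassifierParams(fold=fold)
            elevated.append(summarize(classify_matrix(expr_m, p)).total_elevated)
        assert elevated == sorted(elevated, reverse=True)

    def test_not_detected_non_decreasing_in_cutoff(self, small_atlas_classified):
        expr_m, _, _ = small_atlas_classified
        nd = []
        for cutoff in (0.1, 0.5, 1.0):
            p = ClassifierParams(cutoff=cutoff)
            nd.append(summarize(classify_matrix(expr_m, p)).counts["not_detected"])
        assert nd == sorted(nd)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        values=st.lists(st.floats(min_value=0.5, max_value=1e4), min_size=3, max_size=12),
        c=st.floats(min_value=1.0, max_value=1e3),
    )
    def test_scale_invariance_above_cutoff(self, values, c):
        """Scaling a fully detected profile by c >= 1 never changes its category."""
        p = ClassifierParams()
        tissues = [f"t{i}" for i in range(len(values))]
        before = classify_gene(values, tissues, p)
        after = classify_gene([v * c for v in values], tissues, p)
        assert before.category == after.category


class TestSummarize:
    def test_totals_follow_from_per_category_counts(self):
        s = summary_from_counts(
            dict(zip(CATEGORIES, [2359, 1208, 3227, 8385, 2484, 1021]))
        )
        assert s.total == 18684
        assert s.total_elevated == 6794

    def test_alternative_atlas_counts(self):
        s = summary_from_counts(
            dict(zip(CATEGORIES, [2289, 1307, 3077, 8459, 2537, 1015]))
        )
        assert s.total == 18684
        assert s.total_elevated == 6673

    def test_single_gene_summary(self, params):
        recs = classify_matrix(expr([[10.0] * 6]), params)
        s = summarize(recs)
        assert s.counts["expressed_in_all"] == 1
        assert sum(s.counts.values()) == 1
        assert s.percentages["expressed_in_all"] == 100

    def test_per_tissue_counts_attribute_group_genes_to_each_member(self, params):
        recs = classify_matrix(expr([[10, 9, 1, 1, 1, 1]], tissues=T6), params)
        s = summarize(recs)
        assert s.per_tissue.loc["A", "group_enriched"] == 1
        assert s.per_tissue.loc["B", "group_enriched"] == 1

    def test_empty_classification_rejected(self):
        with pytest.raises(ConfigurationError):
            summarize([])
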