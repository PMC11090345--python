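"""Evaluation statistics: TR, NMI, PD/APD, proportional size, and reports."""

import math

import numpy as np
import pytest
from sklearn.metrics import normalized_mutual_info_score

from micclust.evaluate import (
    EvaluationRecord,
    adjusted_performance_difference,
    build_report,
    compare_feature_sets,
    comparison_table,
    nmi,
    performance_difference,
    proportional_size,
    true_rate,
)


def balanced_labels(n=63):
    return np.array(["cancer", "blood"] * n, dtype=object)


class TestTrueRate:
    def test_perfect_split(self):
        labels = balanced_labels(3)
        clusters = np.where(labels == "cancer", 1, 2)
        assert true_rate(clusters, labels) == 1.0

    def test_known_confusion_matches_mapping_enumeration(self):
        # clusters of sizes 70/56, with 40 of the 63 cancer samples in cluster 1
        labels = np.array(["cancer"] * 63 + ["blood"] * 63, dtype=object)
        clusters = np.concatenate(
            [np.repeat(1, 40), np.repeat(2, 23), np.repeat(1, 30), np.repeat(2, 33)]
        )
        # mapping A: cluster1=cancer -> 40 + 33 correct; mapping B: 23 + 30
        expected = max(40 + 33, 23 + 30) / 126
        assert true_rate(clusters, labels) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(10))
    def test_floor_of_one_half_under_best_mapping(self, seed):
        rng = np.random.default_rng(seed)
        labels = balanced_labels(63)
        clusters = rng.integers(1, 3, size=126)
        if len(np.unique(clusters)) < 2:
            clusters[0] = 3 - clusters[0]
        assert true_rate(clusters, labels) >= 0.5

    def test_more_than_two_clusters_rejected(self):
        with pytest.raises(ValueError):
            true_rate(np.array([1, 2, 3, 1]), np.array(["a", "b", "a", "b"]))


class TestNmi:
    def test_identical_partitions_score_one(self):
        labels = balanced_labels(10)
        clusters = np.where(labels == "cancer", 1, 2)
        assert nmi(clusters, labels) == pytest.approx(1.0)

    def test_single_cluster_scores_zero(self):
        assert nmi(np.ones(20), balanced_labels(10)) == 0.0

    def test_hand_computed_contingency(self):
        # contingency [[30,10],[5,25]]: direct entropy arithmetic
        clusters = np.concatenate([np.repeat(1, 40), np.repeat(2, 30)])
        labels = np.concatenate(
            [np.repeat("a", 30), np.repeat("b", 10), np.repeat("a", 5), np.repeat("b", 25)]
        )

        def H(freqs):
            return -sum(f * math.log2(f) for f in freqs if f > 0)

        hc = H([40 / 70, 30 / 70])
        hl = H([35 / 70, 35 / 70])
        hcl = H([30 / 70, 10 / 70, 5 / 70, 25 / 70])
        expected = (hc + hl - hcl) / math.sqrt(hc * hl)
        assert nmi(clusters, labels) == pytest.approx(expected, abs=1e-12)
        # independent library cross-check (same geometric normalization)
        assert nmi(clusters, labels) == pytest.approx(
            normalized_mutual_info_score(labels, clusters, average_method="geometric"),
            abs=1e-9,
        )

    def test_symmetric_and_label_permutation_invariant(self, rng):
        clusters = rng.integers(1, 3, size=60)
        labels = rng.integers(1, 3, size=60)
        assert nmi(clusters, labels) == pytest.approx(nmi(labels, clusters), abs=1e-12)
        assert nmi(3 - clusters, labels) == pytest.approx(nmi(clusters, labels), abs=1e-12)

    def test_unknown_normalization_rejected(self):
        with pytest.raises(ValueError):
            nmi(np.array([1, 2]), np.array([1, 2]), average="harmonic")


class TestPerformanceDifferences:
    def test_strong_improvement_example(self):
        assert performance_difference(0.524, 0.675) == pytest.approx(15.1)
        assert round(adjusted_performance_difference(0.524, 0.675)) == 29

    def test_moderate_improvement_example(self):
        assert performance_difference(0.571, 0.651) == pytest.approx(8.0)
        assert adjusted_performance_difference(0.571, 0.651) == pytest.approx(14.0, abs=0.05)

    def test_equal_rates_give_zero(self):
        assert performance_difference(0.6, 0.6) == 0.0
        assert adjusted_performance_difference(0.6, 0.6) == 0.0

    def test_antisymmetry_under_argument_swap(self):
        assert performance_difference(0.5, 0.7) == -performance_difference(0.7, 0.5)

    @pytest.mark.parametrize("efs,rfs", [(0.52, 0.61), (0.66, 0.55), (0.5, 0.5)])
    def test_apd_consistency_with_pd(self, efs, rfs):
        pd = performance_difference(efs, rfs)
        apd = adjusted_performance_difference(efs, rfs)
        assert apd == pytest.approx(pd / efs, abs=1e-12)

    def test_zero_efs_rate_is_undefined(self):
        with pytest.raises(ValueError):
            adjusted_performance_difference(0.0, 0.5)


class TestProportionalSize:
    def test_smallest_reduced_set(self):
        assert round(proportional_size(5, 8149), 2) == 0.06

    def test_largest_reduced_set(self):
        assert round(proportional_size(392, 22215), 2) == 1.76

    def test_full_set_is_one_hundred_percent(self):
        assert proportional_size(100, 100) == 100.0

    def test_zero_selection_reports_zero(self):
        assert proportional_size(0, 10) == 0.0

    def test_oversized_selection_rejected(self):
        with pytest.raises(ValueError):
            proportional_size(11, 10)


class TestReports:
    def records(self):
        out = []
        for i, chrom in enumerate(["chr2", "chr1", "chr3"]):
            out.append(EvaluationRecord(chrom, "EFS", 100, 0.56, 0.012))
            out.append(EvaluationRecord(chrom, "MIC>0.65", 4, 0.51, 0.0002))
            clustered = chrom != "chr3"
            out.append(
                EvaluationRecord(chrom, "MIC>0.52", 13 if clustered else 0,
                                 0.59 if clustered else 0.0,
                                 0.02 if clustered else 0.0, clustered=clustered)
            )
        return out

    def test_three_configurations_give_nine_metric_columns(self):
        df = build_report(self.records())
        assert df.shape == (3, 9)

    def test_rows_sorted_by_chromosome_number(self):
        df = build_report(self.records())
        assert list(df.index) == ["chr1", "chr2", "chr3"]

    def test_unclustered_block_renders_as_zeros(self):
        df = build_report(self.records())
        row = df.loc["chr3"]
        assert row["MIC>0.52__features"] == 0
        assert row["MIC>0.52__nmi"] == 0.0
        assert row["MIC>0.52__true_rate"] == 0.0

    def test_duplicate_chromosome_configuration_rejected(self):
        records = self.records()
        records.append(EvaluationRecord("chr1", "EFS", 100, 0.5, 0.0))
        with pytest.raises(ValueError, match="duplicate"):
            build_report(records)

    def test_comparison_skips_unclustered_and_ranks_by_apd(self):
        comps = compare_feature_sets(self.records())
        assert [c.chromosome_id for c in comps] == ["chr1", "chr2"]
        table = comparison_table(comps)
        assert list(table["apd_pct"]) == sorted(table["apd_pct"], reverse=True)
        first = comps[0]
        assert first.pd == pytest.approx((first.tr_rfs - first.tr_efs) * 100)
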