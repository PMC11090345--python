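"""MIC engine: grid MI arithmetic, the constrained grid search, and its oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micclust import cohort as co
from micclust import mic
from micclust.mic import (
    MICPreconditionError,
    admissible_shapes,
    grid_budget,
    grid_mutual_information,
    max_grid_mi,
    mic_exhaustive_oracle,
    mic_profile,
    mic_score,
)

from conftest import make_cohort


def entropy(freqs):
    return -sum(f * math.log2(f) for f in freqs if f > 0)


class TestGridMutualInformation:
    def test_perfect_diagonal_is_one_bit(self):
        assert grid_mutual_information(np.array([[5, 0], [0, 5]])) == pytest.approx(1.0)

    def test_product_distribution_is_zero(self):
        assert grid_mutual_information(np.array([[3, 3], [3, 3]])) == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_mixed_table(self):
        # counts [[4,1],[1,4]]: H_x = H_y = 1 bit, H_xy from cells {.4,.1,.1,.4}
        counts = np.array([[4, 1], [1, 4]])
        expected = entropy([0.5, 0.5]) * 2 - entropy([0.4, 0.1, 0.1, 0.4])
        assert grid_mutual_information(counts) == pytest.approx(expected, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            grid_mutual_information(np.array([[1, -1], [0, 2]]))

    @pytest.mark.parametrize("seed", range(5))
    def test_mi_bounded_by_marginal_entropies(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 9, size=(3, 4))
        counts[0, 0] += 1
        p = counts / counts.sum()
        hx = entropy(p.sum(axis=1))
        hy = entropy(p.sum(axis=0))
        mi = grid_mutual_information(counts)
        assert -1e-12 <= mi <= min(hx, hy) + 1e-12


class TestMaxGridMI:
    def test_monotone_relationship_saturates_two_by_two(self):
        x = np.arange(20.0)
        assert max_grid_mi(x, x, 2, 2) == pytest.approx(1.0)

    def test_matches_brute_force_over_all_single_cut_grids(self):
        # independent x and y: compare to direct enumeration of the 11 x 11 cut pairs
        x = np.arange(12.0)
        y = x[np.random.default_rng(42).permutation(12)]
        best = 0.0
        xs, ys = np.sort(x), np.sort(y)
        for i in range(1, 12):
            for j in range(1, 12):
                xcut, ycut = (xs[i - 1] + xs[i]) / 2, (ys[j - 1] + ys[j]) / 2
                counts = np.zeros((2, 2))
                for xi, yi in zip(x, y):
                    counts[int(xi > xcut), int(yi > ycut)] += 1
                best = max(best, grid_mutual_information(counts))
        assert max_grid_mi(x, y, 2, 2) == pytest.approx(best, abs=1e-12)

    def test_constant_axis_scores_zero(self):
        y = np.arange(15.0)
        assert max_grid_mi(np.ones(15), y, 2, 2) == 0.0

    def test_bounded_by_log_smaller_bin_count(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert max_grid_mi(x, y, 3, 2) <= math.log2(2) + 1e-12


class TestAdmissibleShapes:
    def test_budget_is_not_floored(self):
        assert grid_budget(63) == pytest.approx(63**0.6)

    @pytest.mark.parametrize("n", [11, 20, 63, 126])
    def test_matches_direct_enumeration_of_the_budget_rule(self, n):
        B = n**0.6
        expected = sorted(
            (nx, ny) for nx in range(2, 40) for ny in range(2, 40) if nx * ny < B
        )
        assert admissible_shapes(n) == expected

    def test_smallest_usable_n_admits_only_two_by_two(self):
        assert admissible_shapes(11) == [(2, 2)]

    def test_study_size_includes_product_twelve_grids(self):
        # 63**0.6 = 12.0117 > 12, so 2x6 and 3x4 grids are admissible
        shapes = admissible_shapes(63)
        assert (2, 6) in shapes and (3, 4) in shapes
        assert len(shapes) == 12


class TestMicScore:
    def test_noiseless_functional_relationship(self, rng):
        x = rng.normal(size=63)
        assert mic_score(x, x) == 1.0

    def test_constant_input_scores_zero(self, rng):
        assert mic_score(np.full(63, 2.0), rng.normal(size=63)) == 0.0

    def test_too_small_sample_names_the_budget(self):
        with pytest.raises(MICPreconditionError, match="B\\(n\\)"):
            mic_score(np.arange(10.0), np.arange(10.0))

    def test_non_finite_rejected(self):
        x = np.arange(12.0)
        x[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            mic_score(x, np.arange(12.0))

    def test_small_sample_equals_exhaustive_oracle(self):
        rng = np.random.default_rng(14)
        x, y = rng.normal(size=14), rng.normal(size=14)
        assert mic_score(x, y) == pytest.approx(mic_exhaustive_oracle(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_heuristic_never_exceeds_oracle(self, seed):
        rng = np.random.default_rng(400 + seed)
        x, y = rng.normal(size=18), rng.normal(size=18)
        assert mic_score(x, y, exhaustive=False) <= mic_exhaustive_oracle(x, y) + 1e-12

    @pytest.mark.parametrize("seed", range(6))
    def test_symmetry_is_exact(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=40), rng.normal(size=40)
        assert mic_score(x, y) == mic_score(y, x)

    @pytest.mark.parametrize("seed", range(6))
    def test_monotone_transformations_leave_mic_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=35), rng.normal(size=35)
        assert mic_score(x, y) == mic_score(np.exp(x), y**3)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_score_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(11, 40))
        x = rng.choice([1.5, 2.0, 2.5, 3.0], size=n)  # heavy ties on purpose
        y = rng.normal(size=n)
        assert 0.0 <= mic_score(x, y) <= 1.0


class TestOracle:
    def test_refuses_large_samples(self, rng):
        with pytest.raises(ValueError, match="n <= 20"):
            mic_exhaustive_oracle(rng.normal(size=21), rng.normal(size=21))

    def test_identity_scores_one(self):
        x = np.arange(12.0)
        assert mic_exhaustive_oracle(x, x) == 1.0


class TestMicProfile:
    def test_identical_columns_score_one(self):
        cohort = make_cohort(n=14, m=3, seed=5)
        cohort.cancer_cn[:, 0] = cohort.blood_cn[:, 0]
        profile = mic_profile(cohort)
        assert profile.scores[0] == 1.0
        assert profile.m == 3 and profile.n == 14

    def test_elementwise_equal_to_oracle_at_small_n(self):
        cohort = make_cohort(n=14, m=3, seed=8)
        profile = mic_profile(cohort)
        for j in range(3):
            expected = mic_exhaustive_oracle(cohort.blood_cn[:, j], cohort.cancer_cn[:, j])
            assert profile.scores[j] == pytest.approx(expected, abs=1e-12)

    def test_patient_permutation_invariance(self):
        cohort = make_cohort(n=30, m=8, seed=4)
        perm = np.random.default_rng(0).permutation(30)
        shuffled = co.PairedCohort(
            cohort.chromosome_id,
            [cohort.patient_ids[i] for i in perm],
            list(cohort.loci),
            cohort.cancer_cn[perm],
            cohort.blood_cn[perm],
        )
        assert np.array_equal(mic_profile(cohort).scores, mic_profile(shuffled).scores)

    def test_batch_path_equals_per_locus_path(self):
        # n = 63 routes through the compiled batch loop; it must agree with
        # mic_score exactly, column by column
        cohort = make_cohort(n=63, m=25, seed=11)
        batch = mic_profile(cohort).scores
        ref = np.array(
            [mic_score(cohort.blood_cn[:, j], cohort.cancer_cn[:, j]) for j in range(25)]
        )
        assert np.array_equal(batch, ref)

    def test_profile_tsv_round_trip(self, tmp_path):
        cohort = make_cohort(n=14, m=5, seed=1)
        profile = mic_profile(cohort)
        path = tmp_path / "mic_chrT.tsv"
        mic.write_profile(profile, path)
        back = mic.read_profile(path, chromosome_id="chrT", n=14)
        assert np.array_equal(back.scores, profile.scores)
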