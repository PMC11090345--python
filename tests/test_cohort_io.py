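"""Paired-cohort I/O: layouts, validation, and the unlabeled view."""

import numpy as np
import pytest

from micclust.cohort import (
    INTERLEAVED,
    PAIRED_COLUMNS,
    CohortParseError,
    CohortStructureError,
    PairedCohort,
    default_patient_ids,
    read_cohort,
    to_unlabeled,
    write_cohort,
)

from conftest import make_cohort


def write_lines(path, lines, sep="\t"):
    path.write_text("\n".join(sep.join(row) for row in lines) + "\n")


class TestReadInterleaved:
    def test_shape_bookkeeping(self, tmp_path):
        # 3 patients x 2 groups, 4 loci
        lines = [["observation", "group", "loc_1", "loc_2", "loc_3", "loc_4"]]
        for i in range(3):
            lines.append([str(2 * i + 1), "cancer", "2.1", "2.2", "1.9", "2.0"])
            lines.append([str(2 * i + 2), "blood", "2.0", "2.0", "2.1", "1.8"])
        path = tmp_path / "chr9.tsv"
        write_lines(path, lines)
        cohort = read_cohort(path, INTERLEAVED)
        assert (cohort.n, cohort.m) == (3, 4)
        assert cohort.chromosome_id == "chr9"
        assert cohort.loci == [1, 2, 3, 4]

    def test_snippet_values_land_in_the_right_matrix(self, tmp_path):
        # first observations: cancer 2.22 1.66 1.66 / blood 1.82 1.82 1.82
        lines = [
            ["observation", "group", "loc_1", "loc_2", "loc_3"],
            ["1", "cancer", "2.22", "1.66", "1.66"],
            ["2", "blood", "1.82", "1.82", "1.82"],
            ["3", "Cancer", "1.7", "1.7", "1.7"],
            ["4", "BLOOD", "1.88", "1.86", "1.86"],
        ]
        path = tmp_path / "chr1.tsv"
        write_lines(path, lines)
        cohort = read_cohort(path, INTERLEAVED)
        assert cohort.cancer_cn[0, 0] == 2.22
        assert cohort.blood_cn[0, 0] == 1.82
        assert cohort.cancer_cn[1, 0] == 1.7

    def test_odd_row_count_is_a_structure_error(self, tmp_path):
        lines = [
            ["observation", "group", "loc_1"],
            ["1", "cancer", "2.0"],
            ["2", "blood", "2.0"],
            ["3", "cancer", "2.0"],
        ]
        path = tmp_path / "odd.tsv"
        write_lines(path, lines)
        with pytest.raises(CohortStructureError, match="even number"):
            read_cohort(path, INTERLEAVED)

    def test_broken_alternation_is_rejected_not_reordered(self, tmp_path):
        lines = [
            ["observation", "group", "loc_1"],
            ["1", "blood", "2.0"],
            ["2", "cancer", "2.0"],
        ]
        path = tmp_path / "swapped.tsv"
        write_lines(path, lines)
        with pytest.raises(CohortStructureError, match="alternation"):
            read_cohort(path, INTERLEAVED)

    def test_malformed_cell_names_row_and_column(self, tmp_path):
        lines = [
            ["observation", "group", "loc_1", "loc_2"],
            ["1", "cancer", "2.0", "oops"],
            ["2", "blood", "2.0", "2.1"],
        ]
        path = tmp_path / "bad.tsv"
        write_lines(path, lines)
        with pytest.raises(CohortParseError, match="'oops'.*row 1.*loc_2"):
            read_cohort(path, INTERLEAVED)

    def test_comma_delimiter_is_sniffed(self, tmp_path):
        lines = [
            ["observation", "group", "loc_1"],
            ["1", "cancer", "2.5"],
            ["2", "blood", "1.5"],
        ]
        path = tmp_path / "c.csv"
        write_lines(path, lines, sep=",")
        cohort = read_cohort(path, INTERLEAVED)
        assert cohort.cancer_cn[0, 0] == 2.5


class TestRoundTrip:
    @pytest.mark.parametrize("layout", [INTERLEAVED, PAIRED_COLUMNS])
    def test_write_read_identity(self, tmp_path, layout):
        cohort = make_cohort(n=5, m=10, seed=3, chromosome_id="chr5")
        path = tmp_path / "chr5.tsv"
        write_cohort(cohort, path, layout)
        assert read_cohort(path, layout) == cohort

    def test_layout_conversion_preserves_values(self, tmp_path):
        cohort = make_cohort(n=4, m=6, seed=9, chromosome_id="chr2")
        write_cohort(cohort, tmp_path / "chr2.tsv", PAIRED_COLUMNS)
        back = read_cohort(tmp_path / "chr2.tsv", PAIRED_COLUMNS)
        write_cohort(back, tmp_path / "chr2b.tsv", INTERLEAVED)
        again = read_cohort(tmp_path / "chr2b.tsv", INTERLEAVED, chromosome_id="chr2")
        assert again == cohort

    def test_empty_cohort_is_rejected_on_write(self, tmp_path):
        empty = PairedCohort("chrE", default_patient_ids(2), [],
                             np.empty((2, 0)), np.empty((2, 0)))
        with pytest.raises(CohortStructureError):
            write_cohort(empty, tmp_path / "e.tsv", INTERLEAVED)


class TestInvariants:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(CohortStructureError):
            PairedCohort("c", default_patient_ids(2), [1, 2],
                         np.ones((2, 2)), np.ones((2, 3)))

    def test_non_increasing_loci_rejected(self):
        with pytest.raises(CohortStructureError, match="increasing"):
            PairedCohort("c", default_patient_ids(2), [2, 1],
                         np.ones((2, 2)), np.ones((2, 2)))

    def test_negative_cn_rejected(self):
        with pytest.raises(CohortParseError, match="negative"):
            PairedCohort("c", default_patient_ids(2), [1, 2],
                         np.array([[2.0, -0.1], [2.0, 2.0]]), np.ones((2, 2)))

    def test_out_of_range_values_warn_when_strict(self):
        cohort = make_cohort(n=3, m=2)
        cohort.cancer_cn[0, 0] = 5.0
        with pytest.warns(UserWarning, match="outside"):
            cohort.validate(strict_range=True)


class TestToUnlabeled:
    def test_interleaved_row_order_and_labels(self):
        cohort = make_cohort(n=3, m=4)
        u = to_unlabeled(cohort)
        assert u.values.shape == (6, 4)
        assert list(u.true_labels) == ["cancer", "blood"] * 3
        assert u.sample_ids[0] == "P1_cancer" and u.sample_ids[1] == "P1_blood"

    def test_regrouping_by_labels_inverts_exactly(self):
        cohort = make_cohort(n=4, m=7, seed=2)
        u = to_unlabeled(cohort)
        cancer = u.values[np.asarray(u.true_labels) == "cancer"]
        blood = u.values[np.asarray(u.true_labels) == "blood"]
        assert np.array_equal(cancer, cohort.cancer_cn)
        assert np.array_equal(blood, cohort.blood_cn)

    def test_study_scale_sample_count(self):
        cohort = make_cohort(n=63, m=12)
        u = to_unlabeled(cohort)
        assert u.n_samples == 126
        assert sum(lab == "cancer" for lab in u.true_labels) == 63
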