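"""Fold-decrease computation and tiered candidate selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import seroburden as sb
from seroburden.burden import FoldDecreaseMatrix
from seroburden.errors import ConfigurationError, DomainError, PairingError
from seroburden.io import CONCENTRATION, MeasurementMatrix, SampleSheet


def _fd(values, proteins=None, patients=None):
    proteins = proteins or [f"prot{i}" for i in range(len(values))]
    patients = patients or [f"P{j+1}" for j in range(len(values[0]))]
    return FoldDecreaseMatrix(values=pd.DataFrame(
        values, index=proteins, columns=patients))


class TestFoldDecrease:
    @pytest.mark.parametrize("pre,post,expected", [
        (42.0, 1.0, 42.0),
        (7.0, 7.0, 1.0),
        (2.0, 4.0, 0.5),
    ])
    def test_ratio(self, pre, post, expected):
        assert sb.fold_decrease(pre, post) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            sb.fold_decrease(0.0, 1.0)


class TestBuildFdMatrix:
    def test_reconstructs_published_grid_from_pre_equals_fd(self, pea_table):
        """pre = printed FD, post = 1 reproduces the printed grid."""
        fd_printed = pea_table.fd.values
        samples, rows = {}, []
        for patient in fd_printed.columns:
            samples[f"{patient}_pre"] = fd_printed[patient]
            samples[f"{patient}_post"] = pd.Series(1.0, index=fd_printed.index)
            rows.append((f"{patient}_pre", patient, "patient", "pre", 1))
            rows.append((f"{patient}_post", patient, "patient", "post", 1))
        m = MeasurementMatrix("t", CONCENTRATION, "pg/mL",
                              pd.DataFrame(samples))
        sheet = SampleSheet(rows=pd.DataFrame(
            rows, columns=["sample_id", "subject_id", "role", "timepoint",
                           "replicate_id"]))
        fd = sb.build_fd_matrix(m, sheet)
        pd.testing.assert_frame_equal(
            fd.values[fd_printed.columns], fd_printed, check_names=False)

    def test_pre_equals_post_gives_all_ones(self, small_matrix, small_sheet):
        vals = small_matrix.values.copy()
        for p in ("P1", "P2"):
            vals[f"{p}_post"] = vals[f"{p}_pre"]
        m = small_matrix.replace_values(vals)
        fd = sb.build_fd_matrix(m, small_sheet)
        assert (fd.values == 1.0).all().all()

    def test_replicates_averaged_before_ratio(self):
        rows = pd.DataFrame([
            ("P1_pre_r1", "P1", "patient", "pre", 1),
            ("P1_pre_r2", "P1", "patient", "pre", 2),
            ("P1_post_r1", "P1", "patient", "post", 1),
            ("P1_post_r2", "P1", "patient", "post", 2),
        ], columns=["sample_id", "subject_id", "role", "timepoint",
                    "replicate_id"])
        df = pd.DataFrame([[8.0, 12.0, 4.0, 6.0]], index=["p"],
                          columns=list(rows["sample_id"]))
        fd = sb.build_fd_matrix(
            MeasurementMatrix("t", CONCENTRATION, "pg/mL", df),
            SampleSheet(rows=rows))
        assert fd.values.at["p", "P1"] == pytest.approx(2.0)  # mean 10 / mean 5

    def test_missing_patient_samples_raise_pairing_error(
            self, small_matrix, small_sheet):
        m = small_matrix.subset(samples=["P1_pre", "P1_post", "C1_r1", "C1_r2"])
        with pytest.raises(PairingError, match="P2"):
            sb.build_fd_matrix(m, small_sheet)

    def test_lld_flags_propagate_per_cell(self, small_matrix, small_sheet):
        vals = small_matrix.values.copy()
        vals.at["PROT_A", "P1_post"] = 0.5  # below LLD 1.0
        m = small_matrix.replace_values(vals)
        clipped_m, clipped = sb.clip_to_lld(m)
        fd = sb.build_fd_matrix(clipped_m, small_sheet, clipped=clipped)
        assert fd.flags["lld_clipped_post"].at["PROT_A", "P1"]
        assert not fd.flags["lld_clipped_pre"].at["PROT_A", "P1"]

    def test_both_clipped_gives_fd_exactly_one(self, small_matrix, small_sheet):
        vals = small_matrix.values.copy()
        vals.at["PROT_A", "P1_pre"] = 0.2
        vals.at["PROT_A", "P1_post"] = 0.6
        m, clipped = sb.clip_to_lld(small_matrix.replace_values(vals))
        fd = sb.build_fd_matrix(m, small_sheet, clipped=clipped)
        assert fd.values.at["PROT_A", "P1"] == 1.0


class TestMedianFd:
    def test_published_ca125_row(self, pea_table):
        row = pea_table.fd.values.loc["Cancer antigen 125 (CA125)"]
        assert sb.median_fd(row) == 10.5

    @pytest.mark.parametrize("values,expected", [
        ([3.7], 3.7),
        ([1, 2, 3, 4], 2.5),
    ])
    def test_small_cases(self, values, expected):
        assert sb.median_fd(values) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            sb.median_fd([])


class TestSelectCandidates:
    def test_all_published_pea_rows_selected(self, pea_table):
        table = sb.select_candidates(pea_table.fd)
        assert table.n_selected() == 15

    def test_all_published_qka_rows_selected(self, qka_table):
        table = sb.select_candidates(qka_table.fd)
        assert table.n_selected() == 11

    def test_all_ones_matrix_selects_nothing(self):
        fd = _fd(np.ones((4, 9)))
        assert sb.select_candidates(fd).n_selected() == 0

    def test_min_patients_above_cohort_size_rejected(self, pea_table):
        cfg = sb.AnalysisConfig(min_patients=10)
        with pytest.raises(ConfigurationError):
            sb.select_candidates(pea_table.fd, cfg)

    @given(arrays(float, (6, 5), elements=st.floats(0.1, 30.0)),
           st.floats(1.5, 8.0), st.integers(1, 5))
    def test_matches_brute_force_scan(self, arr, threshold, min_patients):
        fd = _fd(arr.tolist())
        cfg = sb.AnalysisConfig(fd_threshold=threshold,
                                min_patients=min_patients)
        table = sb.select_candidates(fd, cfg)
        for i, protein in enumerate(fd.values.index):
            count = sum(1 for v in arr[i] if v >= threshold)
            assert table.frame.at[protein, "selected"] == \
                (count >= min_patients)

    @given(arrays(float, (6, 5), elements=st.floats(0.1, 30.0)))
    def test_double_monotonicity(self, arr):
        fd = _fd(arr.tolist())
        base = set(sb.select_candidates(
            fd, sb.AnalysisConfig(fd_threshold=2, min_patients=2)).selected)
        harder_t = set(sb.select_candidates(
            fd, sb.AnalysisConfig(fd_threshold=3, min_patients=2)).selected)
        harder_n = set(sb.select_candidates(
            fd, sb.AnalysisConfig(fd_threshold=2, min_patients=4)).selected)
        assert harder_t <= base and harder_n <= base

    def test_strict_vs_inclusive_differ_at_exact_threshold(self):
        fd = _fd([[2.0, 2.0, 2.0]])
        incl = sb.select_candidates(fd, sb.AnalysisConfig(min_patients=3))
        strict = sb.select_candidates(
            fd, sb.AnalysisConfig(min_patients=3, strict_threshold=True))
        assert incl.n_selected() == 1 and strict.n_selected() == 0

    def test_ordering_median_desc_count_desc_label_asc(self):
        fd = _fd([[4.0, 4.0, 1.0], [4.0, 1.0, 4.0], [8.0, 8.0, 8.0]],
                 proteins=["b", "a", "c"])
        table = sb.select_candidates(fd, sb.AnalysisConfig(min_patients=1))
        assert list(table.frame.index) == ["c", "a", "b"]


class TestTierCounts:
    def test_published_tier_counts(self, pea_table):
        assert sb.tier_counts(pea_table.fd, 5, 2) == 13
        assert sb.tier_counts(pea_table.fd, 10, 1) == 9

    def test_all_ones_matrix_has_no_tier_hits(self):
        fd = _fd(np.ones((3, 4)))
        assert sb.tier_counts(fd, 1.0001, 1) == 0

    @given(arrays(float, (5, 6), elements=st.floats(0.1, 40.0)))
    def test_tier_nesting_consistency(self, arr):
        fd = _fd(arr.tolist())
        for m in (1, 2, 3):
            assert sb.tier_counts(fd, 10, m) <= sb.tier_counts(fd, 5, m)


class TestPatientSignatures:
    def test_all_ones_matrix_gives_empty_signatures(self):
        sigs = sb.patient_signatures(_fd(np.ones((3, 4))))
        assert all(s == [] for s in sigs.values())

    def test_sorted_by_descending_fold_decrease(self, pea_table):
        sigs = sb.patient_signatures(pea_table.fd)
        p1 = sigs["P1"]
        fds = [pea_table.fd.values.at[p, "P1"] for p in p1]
        assert fds == sorted(fds, reverse=True)
        assert p1[0] == "Folate receptor 1 (FOLR1)"  # 20.4 tops P1

    @given(arrays(float, (5, 4), elements=st.floats(0.1, 30.0)),
           st.floats(1.5, 10.0))
    def test_sizes_equal_brute_force_column_counts(self, arr, threshold):
        fd = _fd(arr.tolist())
        sigs = sb.patient_signatures(fd, threshold)
        for j, patient in enumerate(fd.values.columns):
            assert len(sigs[patient]) == int((arr[:, j] >= threshold).sum())
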