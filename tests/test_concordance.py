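"""Pearson, Bland–Altman, and analyte matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

import seroburden as sb
from seroburden.burden import FoldDecreaseMatrix
from seroburden.concordance import MODE_PERCENT
from seroburden.errors import (
    AmbiguityError,
    DegenerateInputError,
    DomainError,
    SampleSizeError,
)

vectors = st.lists(st.floats(-100, 100), min_size=4, max_size=12)


def _brute_pearson(x, y):
    x, y = np.asarray(x), np.asarray(y)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))


class TestPearson:
    def test_published_ca125_cross_platform(self, pea_table, qka_table):
        x = pea_table.fd.values.loc["Cancer antigen 125 (CA125)"]
        y = qka_table.fd.values.loc["Cancer antigen 125 (CA125)"]
        r, p, n = sb.pearson(x, y)
        assert n == 9
        assert r == pytest.approx(0.785, abs=0.02)
        assert p == pytest.approx(0.0121, abs=0.005)

    def test_identity_gives_r_one(self):
        r, p, _ = sb.pearson([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(SampleSizeError):
            sb.pearson([1, 2], [3, 4])

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            sb.pearson([1, 1, 1], [1, 2, 3])

    @given(vectors, vectors)
    def test_matches_brute_force_covariance_formula(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        assume(np.std(x) > 1e-6 and np.std(y) > 1e-6)
        r, _, _ = sb.pearson(x, y)
        assert r == pytest.approx(_brute_pearson(x, y), abs=1e-9)

    @given(vectors, vectors, st.floats(0.1, 10), st.floats(-50, 50))
    def test_symmetry_and_affine_invariance(self, x, y, a, b):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        assume(np.std(x) > 1e-3 and np.std(y) > 1e-3)
        r, _, _ = sb.pearson(x, y)
        r_sym, _, _ = sb.pearson(y, x)
        r_aff, _, _ = sb.pearson([a * v + b for v in x], y)
        assert r == pytest.approx(r_sym, abs=1e-9)
        assert r == pytest.approx(r_aff, abs=1e-6)


class TestBlandAltman:
    def test_published_folr1_agreement(self, pea_table, qka_table):
        x = pea_table.fd.values.loc["Folate receptor 1 (FOLR1)"]
        y = qka_table.fd.values.loc["Folate receptor 1 (FOLR1)"]
        res = sb.bland_altman(x, y, ids=list(x.index))
        assert res.bias == pytest.approx(2.88, abs=0.02)
        assert res.loa_low == pytest.approx(-11.36, abs=0.02)
        assert res.loa_high == pytest.approx(17.12, abs=0.02)
        assert res.outlier_ids == []
        assert res.within_loa_fraction == 1.0

    def test_published_ca125_single_outlier(self, pea_table, qka_table):
        x = pea_table.fd.values.loc["Cancer antigen 125 (CA125)"]
        y = qka_table.fd.values.loc["Cancer antigen 125 (CA125)"]
        res = sb.bland_altman(x, y, ids=list(x.index))
        assert res.bias == pytest.approx(-4.21, abs=0.02)
        assert res.outlier_ids == ["P4"]

    def test_identical_vectors_give_degenerate_loa(self):
        res = sb.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0.0 and res.sd_diff == 0.0
        assert res.loa_low == 0.0 and res.loa_high == 0.0
        assert res.outlier_ids == []

    def test_percent_mode_uses_pair_mean_denominator(self):
        res = sb.bland_altman([3.0, 1.0, 4.0], [1.0, 1.0, 4.0],
                              mode=MODE_PERCENT)
        # first pair: 100 * 2 / 2 = 100%
        assert res.bias == pytest.approx(100.0 / 3.0)

    def test_percent_mode_zero_pair_mean_rejected(self):
        with pytest.raises(DomainError, match="zero pair mean"):
            sb.bland_altman([1.0, -1.0], [2.0, 1.0], mode=MODE_PERCENT)

    @given(vectors, vectors)
    def test_antisymmetry_and_loa_width(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        ab = sb.bland_altman(x, y)
        ba = sb.bland_altman(y, x)
        assert ab.bias == pytest.approx(-ba.bias, abs=1e-9)
        assert (ab.loa_high - ab.loa_low) == pytest.approx(
            2 * 1.96 * ab.sd_diff, abs=1e-9)

    @given(vectors, vectors)
    def test_outliers_match_brute_force(self, x, y):
        n = min(len(x), len(y))
        x, y = np.array(x[:n]), np.array(y[:n])
        res = sb.bland_altman(x, y)
        d = x - y
        brute = [i for i in range(n)
                 if d[i] < res.loa_low or d[i] > res.loa_high]
        assert res.outlier_ids == brute
        assert res.within_loa_fraction == pytest.approx(1 - len(brute) / n)

    def test_loa_boundary_is_inside(self):
        # differences (0, 0, 0, 2): mean 0.5, sample SD exactly 1, so with
        # z = 1.5 the largest difference sits exactly on the upper bound
        res = sb.bland_altman([0.0, 0.0, 0.0, 2.0], [0.0] * 4, z=1.5)
        assert res.loa_high == 2.0
        assert res.outlier_ids == []
        assert res.within_loa_fraction == 1.0


class TestMatchTargets:
    def test_parenthetical_synonym_matches_bare_symbol(self):
        m = sb.match_targets(["KLK11"], ["Kallikrein 11 (KLK11)"])
        assert len(m.pairs) == 1
        assert m.pairs[0][:2] == ("KLK11", "Kallikrein 11 (KLK11)")

    def test_identical_lists_fully_matched(self):
        labels = ["CA125", "HE4", "FOLR1"]
        m = sb.match_targets(labels, list(labels))
        assert len(m.pairs) == 3 and not m.unmatched_a and not m.unmatched_b

    def test_disjoint_lists_unmatched(self):
        m = sb.match_targets(["CA125"], ["HE4"])
        assert m.pairs == []
        assert m.unmatched_a == ["CA125"] and m.unmatched_b == ["HE4"]

    def test_published_tables_share_three_rows(self, pea_table, qka_table):
        m = sb.match_targets(pea_table.proteins, qka_table.proteins)
        keys = sorted(k for _, _, k in m.pairs)
        assert keys == ["CA125", "FOLR1", "KLK11"]

    def test_alias_map_consulted(self):
        m = sb.match_targets(["MUC16"], ["Cancer antigen 125 (CA125)"],
                             aliases={"MUC16": "CA125"})
        assert len(m.pairs) == 1

    def test_duplicate_key_on_one_side_is_ambiguous(self):
        with pytest.raises(AmbiguityError):
            sb.match_targets(["CA125"], ["CA125", "ca 125"])


class TestOverlapConcordance:
    def test_identical_platforms_agree_perfectly(self, pea_table):
        fd = pea_table.fd
        matches = sb.match_targets(fd.proteins, fd.proteins)
        res = sb.overlap_concordance(fd, fd, matches)
        assert res.r == pytest.approx(1.0)
        assert res.bias == pytest.approx(0.0)
        assert res.mode == MODE_PERCENT
        assert res.n == 15 * 9

    def test_shared_truth_with_noise_correlates_positively(self):
        rng = np.random.default_rng(7)
        n_sig = 0
        n_rep = 60
        for _ in range(n_rep):
            truth = rng.lognormal(0.5, 0.8, (20, 9))
            a = truth * rng.lognormal(0, 0.1, truth.shape)
            b = truth * rng.lognormal(0, 0.1, truth.shape)
            proteins = [f"p{i}" for i in range(20)]
            patients = [f"P{j}" for j in range(9)]
            fa = FoldDecreaseMatrix(values=pd.DataFrame(
                a, index=proteins, columns=patients))
            fb = FoldDecreaseMatrix(values=pd.DataFrame(
                b, index=proteins, columns=patients))
            matches = sb.match_targets(proteins, proteins)
            res = sb.overlap_concordance(fa, fb, matches)
            if res.r > 0 and res.p_two_sided < 0.05:
                n_sig += 1
        assert n_sig >= 0.9 * n_rep

    def test_too_few_matched_pairs_rejected(self):
        fa = FoldDecreaseMatrix(values=pd.DataFrame(
            [[2.0]], index=["A"], columns=["P1"]))
        matches = sb.match_targets(["A"], ["A"])
        with pytest.raises(SampleSizeError):
            sb.overlap_concordance(fa, fa, matches)
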