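import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from episcan.annotation import (ALA_X_ALA_AREA, BackgroundFreqs,
                                build_wop_fallback_table, conservation_score,
                                exposure_call, normalize_rsa, wop_fallback)
from episcan.io_formats import AA_ALPHABET, WopMatrix

UNIFORM = BackgroundFreqs.uniform()


class TestBackground:
    def test_robinson_robinson_is_valid_distribution(self):
        bg = BackgroundFreqs.robinson_robinson()
        assert bg.p.sum() == pytest.approx(1.0, abs=1e-9)
        assert (bg.p > 0).all()

    def test_rejects_incomplete_table(self):
        with pytest.raises(ValueError, match="missing"):
            BackgroundFreqs.from_mapping({"A": 1.0})

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError, match="sum"):
            BackgroundFreqs(np.full(20, 0.06))


class TestConservation:
    def test_profile_equal_to_background_scores_zero(self):
        bg = BackgroundFreqs.robinson_robinson()
        row = bg.p * 100.0
        assert conservation_score(row, bg) == pytest.approx(0.0, abs=1e-12)

    def test_single_mass_uniform_background(self):
        row = np.zeros(20)
        row[4] = 100.0
        # 1 * log2(1 / 0.05) = log2(20)
        assert conservation_score(row, UNIFORM) == pytest.approx(
            np.log2(20), abs=1e-12)

    def test_two_mass_uniform_background(self):
        row = np.zeros(20)
        row[0] = row[7] = 50.0
        # 2 * 0.5 * log2(0.5/0.05) = log2(10)
        assert conservation_score(row, UNIFORM) == pytest.approx(
            np.log2(10), abs=1e-12)

    def test_negative_entry_rejected(self):
        row = np.zeros(20)
        row[0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            conservation_score(row, UNIFORM)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0.0, 100.0), min_size=20, max_size=20),
           st.permutations(list(range(20))))
    def test_invariant_under_joint_permutation(self, row, perm):
        bg = BackgroundFreqs.robinson_robinson()
        row = np.array(row)
        perm = np.array(perm)
        direct = conservation_score(row, bg)
        permuted = conservation_score(row[perm], BackgroundFreqs(bg.p[perm]))
        assert permuted == pytest.approx(direct, rel=1e-9, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0.001, 1.0), min_size=20, max_size=20))
    def test_proper_distribution_gives_nonnegative_kl(self, raw):
        p = np.array(raw)
        p = p / p.sum()
        assert conservation_score(p * 100.0, UNIFORM) >= -1e-9


class TestWopFallback:
    def test_identity_without_zero_rows(self):
        m = WopMatrix(np.full((3, 20), 5.0))
        table = {aa: np.full(20, 1.0) for aa in AA_ALPHABET}
        out = wop_fallback(m, "ACD", table)
        np.testing.assert_array_equal(out.values, m.values)

    def test_zero_row_replaced_by_type_vector(self):
        vals = np.full((3, 20), 5.0)
        vals[1] = 0.0
        table = {aa: np.full(20, float(i + 1))
                 for i, aa in enumerate(AA_ALPHABET)}
        out = wop_fallback(WopMatrix(vals), "CAC", table)
        np.testing.assert_array_equal(out.values[1], table["A"])
        np.testing.assert_array_equal(out.values[0], vals[0])
        assert not out.zero_rows.any()

    def test_missing_type_raises(self):
        vals = np.zeros((1, 20))
        with pytest.raises(KeyError):
            wop_fallback(WopMatrix(vals), "W", {"A": np.ones(20)})

    def test_table_is_per_type_mean_of_nonzero_rows(self):
        # toy 2-chain training set, verified against a hand-summed average
        m1 = np.zeros((3, 20))
        m1[0, 0] = 10.0   # A row
        m1[1, 1] = 20.0   # A row
        m1[2] = 0.0       # A row, all-zero: excluded
        m2 = np.zeros((2, 20))
        m2[0, 2] = 30.0   # A row
        m2[1, 3] = 40.0   # C row
        table = build_wop_fallback_table(
            [WopMatrix(m1), WopMatrix(m2)], ["AAA", "AC"])
        expected_a = (m1[0] + m1[1] + m2[0]) / 3.0
        np.testing.assert_allclose(table["A"], expected_a)
        np.testing.assert_allclose(table["C"], m2[1])
        # residue types never observed fall back to the uniform vector
        np.testing.assert_allclose(table["W"], np.full(20, 5.0))


class TestRsa:
    def test_self_normalization(self):
        assert normalize_rsa(ALA_X_ALA_AREA["W"], "W") == 1.0

    def test_zero(self):
        assert normalize_rsa(0.0, "A") == 0.0

    def test_clipping(self):
        assert normalize_rsa(ALA_X_ALA_AREA["G"] * 2, "G") == 1.0

    def test_unknown_residue(self):
        with pytest.raises(KeyError):
            normalize_rsa(10.0, "X")

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.floats(0, 400), st.floats(0, 400),
           st.sampled_from(AA_ALPHABET))
    def test_monotone_in_asa(self, a, b, res):
        lo, hi = sorted((a, b))
        assert normalize_rsa(lo, res) <= normalize_rsa(hi, res)

    @pytest.mark.parametrize("rsa,exposed", [
        (0.10, False),   # buried below the 25% threshold
        (0.25, True),    # boundary is exposed ("otherwise" branch)
        (0.99, True),
    ])
    def test_exposure_threshold(self, rsa, exposed):
        assert exposure_call(rsa) is exposed

    def test_exposure_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            exposure_call(1.2)
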