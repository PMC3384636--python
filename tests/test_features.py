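import hashlib

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_fragment, random_fragment
from episcan.features import (FEATURE_GROUPS, FEATURE_NAMES, N_FEATURES,
                              class_content_entropy, dipeptide_scores,
                              extract_features, group_cardinalities,
                              per_residue_raap, raap_stats, segment_counts,
                              sliding_means, sliding_stat)
from episcan.io_formats import DipeptideScale
from episcan.similarity import FragmentLibrary, fragment_similarity

AAS = "ACDEFGHIKLMNPQRSTVWY"


def constant_scale(v=0.5):
    return DipeptideScale({a + b: v for a in AAS for b in AAS},
                          normalized=True)


@pytest.fixture(scope="module")
def library(toy_scale):
    rng = np.random.default_rng(5)
    peps = ["".join(rng.choice(list(AAS), 20)) for _ in range(10)]
    return FragmentLibrary(peps[:5], peps[5:])


class TestSegments:
    def test_worked_example(self):
        # the canonical mixed H/E/C string: 2 helix, 4 coil, 2 strand runs
        c = segment_counts("HHHCEEEEEEEECCCHHHCCCECC")
        assert (c["H"], c["C"], c["E"]) == (2, 4, 2)
        assert c["total"] == 8

    def test_single_run(self):
        c = segment_counts("H" * 20)
        assert (c["H"], c["E"], c["C"], c["total"]) == (1, 0, 0, 1)

    def test_maximal_alternation(self):
        c = segment_counts("HE" * 10)
        assert (c["H"], c["E"], c["total"]) == (10, 10, 20)

    def test_illegal_label(self):
        with pytest.raises(ValueError):
            segment_counts("HXC")

    @settings(deadline=None, derandomize=True, max_examples=80)
    @given(st.text(alphabet="HEC", min_size=1, max_size=30))
    def test_totals_and_bounds(self, ss):
        c = segment_counts(ss)
        assert c["total"] == c["H"] + c["E"] + c["C"]
        assert 1 <= c["total"] <= len(ss)


class TestContentEntropy:
    def test_degenerate(self):
        contents, ent = class_content_entropy("H" * 20, "HEC")
        assert contents["H"] == 1.0 and ent == 0.0

    def test_two_even_classes(self):
        _, ent = class_content_entropy("H" * 10 + "C" * 10, "HEC")
        assert ent == pytest.approx(np.log(0.5), abs=1e-12)  # ~ -0.6931

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.text(alphabet="HEC", min_size=1, max_size=40))
    def test_contents_sum_to_one_entropy_nonpositive(self, ss):
        contents, ent = class_content_entropy(ss, "HEC")
        assert sum(contents.values()) == pytest.approx(1.0)
        assert ent <= 0.0


class TestSlidingStat:
    def test_constant(self):
        v = np.full(20, 0.5)
        for n in (1, 5, 20):
            assert sliding_stat(v, n, "max") == 0.5
            assert sliding_stat(v, n, "min") == 0.5

    def test_arithmetic_sequence(self):
        v = np.arange(1, 21, dtype=float)
        assert sliding_stat(v, 5, "max") == 18.0  # mean of 16..20
        assert sliding_stat(v, 5, "min") == 3.0   # mean of 1..5

    def test_full_window_equals_mean(self, rng):
        v = rng.random(20)
        assert sliding_stat(v, 20, "max") == pytest.approx(v.mean())
        assert sliding_stat(v, 20, "min") == pytest.approx(v.mean())

    def test_window_too_long(self):
        with pytest.raises(ValueError):
            sliding_stat(np.ones(5), 6, "max")

    def test_matches_window_enumeration(self, rng):
        v = rng.random(20)
        for n in (1, 3, 7, 19):
            expected = [v[i:i + n].mean() for i in range(len(v) - n + 1)]
            np.testing.assert_allclose(sliding_means(v, n), expected)


class TestRaapStats:
    def test_constant_scale(self):
        frag = make_fragment()
        stats = raap_stats(frag, constant_scale(0.3))
        assert stats["avg_RAAP"] == pytest.approx(0.3)
        assert stats["sd_RAAP"] == pytest.approx(0.0)
        for n in range(5, 19):
            assert stats[f"max_RAAP_slide_{n}"] == pytest.approx(0.3)
            assert stats[f"min_RAAP_slide_{n}"] == pytest.approx(0.3)

    def test_average_of_19_pair_scores(self, toy_scale):
        frag = make_fragment(peptide=AAS)
        dipep = [toy_scale.values[AAS[i:i + 2]] for i in range(19)]
        stats = raap_stats(frag, toy_scale)
        assert stats["avg_RAAP"] == pytest.approx(np.mean(dipep))
        assert stats["sd_RAAP"] == pytest.approx(np.std(dipep))

    def test_affine_shift_of_scale(self, rng):
        vals = {a + b: rng.uniform(-0.4, 0.4) for a in AAS for b in AAS}
        base = DipeptideScale(vals, normalized=True)
        shifted = DipeptideScale({k: v + 0.2 for k, v in vals.items()},
                                 normalized=True)
        frag = make_fragment(peptide="".join(rng.choice(list(AAS), 20)))
        s0, s1 = raap_stats(frag, base), raap_stats(frag, shifted)
        assert s1["avg_RAAP"] == pytest.approx(s0["avg_RAAP"] + 0.2)
        assert s1["sd_RAAP"] == pytest.approx(s0["sd_RAAP"])

    def test_missing_dipeptide_strict(self):
        scale = DipeptideScale({"AC": 0.1}, normalized=True)
        frag = make_fragment()
        with pytest.raises(Exception, match="missing"):
            raap_stats(frag, scale)

    def test_per_residue_track(self):
        dipep = np.array([1.0, 3.0, 5.0])
        np.testing.assert_allclose(per_residue_raap(dipep),
                                   [1.0, 2.0, 4.0, 5.0])


class TestVectorStructure:
    def test_length_and_group_cardinalities(self):
        assert N_FEATURES == 198
        assert group_cardinalities() == {
            "SS": 8, "RA": 33, "RP": 30, "CS": 29, "SS+RA": 12, "SS+CS": 6,
            "SS+RP": 6, "RP+RA": 30, "RP+CS": 28, "SS+RA+RP": 6, "SIM": 10}

    def test_names_unique_and_stable(self):
        assert len(set(FEATURE_NAMES)) == 198
        digest = hashlib.sha256(
            "\n".join(FEATURE_NAMES).encode()).hexdigest()[:16]
        # frozen canonical order: selection manifests refer to these names
        assert digest == _FROZEN_NAME_DIGEST

    def test_determinism(self, toy_scale, library, rng):
        frag = random_fragment(rng)
        v1 = extract_features(frag, library, toy_scale)
        v2 = extract_features(frag, library, toy_scale)
        np.testing.assert_array_equal(v1.values, v2.values)

    def test_manifest_subsetting(self, toy_scale, library, rng):
        frag = random_fragment(rng)
        full = extract_features(frag, library, toy_scale)
        manifest = ["avg_RAAP", "content_H", "max_similarity_epitope_1"]
        sub = extract_features(frag, library, toy_scale, manifest=manifest)
        assert list(sub.names) == manifest
        d = full.as_dict()
        np.testing.assert_array_equal(sub.values,
                                      [d[n] for n in manifest])


_FROZEN_NAME_DIGEST = "6a9d81e5cd503fc1"


class TestCombinedGroups:
    def test_empty_class_convention(self, toy_scale, library):
        frag = make_fragment(ss="H" * 20)  # no strand residues anywhere
        d = extract_features(frag, library, toy_scale).as_dict()
        for name in ("RSA_E", "CON_E", "RAAP_E", "RSA_max_segment_E",
                     "CON_max_segment_E", "RAAP_max_segment_E",
                     "Num_E_Bd", "Num_E_Ed", "RAAP_E_Bd", "RAAP_E_Ed"):
            assert d[name] == 0.0, name

    def test_constant_channels_propagate(self, library):
        frag = make_fragment(rsa=np.full(20, 0.7))
        d = extract_features(frag, library, constant_scale(0.4)).as_dict()
        for n in range(5, 19):
            assert d[f"avg_RAAP_max_RSA_slide_{n}"] == pytest.approx(0.4)
            assert d[f"avg_RAAP_min_RSA_slide_{n}"] == pytest.approx(0.4)

    def test_longest_helix_run_mean(self, toy_scale, library, rng):
        rsa = rng.random(20)
        ss = "C" * 3 + "H" * 5 + "C" * 4 + "H" * 2 + "C" * 6
        frag = make_fragment(ss=ss, rsa=rsa, conservation=rng.random(20))
        d = extract_features(frag, library, toy_scale).as_dict()
        assert d["RSA_max_segment_H"] == pytest.approx(rsa[3:8].mean())
        assert d["CON_max_segment_H"] == pytest.approx(
            frag.conservation[3:8].mean())

    def test_leftmost_tie_break_for_longest_segment(self, toy_scale,
                                                    library, rng):
        rsa = rng.random(20)
        ss = "H" * 5 + "C" * 5 + "H" * 5 + "C" * 5  # two 5-long H runs
        frag = make_fragment(ss=ss, rsa=rsa)
        d = extract_features(frag, library, toy_scale).as_dict()
        assert d["RSA_max_segment_H"] == pytest.approx(rsa[:5].mean())


def _reference_values(frag, library, toy_scale):
    """Straight-line recomputation of one feature per group."""
    ss = np.array(list(frag.ss))
    exposed = frag.exposure
    dipep = np.array([toy_scale.values[frag.peptide[i:i + 2]]
                      for i in range(19)])
    res_raap = np.array(
        [dipep[max(i - 1, 0):i + 1].mean() if 0 < i < 19
         else (dipep[0] if i == 0 else dipep[18]) for i in range(20)])
    out = {}
    out["content_H"] = (ss == "H").sum() / 20
    runs = []
    for i, c in enumerate(frag.ss):
        if i == 0 or frag.ss[i - 1] != c:
            runs.append([c, i, 0])
        runs[-1][2] += 1
    out["NumSeg_C"] = sum(1 for r in runs if r[0] == "C")
    out["entropy_RSA"] = sum(
        p * np.log(p) for p in
        [exposed.mean(), 1 - exposed.mean()] if p > 0)
    out["RSA_Bd"] = (frag.rsa[~exposed].mean() if (~exposed).any() else 0.0)
    wins7 = [frag.rsa[i:i + 7].mean() for i in range(14)]
    out["max_RSA_slide_7"] = max(wins7)
    out["avg_RAAP"] = dipep.mean()
    cons9 = [frag.conservation[i:i + 9].mean() for i in range(12)]
    out["min_CON_slide_9"] = min(cons9)
    out["Num_H_Ed"] = int(((ss == "H") & exposed).sum())
    mask_e = ss == "E"
    out["RSA_E"] = frag.rsa[mask_e].mean() if mask_e.any() else 0.0
    out["CON_C"] = (frag.conservation[ss == "C"].mean()
                    if (ss == "C").any() else 0.0)
    mask_h = ss == "H"
    out["RAAP_H"] = res_raap[mask_h].mean() if mask_h.any() else 0.0
    out["RAAP_Ed"] = res_raap[exposed].mean() if exposed.any() else 0.0
    w = np.argmax([frag.rsa[i:i + 6].mean() for i in range(15)])
    out["avg_RAAP_max_RSA_slide_6"] = dipep[w:w + 5].mean()
    w = np.argmin([frag.conservation[i:i + 11].mean() for i in range(10)])
    out["avg_RAAP_min_CON_slide_11"] = dipep[w:w + 10].mean()
    mask_cb = (ss == "C") & ~exposed
    out["RAAP_C_Bd"] = res_raap[mask_cb].mean() if mask_cb.any() else 0.0
    out["max_similarity_epitope_1"] = max(
        fragment_similarity(frag.peptide, p) for p in library.epitopes)
    out["max_similarity_non-epitope_2"] = sorted(
        (fragment_similarity(frag.peptide, p)
         for p in library.non_epitopes), reverse=True)[1]
    return out


class TestAgainstReference:
    def test_fifty_random_fragments(self, toy_scale, library, rng):
        for _ in range(50):
            frag = random_fragment(rng)
            d = extract_features(frag, library, toy_scale).as_dict()
            for name, ref in _reference_values(frag, library,
                                               toy_scale).items():
                assert d[name] == pytest.approx(ref, abs=1e-10), name

    def test_sliding_extrema_bracket_window_means(self, toy_scale,
                                                  library, rng):
        # every size-n window mean lies between the reported extrema
        # (the full-channel mean itself need not: terminal residues fall in
        # fewer windows, so overlapping-window means under-weight them)
        for _ in range(10):
            frag = random_fragment(rng)
            d = extract_features(frag, library, toy_scale).as_dict()
            for chan, values in (("RSA", frag.rsa),
                                 ("CON", frag.conservation)):
                for n in range(5, 19):
                    means = sliding_means(values, n)
                    assert d[f"min_{chan}_slide_{n}"] == pytest.approx(
                        means.min())
                    assert d[f"max_{chan}_slide_{n}"] == pytest.approx(
                        means.max())
                    assert (d[f"min_{chan}_slide_{n}"] - 1e-12
                            <= means.mean()
                            <= d[f"max_{chan}_slide_{n}"] + 1e-12)

    def test_content_sums(self, toy_scale, library, rng):
        for _ in range(10):
            d = extract_features(random_fragment(rng), library,
                                 toy_scale).as_dict()
            assert (d["content_H"] + d["content_E"] + d["content_C"]
                    == pytest.approx(1.0))
            assert d["content_Bd"] + d["content_Ed"] == pytest.approx(1.0)
            assert d["NumSeg_SS"] == (d["NumSeg_H"] + d["NumSeg_E"]
                                      + d["NumSeg_C"])
            assert 1 <= d["NumSeg_SS"] <= 20
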