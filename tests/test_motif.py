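"""PWM machinery and the iterative motif search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosmap.alphabet import AA_INDEX, AMINO_ACIDS
from phosmap.motif import (M3Config, M3MotifFinder, PWMMatrix,
                           Phosphopeptide, consensus_string,
                           extract_foreground_background, frequency_matrix,
                           m3, match_score, match_scores, random_cutoff,
                           site_window)
from phosmap.simulate import (planted_pwm, random_class_windows,
                              sample_windows_from_pwm)
from phosmap.types import KSREdge, Phosphosite, ProteinRecord


def _uniform_bg(width=15):
    v = np.zeros((21, width))
    v[:20] = 1.0 / 20
    return PWMMatrix(v)


class TestSiteWindow:
    def test_terminal_padding_and_center(self):
        w = site_window("MKSA", 3, 15)
        assert w == "-----MKSA------"
        assert len(w) == 15 and w[7] == "S"

    def test_interior_site_unpadded(self):
        seq = "A" * 7 + "S" + "C" * 7
        assert site_window(seq, 8, 15) == seq

    def test_position_out_of_range(self):
        with pytest.raises(ValueError):
            site_window("MKS", 4, 15)


class TestFrequencyMatrix:
    def test_single_peptide_zero_pseudocount_is_one_hot(self):
        pwm = frequency_matrix(["ACD"], pseudocount=0.0)
        assert pwm.values[AA_INDEX["A"], 0] == 1.0
        assert pwm.values[AA_INDEX["C"], 1] == 1.0
        assert pwm.values.sum() == pytest.approx(3.0)

    def test_duplication_invariance_without_pseudocount(self):
        # with a pseudocount the duplicate sharpens the matrix (the
        # pseudocount's relative weight shrinks); invariance holds at 0
        one = frequency_matrix(["ACD"], 0.0)
        two = frequency_matrix(["ACD", "ACD"], 0.0)
        np.testing.assert_allclose(one.values, two.values, atol=1e-12)

    def test_hand_computed_entries(self):
        peps = ["ACD", "ACD", "AYD", "CCD"]
        pwm = frequency_matrix(peps, pseudocount=0.5)
        denom = 4 + 21 * 0.5
        assert pwm.values[AA_INDEX["A"], 0] == pytest.approx(3.5 / denom)
        assert pwm.values[AA_INDEX["C"], 0] == pytest.approx(1.5 / denom)
        assert pwm.values[AA_INDEX["Y"], 1] == pytest.approx(1.5 / denom)
        assert pwm.values[AA_INDEX["D"], 2] == pytest.approx(4.5 / denom)
        assert pwm.values.sum(axis=0) == pytest.approx(np.ones(3))

    def test_mixed_widths_rejected(self):
        with pytest.raises(ValueError, match="width"):
            frequency_matrix(["ACD", "AC"])


class TestMatchScore:
    def test_fg_equals_bg_scores_zero(self, rng):
        wins = random_class_windows(20, "ST", rng)
        pwm = frequency_matrix(wins, 0.5)
        assert match_scores(wins, pwm, pwm) == pytest.approx(np.zeros(20))

    def test_one_hot_vs_uniform_closed_form(self):
        win = "ARNDCQEGHSILKMFPT"[:15]
        win = win[:7] + "S" + win[8:]
        fg = frequency_matrix([win], pseudocount=0.0)
        assert match_score(win, fg, _uniform_bg()) == pytest.approx(
            15 * np.log2(20))

    def test_matches_positionwise_sum_oracle(self, rng):
        fg = frequency_matrix(random_class_windows(12, "ST", rng), 0.5)
        bg = frequency_matrix(random_class_windows(30, "ST", rng), 0.5)
        win = random_class_windows(1, "ST", rng)[0]
        oracle = sum(
            np.log2(fg.values[AA_INDEX[c], j] / bg.values[AA_INDEX[c], j])
            for j, c in enumerate(win))
        assert match_score(win, fg, bg) == pytest.approx(oracle)

    def test_zero_background_probability_rejected(self):
        fg = frequency_matrix(["AAA"], pseudocount=0.5)
        bg = frequency_matrix(["CCC"], pseudocount=0.0)
        with pytest.raises(ValueError, match="background"):
            match_score("AAA", fg, bg)


class TestRandomCutoff:
    def test_fg_equals_bg_gives_zero(self, rng):
        wins = random_class_windows(50, "ST", rng)
        pwm = frequency_matrix(wins, 0.5)
        cut = random_cutoff(wins, pwm, pwm, M3Config())
        assert cut == 0.0

    def test_monotone_in_percentile(self, rng):
        bg_wins = random_class_windows(100, "ST", rng)
        fg = frequency_matrix(random_class_windows(10, "ST", rng), 0.5)
        bg = frequency_matrix(bg_wins, 0.5)
        cuts = [random_cutoff(bg_wins, fg, bg,
                              M3Config(cutoff_percentile=q, rng_seed=5))
                for q in (0.5, 0.9, 0.99)]
        assert cuts == sorted(cuts)

    def test_seed_reproducibility(self, rng):
        bg_wins = random_class_windows(100, "ST", rng)
        fg = frequency_matrix(random_class_windows(10, "ST", rng), 0.5)
        bg = frequency_matrix(bg_wins, 0.5)
        a = random_cutoff(bg_wins, fg, bg, M3Config(rng_seed=3))
        b = random_cutoff(bg_wins, fg, bg, M3Config(rng_seed=3))
        assert a == b


class TestConsensus:
    def test_band_rules(self):
        width = 3
        v = np.zeros((21, width))
        v[AA_INDEX["R"], 0] = 1.0                       # one-hot -> 'R'
        v[:20, 1] = 1.0 / 20                            # uniform -> 'x'
        v[AA_INDEX["S"], 1] = 1.0 / 20                  # center col
        v[:, 1] /= v[:, 1].sum()
        v[AA_INDEX["L"], 2] = 0.3                       # 0.3 -> lowercase
        others = [i for i in range(20) if i != AA_INDEX["L"]]
        v[others, 2] = 0.7 / len(others)
        pwm = PWMMatrix(v)
        s = consensus_string(pwm, "ST")
        assert s[0] == "R" and s[2] == "l"
        assert s[1] in "st"  # center rendered as class letter

    def test_uniform_noncenter_is_x(self):
        pwm = _uniform_bg(3)
        assert consensus_string(pwm, "Y") == "xyx"


class TestExtract:
    def test_enumeration_and_padding(self):
        proteome = {f"P{i}": ProteinRecord(f"P{i}", "A" * 7 + "S" + "A" * 3
                                           + "T" + "A" * 8)
                    for i in range(3)}
        edges = [KSREdge("K1", f"P{i}", "raw") for i in range(3)]
        sites = [Phosphosite(f"P{i}", 8, "S") for i in range(3)]
        sites += [Phosphosite(f"P{i}", 12, "T") for i in range(3)]
        fg, bg = extract_foreground_background(edges, sites, proteome)
        assert len(fg[("K1", "ST")]) == 6
        assert len(bg["ST"]) == 6
        for pep in fg[("K1", "ST")]:
            assert pep.window[7] == pep.residue

    def test_dual_specificity_split(self):
        seq = "A" * 7 + "S" + "A" * 7 + "Y" + "A" * 7
        proteome = {"P0": ProteinRecord("P0", seq)}
        edges = [KSREdge("KD", "P0", "raw")]
        sites = [Phosphosite("P0", 8, "S"), Phosphosite("P0", 16, "Y")]
        fg, bg = extract_foreground_background(edges, sites, proteome)
        assert set(fg) == {("KD", "ST"), ("KD", "Y")}
        assert len(bg["Y"]) == 1


class TestM3:
    def _bg(self, rng, n=300):
        return random_class_windows(n, "ST", rng)

    def test_hand_traceable_run(self, rng):
        # unrelated windows use common letters (L, E) so their pseudocount
        # probability under the seed PWM stays below background frequency
        core = "AAAAAAASAAAAAAA"
        fg = [core] * 10 + ["LLLLLLLSLLLLLLL", "EEEEEEESEEEEEEE"]
        motif = m3(fg, self._bg(rng), substrate_count=12,
                   config=M3Config(rng_seed=0))
        assert sorted(motif.seed_peptides) == [core] * 10
        denom = 10 + 21 * 0.5
        assert motif.pwm.values[AA_INDEX["A"], 0] == pytest.approx(
            10.5 / denom)
        assert motif.consensus[7] == "s"

    def test_substrate_count_cap(self, rng):
        fg = random_class_windows(40, "ST", rng)
        motif = m3(fg, self._bg(rng), substrate_count=10,
                   config=M3Config(rng_seed=0))
        assert len(motif.seed_peptides) == 10

    def test_small_foreground_skips_iteration(self, rng):
        fg = random_class_windows(4, "ST", rng)
        with pytest.warns(UserWarning, match="smaller than seed_size"):
            motif = m3(fg, self._bg(rng), substrate_count=50,
                       config=M3Config(rng_seed=0))
        assert sorted(motif.seed_peptides) == sorted(fg)

    def test_degenerate_fg_equals_bg_stops_at_seed_size(self):
        wins = ["AAAAAAASAAAAAAA"] * 30
        motif = m3(wins, wins, substrate_count=30,
                   config=M3Config(rng_seed=0))
        assert len(motif.seed_peptides) == M3Config().seed_size

    def test_deterministic_for_fixed_seed(self, rng):
        pwm = planted_pwm("S", 0.9, 15, rng)
        fg = sample_windows_from_pwm(pwm, 25, rng) \
            + random_class_windows(25, "ST", rng)
        bg = self._bg(rng)
        a = m3(fg, bg, 100, M3Config(rng_seed=7))
        b = m3(fg, bg, 100, M3Config(rng_seed=7))
        assert a.seed_peptides == b.seed_peptides
        np.testing.assert_array_equal(a.pwm.values, b.pwm.values)
        assert a.final_cutoff == b.final_cutoff

    def test_seeds_are_foreground_members(self, rng):
        fg = random_class_windows(30, "ST", rng)
        motif = m3(fg, self._bg(rng), 100, M3Config(rng_seed=0))
        fg_multiset = sorted(fg)
        for s in motif.seed_peptides:
            assert s in fg_multiset
        assert len(motif.seed_peptides) <= min(len(fg), 100)

    def test_planted_motif_recovered(self, rng):
        from phosmap.compare import pwm_similarity
        pwm = planted_pwm("S", 0.9, 15, rng)
        fg = sample_windows_from_pwm(pwm, 40, rng) \
            + random_class_windows(60, "ST", rng)
        motif = m3(fg, self._bg(rng, 400), 100, M3Config(rng_seed=0))
        assert pwm_similarity(motif.pwm, pwm) >= 0.9

    def test_empty_foreground_rejected(self, rng):
        with pytest.raises(ValueError, match="empty foreground"):
            m3([], self._bg(rng), 10, M3Config())

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_duplicating_a_seed_never_lowers_its_letter_probs(self, seed):
        r = np.random.default_rng(seed)
        wins = random_class_windows(8, "ST", r)
        before = frequency_matrix(wins, 0.5)
        after = frequency_matrix(wins + [wins[0]], 0.5)
        for j, c in enumerate(wins[0]):
            assert after.values[AA_INDEX[c], j] >= \
                before.values[AA_INDEX[c], j] - 1e-12


class TestM3Estimator:
    def test_fit_transform_predict(self, rng):
        pwm = planted_pwm("S", 0.95, 15, rng)
        fg = sample_windows_from_pwm(pwm, 30, rng)
        bg = random_class_windows(300, "ST", rng)
        est = M3MotifFinder(random_state=0).fit(fg, bg, substrate_count=100)
        assert est.consensus_[7] == "s"
        planted_scores = est.transform(sample_windows_from_pwm(pwm, 10, rng))
        noise_scores = est.transform(random_class_windows(10, "ST", rng))
        assert planted_scores.mean() > noise_scores.mean()
        assert est.predict(sample_windows_from_pwm(pwm, 10, rng)).mean() \
            >= 0.8

    def test_sklearn_params(self):
        from sklearn.base import clone
        est = M3MotifFinder(seed_size=5, n_random=500)
        assert clone(est).get_params()["seed_size"] == 5
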