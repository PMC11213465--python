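"""PWM construction, log-odds scanning, exact null p-values, conservation."""

import itertools

import numpy as np
import pytest

from riboseek.motifs import (
    PWM,
    build_pwm,
    conserved_window_detect,
    cross_species_site_pairs,
    read_pwm,
    reverse_complement,
    scan_sequence,
    score_pvalue,
)


def random_pwm(rng, width, name="m"):
    probs = rng.dirichlet(np.ones(4) * 2.0, size=width)
    return PWM(probs, name=name)


def enumerate_all_windows(pwm: PWM):
    """Independent oracle: score and weight of every one of the 4^w windows."""
    words = np.array(list(itertools.product(range(4), repeat=pwm.width)))
    lo = pwm.log_odds
    scores = lo[np.arange(pwm.width)[None, :], words].sum(axis=1)
    probs = pwm.background[words].prod(axis=1)
    return scores, probs


def enumerate_pvalue(pwm: PWM, score: float) -> float:
    scores, probs = enumerate_all_windows(pwm)
    return float(probs[scores >= score - 1e-9].sum())


class TestBuildPwm:
    def test_pseudocounted_column(self):
        counts = np.array([[3, 1, 0, 0]])
        pwm = build_pwm(counts, pseudocount=0.25)
        assert np.allclose(pwm.probabilities[0], [0.65, 0.25, 0.05, 0.05])

    def test_all_zero_column_is_uniform(self):
        pwm = build_pwm(np.zeros((1, 4)), pseudocount=0.25)
        assert np.allclose(pwm.probabilities[0], 0.25)

    def test_zero_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(np.ones((2, 4)), pseudocount=0.0)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(np.zeros((0, 4)))


def two_bit_pwm():
    # each position: p = (0.5, 0.25, 0.125, 0.125) over uniform background
    # -> per-letter contributions (1, 0, -1, -1) bits
    probs = np.array([[0.5, 0.25, 0.125, 0.125]] * 2)
    return PWM(probs, name="2bit")


class TestScoreAndPvalue:
    def test_forced_two_position_score(self):
        probs = np.array([[0.5, 1 / 6, 1 / 6, 1 / 6],
                          [1 / 6, 0.5, 1 / 6, 1 / 6]])
        pwm = PWM(probs)
        hits = scan_sequence(pwm, "AC", p_threshold=1.0, strands="forward")
        assert len(hits) == 1
        assert hits[0].score == pytest.approx(2 * np.log2(2.0))

    def test_dinucleotide_enumeration(self):
        pwm = two_bit_pwm()
        # only AA scores 2 bits: p = 1/16
        assert score_pvalue(pwm, 2.0) == pytest.approx(1 / 16)
        assert score_pvalue(pwm, pwm.min_score() - 1) == pytest.approx(1.0)
        assert score_pvalue(pwm, pwm.max_score() + 1) == 0.0

    def test_pvalue_monotone_nonincreasing(self, rng):
        pwm = random_pwm(rng, 5)
        grid = np.linspace(pwm.min_score() - 0.5, pwm.max_score() + 0.5, 60)
        ps = [score_pvalue(pwm, s) for s in grid]
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("width", [1, 2, 3, 4, 5, 6])
    def test_dp_matches_exhaustive_enumeration(self, width, rng):
        """DP null equals brute-force enumeration over all 4^w windows."""
        for _ in range(3):
            pwm = random_pwm(rng, width)
            enum_scores, enum_probs = enumerate_all_windows(pwm)
            scores, _ = pwm.score_distribution()
            pick = rng.choice(len(scores), size=min(len(scores), 30),
                              replace=False)
            probe = np.concatenate([scores[pick], scores[pick] + 1e-6,
                                    scores[pick] - 1e-6,
                                    [pwm.min_score() - 1, pwm.max_score() + 1]])
            for s in probe:
                expected = float(enum_probs[enum_scores >= s - 1e-9].sum())
                assert score_pvalue(pwm, float(s)) == pytest.approx(
                    expected, abs=1e-6
                )


class TestScan:
    def test_short_sequence_yields_empty(self, rng):
        pwm = random_pwm(rng, 6)
        assert scan_sequence(pwm, "ACG") == []

    def test_hits_match_per_offset_brute_force(self, rng):
        """Scan on 1 kb random sequence equals exhaustive per-offset scoring."""
        pwm = random_pwm(rng, 6)
        seq = "".join(rng.choice(list("ACGT"), 1000))
        thr = 1e-2
        hits = scan_sequence(pwm, seq, p_threshold=thr)
        brute = set()
        lo = pwm.log_odds
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            for i in range(len(s) - pwm.width + 1):
                window = s[i : i + pwm.width]
                sc = sum(lo[j, "ACGT".index(b)] for j, b in enumerate(window))
                if score_pvalue(pwm, sc) <= thr:
                    start = i if strand == "+" else len(s) - i - pwm.width
                    brute.add((start, strand, round(sc, 9)))
        assert {(h.start, h.strand, round(h.score, 9)) for h in hits} == brute

    def test_windows_containing_n_are_skipped(self, rng):
        pwm = random_pwm(rng, 3)
        hits = scan_sequence(pwm, "ACGNNACG", p_threshold=1.0)
        assert all("N" not in "ACGNNACG"[h.start : h.end] for h in hits)
        starts_fwd = {h.start for h in hits if h.strand == "+"}
        assert starts_fwd == {0, 5}

    def test_threshold_monotonicity(self, rng):
        pwm = random_pwm(rng, 5)
        seq = "".join(rng.choice(list("ACGT"), 500))
        counts = [len(scan_sequence(pwm, seq, p)) for p in (1e-4, 1e-2, 0.5, 1.0)]
        assert counts == sorted(counts)

    def test_reverse_complement_symmetry(self, rng):
        pwm = random_pwm(rng, 4)
        seq = "".join(rng.choice(list("ACGT"), 300))
        fwd = scan_sequence(pwm, seq, p_threshold=0.05)
        rev = scan_sequence(pwm, reverse_complement(seq), p_threshold=0.05)
        L, w = len(seq), pwm.width
        mapped = {(L - h.end, {"+": "-", "-": "+"}[h.strand], round(h.score, 9))
                  for h in rev}
        assert {(h.start, h.strand, round(h.score, 9)) for h in fwd} == mapped

    def test_palindromic_pwm_reports_both_strands(self):
        # ACGT-palindrome: position probs mirror to their complements reversed
        probs = np.array([
            [0.7, 0.1, 0.1, 0.1],
            [0.1, 0.7, 0.1, 0.1],
            [0.1, 0.1, 0.7, 0.1],
            [0.1, 0.1, 0.1, 0.7],
        ])
        pwm = PWM(probs, name="pal")
        hits = scan_sequence(pwm, "TTACGTTT", p_threshold=1 / 256 + 1e-9)
        assert {(h.start, h.strand) for h in hits} == {(2, "+"), (2, "-")}
        scores = [h.score for h in hits]
        assert scores[0] == pytest.approx(scores[1])


class TestConservedWindows:
    def test_identical_promoters_single_full_window(self):
        seq = "ACGT" * 25
        wins = conserved_window_detect(seq, seq, window_len=50, identity_min=70)
        assert len(wins) == 1
        assert (wins[0].start, wins[0].end) == (0, 100)
        assert wins[0].identity == 100.0

    def test_two_planted_blocks_recovered(self, rng):
        bases = list("ACGT")
        a = rng.choice(bases, 1000)
        b = rng.choice(bases, 1000)
        for s, e in ((200, 280), (700, 780)):
            b[s:e] = a[s:e]
        wins = conserved_window_detect("".join(a), "".join(b))
        assert len(wins) == 2
        for (s, e), w in zip(((200, 280), (700, 780)), wins):
            assert abs(w.start - s) < 50 and abs(w.end - e) < 50
            assert w.identity >= 70

    def test_independent_random_sequences_have_no_windows(self, rng):
        bases = list("ACGT")
        a = "".join(rng.choice(bases, 1000))
        b = "".join(rng.choice(bases, 1000))
        assert conserved_window_detect(a, b) == []

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conserved_window_detect("ACGT" * 30, "ACGT" * 40)


class TestSitePairs:
    def make_hit(self, start, motif="MEF2", strand="+", width=8):
        from riboseek.motifs import MotifHit

        return MotifHit("p", motif, start, start + width, strand, 10.0, 1e-5)

    def test_matching_offsets_pair(self):
        from riboseek.motifs import ConservedWindow

        win = ConservedWindow(100, 200, 95.0)
        pairs = cross_species_site_pairs(
            [self.make_hit(120)], [self.make_hit(122)], [win]
        )
        assert len(pairs) == 1 and pairs[0].motif == "MEF2"

    def test_hit_in_one_species_only(self):
        from riboseek.motifs import ConservedWindow

        win = ConservedWindow(100, 200, 95.0)
        assert cross_species_site_pairs([self.make_hit(120)], [], [win]) == []

    def test_hits_outside_windows_do_not_pair(self):
        from riboseek.motifs import ConservedWindow

        win = ConservedWindow(100, 200, 95.0)
        pairs = cross_species_site_pairs(
            [self.make_hit(300)], [self.make_hit(300)], [win]
        )
        assert pairs == []

    def test_different_motif_names_do_not_pair(self):
        from riboseek.motifs import ConservedWindow

        win = ConservedWindow(100, 200, 95.0)
        pairs = cross_species_site_pairs(
            [self.make_hit(120, motif="A")], [self.make_hit(120, motif="B")], [win]
        )
        assert pairs == []


class TestPwmIO:
    def test_round_trip_positions_in_rows(self, tmp_path, rng):
        pwm = random_pwm(rng, 7, name="rt")
        path = tmp_path / "m.mat"
        with open(path, "w") as fh:
            fh.write(">rt\n")
            for row in pwm.probabilities:
                fh.write(" ".join(f"{v:.9f}" for v in row) + "\n")
        loaded = read_pwm(path)
        assert loaded.name == "rt"
        assert np.allclose(loaded.probabilities, pwm.probabilities, atol=1e-6)

    def test_transposed_layout_detected(self, tmp_path, rng):
        pwm = random_pwm(rng, 7)
        path = tmp_path / "m.mat"
        with open(path, "w") as fh:
            for row in pwm.probabilities.T:  # 4 rows x width columns
                fh.write(" ".join(f"{v:.9f}" for v in row) + "\n")
        loaded = read_pwm(path)
        assert np.allclose(loaded.probabilities, pwm.probabilities, atol=1e-6)
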