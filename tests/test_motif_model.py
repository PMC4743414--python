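"""PWM parsing, log-odds scoring, exact score distributions and the
balanced FPR/FNR threshold, checked against brute-force enumeration."""

import math
from itertools import product

import numpy as np
import pytest

from enhanceodimer._util import revcomp
from enhanceodimer.motif_model import (
    NEG_INF,
    PWM,
    TransfacParseError,
    balanced_threshold,
    discretize,
    load_transfac,
    log_odds_score,
    scan,
    score_distribution,
    write_transfac,
)
from enhanceodimer.synthetic_data import make_pwm

ALPHABET = "ACGT"


# ---------------------------------------------------------------------------
# independent oracle: full 4^w enumeration


def enumerate_distribution(pwm: PWM, model: str, bin_width: float = 0.1):
    """Discretised score distribution by brute-force word enumeration."""
    lo = pwm.log_odds
    weights = np.tile(pwm.background, (pwm.width, 1)) if model == "background" else pwm.probs
    masses: dict[int, float] = {}
    for word in product(range(4), repeat=pwm.width):
        prob = 1.0
        score_bin = 0
        for i, b in enumerate(word):
            prob *= weights[i][b]
            score_bin += math.floor(lo[i][b] / bin_width + 0.5)
        masses[score_bin] = masses.get(score_bin, 0.0) + prob
    return masses


def brute_force_threshold(pwm: PWM, ratio: float = 100.0, bin_width: float = 0.1) -> float:
    """Smallest grid threshold satisfying FPR <= ratio * FNR, by enumeration."""
    bg = enumerate_distribution(pwm, "background", bin_width)
    mo = enumerate_distribution(pwm, "motif", bin_width)
    bins = sorted(set(bg) | set(mo))
    for k in range(bins[0], bins[-1] + 1):
        fpr = sum(p for b, p in bg.items() if b >= k)
        fnr = sum(p for b, p in mo.items() if b < k)
        if fpr <= ratio * fnr:
            return k * bin_width
    return bins[-1] * bin_width


# ---------------------------------------------------------------------------
# TRANSFAC parsing


class TestLoadTransfac:
    def test_counts_transcribed_exactly(self, tmp_path):
        path = tmp_path / "one.transfac"
        path.write_text(
            "ID  M1\nP0  A C G T\n01  10 0 0 0\n02  0 10 0 0\n03  0 0 10 0\n//\n"
        )
        (pwm,) = load_transfac(path)
        assert pwm.width == 3
        assert pwm.consensus == "ACG"
        np.testing.assert_array_equal(pwm.counts[:, 0], [10, 0, 0])

    def test_two_records(self, tmp_path):
        path = tmp_path / "two.transfac"
        path.write_text(
            "ID  M1\nP0  A C G T\n01  1 2 3 4\n//\n"
            "ID  M2\nP0  A C G T\n01  4 3 2 1\n02  1 1 1 1\n//\n"
        )
        pwms = load_transfac(path)
        assert [p.id for p in pwms] == ["M1", "M2"]
        assert [p.width for p in pwms] == [1, 2]

    def test_malformed_row_names_the_line(self, tmp_path):
        path = tmp_path / "bad.transfac"
        path.write_text("ID  M1\nP0  A C G T\n01  2 3 foo 1\n//\n")
        with pytest.raises(TransfacParseError, match="01"):
            load_transfac(path)

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.transfac"
        path.write_text("")
        with pytest.warns(UserWarning):
            assert load_transfac(path) == []

    def test_roundtrip(self, tmp_path, pwm_factory):
        pwms = [pwm_factory(4, s) for s in range(3)]
        path = tmp_path / "rt.transfac"
        write_transfac(pwms, path)
        back = load_transfac(path)
        assert [p.id for p in back] == [p.id for p in pwms]
        for orig, re_read in zip(pwms, back):
            np.testing.assert_allclose(re_read.counts, orig.counts, rtol=1e-4, atol=1e-4)


# ---------------------------------------------------------------------------
# scoring


class TestLogOddsScore:
    def test_background_pwm_scores_zero(self, uniform_pwm):
        seq = "ACGTACGTAC"
        for start in range(len(seq) - uniform_pwm.width + 1):
            assert log_odds_score(uniform_pwm, seq, start) == pytest.approx(0.0)

    def test_hand_computed_two_column_score(self):
        # probabilities set exactly (pseudocount off): 2 * log2(0.97/0.25)
        pwm = PWM(
            id="H",
            counts=np.array([[0.97, 0.01, 0.01, 0.01], [0.01, 0.97, 0.01, 0.01]]),
            pseudocount_fraction=0.0,
        )
        expected = 2 * math.log2(0.97 / 0.25)
        assert log_odds_score(pwm, "AC", 0) == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(3.9123, abs=1e-3)

    def test_minus_strand_is_reverse_complement(self, pwm_factory):
        pwm = pwm_factory(3, 11)
        assert log_odds_score(pwm, "ACT", 0, "-") == pytest.approx(
            log_odds_score(pwm, revcomp("ACT"), 0, "+")
        )

    def test_n_disqualifies_window(self, uniform_pwm):
        assert log_odds_score(uniform_pwm, "ACNTACGT", 0) == NEG_INF

    def test_out_of_bounds_raises(self, uniform_pwm):
        with pytest.raises(IndexError):
            log_odds_score(uniform_pwm, "ACG", 0)


# ---------------------------------------------------------------------------
# score distributions


class TestScoreDistribution:
    def test_width_one_pwm_has_four_atoms(self):
        pwm = PWM(id="W1", counts=np.array([[40.0, 30.0, 20.0, 10.0]]))
        dist = score_distribution(pwm, "background", bin_width=0.01)
        assert len(dist.masses[dist.masses > 0]) == 4
        np.testing.assert_allclose(dist.masses[dist.masses > 0], 0.25)

    @pytest.mark.parametrize("model", ["background", "motif"])
    @pytest.mark.parametrize("width", [2, 4, 6])
    def test_matches_enumeration(self, pwm_factory, model, width):
        pwm = pwm_factory(width, seed=width * 7 + 1)
        dist = score_distribution(pwm, model, bin_width=0.1)
        expected = enumerate_distribution(pwm, model, bin_width=0.1)
        actual = {
            int(b): m for b, m in zip(dist.scores_bins(), dist.masses) if m > 0
        }
        assert set(actual) == {b for b, p in expected.items() if p > 1e-15}
        for b, p in expected.items():
            assert actual.get(b, 0.0) == pytest.approx(p, abs=1e-9)

    def test_mass_conservation(self, pwm_factory):
        for seed in range(10):
            pwm = pwm_factory(5, seed)
            for model in ("background", "motif"):
                dist = score_distribution(pwm, model)
                assert dist.masses.sum() == pytest.approx(1.0, abs=1e-6)

    def test_refining_bins_preserves_cumulative_mass(self, pwm_factory):
        pwm = pwm_factory(4, 3)
        coarse = score_distribution(pwm, "background", bin_width=0.2)
        fine = score_distribution(pwm, "background", bin_width=0.1)
        # cumulative probability at any coarse bin edge moves by at most
        # the largest single coarse-bin mass
        biggest = coarse.masses.max()
        for t in coarse.scores:
            assert abs(coarse.sf(t) - fine.sf(t)) <= biggest + 1e-9


# ---------------------------------------------------------------------------
# balanced threshold


class TestBalancedThreshold:
    def test_agrees_with_enumeration_small_widths(self, pwm_factory):
        for seed in range(12):
            width = 2 + seed % 4
            pwm = pwm_factory(width, seed + 100)
            assert balanced_threshold(pwm) == pytest.approx(
                brute_force_threshold(pwm), abs=1e-9
            )

    def test_monotone_in_ratio(self, pwm_factory):
        for seed in range(5):
            pwm = pwm_factory(4, seed + 50)
            t100 = balanced_threshold(pwm, ratio=100)
            t1000 = balanced_threshold(pwm, ratio=1000)
            assert t1000 <= t100 + 1e-9

    def test_balanced_condition_holds_and_is_tight(self, pwm_factory):
        bw = 0.1
        for seed in range(8):
            pwm = pwm_factory(4, seed + 200)
            t = balanced_threshold(pwm, ratio=100, bin_width=bw)
            bg = score_distribution(pwm, "background", bw)
            mo = score_distribution(pwm, "motif", bw)
            assert bg.sf(t) <= 100 * mo.cdf_below(t) + 1e-12
            below = t - bw
            if discretize(below, bw) >= min(bg.offset, mo.offset):
                assert bg.sf(below) > 100 * mo.cdf_below(below)


# ---------------------------------------------------------------------------
# scanning


class TestScan:
    def test_planted_consensus_found_once(self):
        pwm = make_pwm("P", "ACGTTACG", dominant=0.97)
        seq = "T" * 20 + "ACGTTACG" + "T" * 20
        hits = scan(pwm, seq, threshold=10.0)
        assert [(h.start, h.strand) for h in hits] == [(20, "+")]

    def test_reverse_complement_symmetry(self, pwm_factory):
        pwm = pwm_factory(4, 77)
        seq = "ACGTTGCAATGCGGTAC"
        fwd = scan(pwm, seq, threshold=0.5)
        rev = scan(pwm, revcomp(seq), threshold=0.5)
        assert len(fwd) == len(rev)
        flipped = {
            (len(seq) - h.end, {"+": "-", "-": "+"}[h.strand], round(h.score, 6))
            for h in fwd
        }
        assert flipped == {(h.start, h.strand, round(h.score, 6)) for h in rev}

    def test_sequence_shorter_than_width(self, uniform_pwm):
        assert scan(uniform_pwm, "AC", threshold=-10) == []

    def test_sorted_plus_before_minus(self, uniform_pwm):
        hits = scan(uniform_pwm, "ACGTACGT", threshold=-1.0)
        keys = [(h.start, h.strand) for h in hits]
        assert keys == sorted(keys)
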