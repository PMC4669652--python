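"""PWM construction, exact threshold calibration, scanning, GC-matched
background sampling, and the binomial enrichment test."""

import numpy as np
import pytest

from _oracles import binomial_tail_exact, pwm_tail_enumeration
from peaklab.errors import FormatError, SamplingError, UsageError
from peaklab.genome import Genome
from peaklab.motifs import (
    PFM,
    binomial_enrichment,
    build_pwm,
    enrich_motif_set,
    gc_histogram,
    sample_gc_matched_background,
    score_distribution,
    score_threshold,
    star_annotation,
    window_has_hit,
)
from peaklab.synthetic import generate_genome


def _pfm(counts, motif_id="M", name="M"):
    return PFM(motif_id, name, np.array(counts, dtype=np.int64))


class TestBuildPwm:
    def test_pure_column_approaches_log_odds_limit(self):
        pfm = _pfm([[4], [0], [0], [0]])
        pwm = build_pwm(pfm, pseudocount=1e-9)
        assert pwm.scores[0, 0] == pytest.approx(2.0, abs=1e-6)  # log2(4)

    def test_flat_column_scores_zero(self):
        pfm = _pfm([[3], [3], [3], [3]])
        pwm = build_pwm(pfm)
        assert np.allclose(pwm.scores, 0.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_hand_formula(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 40, size=(4, 5)) + 1
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        pc = 0.8
        pwm = build_pwm(_pfm(counts), bg, pc)
        colsum = counts.sum(axis=0)
        expected = np.log2(
            ((counts + pc * bg[:, None]) / (colsum + pc)) / bg[:, None]
        )
        assert np.allclose(pwm.scores, expected)

    def test_rejects_bad_background(self):
        with pytest.raises(UsageError):
            build_pwm(_pfm([[1], [1], [1], [1]]), [0.5, 0.5, 0.0, 0.0])
        with pytest.raises(UsageError):
            build_pwm(_pfm([[1], [1], [1], [1]]), [0.4, 0.4, 0.4, 0.4])


class TestScoreThreshold:
    @pytest.mark.parametrize("width", [3, 4, 5])
    @pytest.mark.parametrize("p_target", [1e-2, 1e-3])
    def test_dp_tail_equals_exhaustive_enumeration(self, width, p_target):
        rng = np.random.default_rng(width)
        counts = rng.integers(0, 25, size=(4, width)) + 1
        pwm = build_pwm(_pfm(counts), [0.3, 0.2, 0.2, 0.3])
        t = score_threshold(pwm, p_target)
        scores, probs = pwm_tail_enumeration(pwm)
        gran = 1e-3
        enum_tail = probs[scores * gran >= t - gran / 2].sum()
        lo, dist = score_distribution(pwm)
        support = (lo + np.arange(len(dist))) * gran
        dp_tail = dist[support >= t - gran / 2].sum()
        assert dp_tail == pytest.approx(enum_tail, abs=1e-12)
        assert enum_tail <= p_target
        # minimality: one granularity step lower exceeds the target
        below = probs[scores * gran >= t - 1.5 * gran].sum()
        assert below > p_target

    def test_p_target_one_returns_minimum_score(self):
        pwm = build_pwm(_pfm([[5, 1], [1, 5], [1, 1], [1, 1]]))
        t = score_threshold(pwm, 1.0)
        assert t == pytest.approx(pwm.min_score(), abs=2e-3)

    def test_threshold_monotone_in_target(self):
        pwm = build_pwm(_pfm([[9, 0, 2], [1, 8, 2], [0, 1, 3], [0, 1, 3]]))
        assert score_threshold(pwm, 1e-5) >= score_threshold(pwm, 1e-3)

    def test_rejects_bad_target(self):
        pwm = build_pwm(_pfm([[1], [1], [1], [1]]))
        with pytest.raises(UsageError):
            score_threshold(pwm, 0.0)


class TestScanning:
    CONSENSUS = "ACGTACGT"

    @pytest.fixture
    def sharp_pwm(self):
        base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        counts = np.ones((4, len(self.CONSENSUS)), dtype=np.int64)
        for j, b in enumerate(self.CONSENSUS):
            counts[base_idx[b], j] = 100
        return build_pwm(_pfm(counts))

    def test_detects_planted_consensus(self, sharp_pwm):
        t = score_threshold(sharp_pwm, 1e-4)
        seq = "TTTTTTTT" + self.CONSENSUS + "TTTTTTTT"
        assert window_has_hit(seq, sharp_pwm, t)

    def test_detects_reverse_complement(self, sharp_pwm):
        t = score_threshold(sharp_pwm, 1e-4)
        rc = self.CONSENSUS.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        seq = "TTTTTTTT" + rc + "TTTTTTTT"
        assert window_has_hit(seq, sharp_pwm, t)

    def test_all_ambiguous_window_never_hits(self, sharp_pwm):
        assert not window_has_hit("N" * 30, sharp_pwm, -1e9)

    def test_window_shorter_than_motif(self, sharp_pwm):
        assert not window_has_hit("ACG", sharp_pwm, -1e9)

    def test_non_iupac_character_rejected(self, sharp_pwm):
        with pytest.raises(FormatError):
            window_has_hit("ACGTACGTXACGT", sharp_pwm, 0.0)


class TestGcBackground:
    def test_homogeneous_genome_matches_trivially(self):
        genome = generate_genome({"chr1": 200_000}, gc_profile=0.5, seed=0)
        peak_seqs = [genome.fetch("chr1", i * 500, i * 500 + 201) for i in range(60)]
        hist = gc_histogram(peak_seqs)
        wins = sample_gc_matched_background(genome, 200, 201, hist, seed=0)
        gcs = [genome.gc_fraction(*w) for w in wins]
        assert len(wins) == 200
        assert abs(np.mean(gcs) - np.mean([
            (s.count("G") + s.count("C")) / len(s) for s in peak_seqs
        ])) < 0.02

    def test_gradient_genome_matches_target_gc(self):
        genome = generate_genome(
            {"chr1": 400_000}, {"chr1": [0.3, 0.45, 0.6, 0.75]}, seed=1
        )
        hist = np.zeros(20)
        hist[12] = 1.0  # demand the [0.60, 0.65) bin
        wins = sample_gc_matched_background(genome, 300, 201, hist, seed=2)
        gcs = [genome.gc_fraction(*w) for w in wins]
        assert 0.60 <= np.mean(gcs) < 0.65

    def test_deterministic_under_seed(self):
        genome = generate_genome({"chr1": 100_000}, 0.45, seed=0)
        hist = gc_histogram([genome.fetch("chr1", i * 300, i * 300 + 201)
                             for i in range(40)])
        w1 = sample_gc_matched_background(genome, 100, 201, hist, seed=7)
        w2 = sample_gc_matched_background(genome, 100, 201, hist, seed=7)
        assert w1 == w2

    def test_unobtainable_bin_raises_naming_it(self):
        genome = generate_genome({"chr1": 50_000}, 0.40, seed=0)
        hist = np.zeros(20)
        hist[19] = 1.0  # demand GC in [0.95, 1.0] from a 0.40-GC genome
        with pytest.raises(SamplingError, match="0.95"):
            sample_gc_matched_background(
                genome, 5, 201, hist, seed=0, max_draw_factor=100
            )


class TestBinomial:
    def test_closed_form_all_hits_at_half(self):
        # p0 = (4+1)/(8+2) = 0.5; all 10 of 10 hits: p = 2^-10
        assert binomial_enrichment(10, 10, 4, 8) == pytest.approx(2**-10, rel=1e-12)

    def test_rate_equal_to_background_is_insignificant(self):
        assert binomial_enrichment(50, 100, 499, 998) >= 0.5

    def test_zero_hits_gives_p_one(self):
        assert binomial_enrichment(0, 50, 10, 100) == 1.0

    def test_empty_peak_side_rejected(self):
        with pytest.raises(UsageError):
            binomial_enrichment(0, 0, 1, 10)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exact_rational_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_peak = int(rng.integers(1, 200))
        k_peak = int(rng.integers(0, n_peak + 1))
        n_bg = int(rng.integers(1, 2000))
        k_bg = int(rng.integers(0, n_bg + 1))
        got = binomial_enrichment(k_peak, n_peak, k_bg, n_bg)
        exact = binomial_tail_exact(k_peak, n_peak, k_bg, n_bg)
        assert got == pytest.approx(exact, rel=1e-9)


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [(1e-12, "***"), (1e-10, "**"), (5e-3, "**"), (0.05, "*"),
         (0.0999, "*"), (0.1, ""), (0.5, ""), (1.0, "")],
    )
    def test_tiers(self, p, expected):
        assert star_annotation(p) == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(UsageError):
            star_annotation(1.5)


class TestEnrichMotifSet:
    def test_empty_library_gives_empty_list(self, mini_world):
        w = mini_world
        assert enrich_motif_set(w.peaks_A, w.genome, []) == []

    def test_duplicate_motifs_get_identical_records_in_stable_order(self, mini_world):
        w = mini_world
        twin = PFM("M_b", w.motif.name, w.motif.counts)
        orig = PFM("M_a", w.motif.name, w.motif.counts)
        records = enrich_motif_set(
            w.peaks_A, w.genome, [twin, orig], seed=0, bg_multiplier=3
        )
        assert [r.motif_id for r in records] == ["M_a", "M_b"]
        assert records[0].p_binomial == records[1].p_binomial
        assert records[0].k_peak == records[1].k_peak

    def test_invariant_to_peak_order(self, mini_world):
        w = mini_world
        reversed_peaks = type(w.peaks_A)(
            "rev", list(w.peaks_A.peaks)[::-1], w.peaks_A.genome_id
        )
        r1 = enrich_motif_set(w.peaks_A, w.genome, [w.motif], seed=0,
                              bg_multiplier=3)
        r2 = enrich_motif_set(reversed_peaks, w.genome, [w.motif], seed=0,
                              bg_multiplier=3)
        assert r1[0].k_peak == r2[0].k_peak
        assert r1[0].p_binomial == r2[0].p_binomial
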