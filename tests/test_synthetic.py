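"""Generator contracts: determinism, exact constructed truths, and the
statistical structure the downstream analyses assume."""

import numpy as np
import pytest

from peaklab.errors import GenerationError, UsageError
from peaklab.genome import gc_fraction
from peaklab.intervals import venn_counts
from peaklab.motifs import build_pwm, score_threshold, window_has_hit
from peaklab.qc import pbc
from peaklab.synthetic import (
    generate_genes,
    generate_genome,
    generate_peak_pair,
    generate_tags,
    generate_world,
    place_matched_set,
    plant_motifs,
    scatter_peaks,
)
from peaklab.genes import promoter_fraction


def sharp_pfm(rng, width=8, dominant=5000, motif_id="SHARP"):
    """Near-consensus motif: dominant count per column >> alternatives."""
    from peaklab.motifs import PFM

    counts = np.ones((4, width), dtype=np.int64)
    for j in range(width):
        counts[int(rng.integers(0, 4)), j] = dominant
    return PFM(motif_id, motif_id, counts)


class TestGenome:
    def test_gc_target_hit_within_binomial_ci(self):
        g = generate_genome({"chr1": 100_000}, gc_profile=0.5, seed=0)
        assert abs(gc_fraction(g.sequence("chr1")) - 0.5) < 0.01

    def test_same_seed_reproduces_sequence(self):
        g1 = generate_genome({"chr1": 20_000}, 0.42, seed=3)
        g2 = generate_genome({"chr1": 20_000}, 0.42, seed=3)
        assert g1.sequence("chr1") == g2.sequence("chr1")

    def test_region_targets_ordered(self):
        g = generate_genome({"chr1": 100_000}, {"chr1": [0.3, 0.7]}, seed=1)
        lo = gc_fraction(g.fetch("chr1", 0, 50_000))
        hi = gc_fraction(g.fetch("chr1", 50_000, 100_000))
        assert lo < hi

    def test_rejects_bad_gc_target(self):
        with pytest.raises(UsageError):
            generate_genome({"chr1": 20_000}, 1.5, seed=0)


class TestPeakPair:
    def test_zero_overlap_fraction(self):
        A, B, truth = generate_peak_pair(50, 50, 0.0, seed=0)
        v = venn_counts(A, B)
        assert v.common_clusters == 0
        assert truth.n_overlapping == 0

    def test_full_overlap_fraction(self):
        A, B, truth = generate_peak_pair(60, 40, 1.0, seed=1)
        v = venn_counts(A, B)
        assert v.B_shared == 40 == truth.n_overlapping

    def test_exact_constructed_count(self):
        A, B, truth = generate_peak_pair(300, 200, 0.37, seed=2)
        v = venn_counts(A, B)
        assert v.B_shared == truth.n_overlapping == 74
        assert v.A_shared == 74
        assert v.common_clusters == 74

    def test_insufficient_space_raises(self):
        with pytest.raises(GenerationError):
            generate_peak_pair(2_000, 2_000, 0.0, {"chr1": 50_000}, seed=0)

    def test_deterministic(self):
        A1, B1, _ = generate_peak_pair(40, 40, 0.5, seed=9)
        A2, B2, _ = generate_peak_pair(40, 40, 0.5, seed=9)
        assert A1.peaks == A2.peaks and B1.peaks == B2.peaks


class TestPlaceMatchedSet:
    def test_truth_holds_against_fixed_a(self):
        A = scatter_peaks(150, seed=4, label="A")
        B, truth = place_matched_set(A, 100, 0.42, seed=5)
        v = venn_counts(A, B)
        assert v.B_shared == truth.n_overlapping == 42
        assert v.A_shared == 42
        assert v.common_clusters == 42


class TestGenes:
    def test_full_proximal_planting_gives_100_percent(self):
        peaks = scatter_peaks(60, seed=0, label="P")
        genes, placed, _ = generate_genes(
            50, tss_proximal_peaks=peaks, tss_proximal_frac=1.0, seed=1
        )
        assert promoter_fraction(placed, genes) == 100.0

    def test_partial_planting_is_exact(self):
        peaks = scatter_peaks(200, seed=2, label="P")
        genes, placed, truth = generate_genes(
            100, tss_proximal_peaks=peaks, tss_proximal_frac=0.7, seed=3
        )
        assert len(truth.proximal_peaks) == 140
        assert promoter_fraction(placed, genes) == 70.0

    def test_histogram_roughly_symmetric_with_random_strands(self):
        from peaklab.genes import tss_histogram

        peaks = scatter_peaks(400, seed=6, label="P")
        genes, placed, _ = generate_genes(
            150, tss_proximal_peaks=peaks, tss_proximal_frac=1.0, seed=7,
        )
        frame = tss_histogram(placed, genes)
        up = frame.loc[frame["bin"] == "[-1000,0)", "count"].item()
        down = frame.loc[frame["bin"] == "[0,1000)", "count"].item()
        assert up + down == 400
        # random strands + uniform offsets: both sides populated comparably
        assert min(up, down) > 0.35 * 400


class TestPlantMotifs:
    def test_full_planting_detected_in_nearly_all_windows(self):
        rng = np.random.default_rng(0)
        pfm = sharp_pfm(rng)
        genome = generate_genome({"chr1": 400_000}, 0.45, seed=1)
        peaks = scatter_peaks(200, {"chr1": 400_000}, seed=2, label="P")
        planted, truth = plant_motifs(genome, peaks, pfm, 1.0, 0.0, seed=3)
        pwm = build_pwm(pfm)
        t = score_threshold(pwm, 1e-4)
        hits = sum(
            window_has_hit(planted.fetch(*w), pwm, t) for w in truth.peak_windows
        )
        assert hits >= 0.99 * len(truth.peak_windows)

    def test_no_planting_matches_false_positive_budget(self):
        rng = np.random.default_rng(1)
        pfm = sharp_pfm(rng)
        genome = generate_genome({"chr1": 400_000}, 0.45, seed=4)
        peaks = scatter_peaks(300, {"chr1": 400_000}, seed=5, label="P")
        planted, truth = plant_motifs(genome, peaks, pfm, 0.0, 0.0, seed=6)
        pwm = build_pwm(pfm)
        t = score_threshold(pwm, 1e-4)
        hits = sum(
            window_has_hit(planted.fetch(*w), pwm, t) for w in truth.peak_windows
        )
        # expected hit rate <= ~2 * 194 positions * 1e-4 per window
        assert hits / len(truth.peak_windows) < 0.15

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        pfm = sharp_pfm(rng)
        genome = generate_genome({"chr1": 100_000}, 0.45, seed=0)
        peaks = scatter_peaks(30, {"chr1": 100_000}, seed=1, label="P")
        g1, t1 = plant_motifs(genome, peaks, pfm, 0.5, 0.1, seed=11)
        g2, t2 = plant_motifs(genome, peaks, pfm, 0.5, 0.1, seed=11)
        assert g1.sequence("chr1") == g2.sequence("chr1")
        assert t1 == t2


class TestTags:
    def test_no_duplication_gives_perfect_pbc(self):
        peaks = scatter_peaks(50, seed=0, label="P")
        tags, truth = generate_tags(peaks, 0.3, 5_000, 200, 36, 0.0, seed=1)
        assert pbc(tags) == 1.0
        assert truth.expected_pbc == 1.0

    def test_measured_pbc_equals_bookkeeping(self):
        peaks = scatter_peaks(50, seed=0, label="P")
        tags, truth = generate_tags(peaks, 0.3, 5_000, 200, 36, 0.25, seed=2)
        assert pbc(tags) == pytest.approx(truth.expected_pbc, abs=1e-12)

    def test_invalid_parameters_rejected(self):
        peaks = scatter_peaks(5, seed=0, label="P")
        with pytest.raises(UsageError):
            generate_tags(peaks, 0.3, 100, 30, 36, 0.0, seed=0)  # frag < read
        with pytest.raises(UsageError):
            generate_tags(peaks, 1.3, 100, 200, 36, 0.0, seed=0)

    def test_deterministic(self):
        peaks = scatter_peaks(20, seed=3, label="P")
        t1, _ = generate_tags(peaks, 0.5, 1_000, 200, 36, 0.1, seed=4)
        t2, _ = generate_tags(peaks, 0.5, 1_000, 200, 36, 0.1, seed=4)
        assert t1 == t2


class TestWorld:
    def test_world_truths_hold_jointly(self, mini_world):
        w = mini_world
        v = venn_counts(w.peaks_A, w.peaks_B)
        assert v.B_shared == w.pair_truth.n_overlapping
        assert v.A_shared == w.pair_truth.n_overlapping
        assert v.common_clusters == w.pair_truth.n_overlapping
        measured = promoter_fraction(w.peaks_A, w.genes)
        expected = 100.0 * len(w.gene_truth.proximal_peaks) / len(w.peaks_A)
        assert measured == expected

    def test_world_deterministic(self):
        w1 = generate_world(seed=5, chrom_sizes={"chr1": 200_000},
                            n_A=30, n_B=30, n_genes=20, n_tags=2_000,
                            n_decoys=1, tss_proximal_frac=0.5)
        w2 = generate_world(seed=5, chrom_sizes={"chr1": 200_000},
                            n_A=30, n_B=30, n_genes=20, n_tags=2_000,
                            n_decoys=1, tss_proximal_frac=0.5)
        assert w1.peaks_A.peaks == w2.peaks_A.peaks
        assert w1.tags == w2.tags
        assert w1.genome.sequence("chr1") == w2.genome.sequence("chr1")
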