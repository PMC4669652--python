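"""Co-localization statistics: exact Fisher tail, permutation null
calibration, heat-map construction, Jaccard."""

from math import comb

import numpy as np
import pytest

from _oracles import fisher_tail_exact, heatmap_oracle
from conftest import random_peakset
from peaklab.coloc import (
    ContingencyTable2x2,
    fisher_colocalization,
    fisher_pvalue,
    heatmap_matrix,
    jaccard,
    permutation_overlap_test,
)
from peaklab.errors import UsageError
from peaklab.intervals import Peak, PeakSet
from peaklab.synthetic import scatter_peaks


class TestFisher:
    def test_fully_concentrated_table(self):
        # all 5 positive-A bins are positive-B: p = 1 / C(100, 5)
        p, _ = fisher_pvalue(ContingencyTable2x2(5, 0, 0, 95))
        assert p == pytest.approx(1 / comb(100, 5), rel=1e-12)

    def test_no_enrichment_has_large_p(self):
        p, _ = fisher_pvalue(ContingencyTable2x2(0, 10, 10, 80))
        assert p >= 0.5

    def test_log10_stays_finite_when_p_underflows(self):
        p, log10p = fisher_pvalue(ContingencyTable2x2(400, 0, 0, 2000))
        assert p == 0.0 or p < 1e-300
        assert np.isfinite(log10p) and log10p < -300

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exact_integer_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
        if a + b + c + d == 0:
            a = 1
        p, _ = fisher_pvalue(ContingencyTable2x2(a, b, c, d))
        exact = fisher_tail_exact(a, a + b, a + c, a + b + c + d)
        assert p == pytest.approx(exact, rel=1e-9)

    def test_monotone_in_concordant_cell(self):
        # fixed margins K = 20, n = 20, N = 100; p must fall as a grows
        ps = []
        for a in range(0, 21):
            b = 20 - a
            c = 20 - a
            d = 100 - a - b - c
            ps.append(fisher_pvalue(ContingencyTable2x2(a, b, c, d))[0])
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_binning_labels_via_one_bp_rule(self):
        # a 1-bp peak straddling a bin boundary marks only its own bin;
        # a peak spanning the boundary marks both
        A = PeakSet("A", [Peak("chr1", 99, 101)], "g")
        B = PeakSet("B", [Peak("chr1", 100, 101)], "g")
        table, _ = fisher_colocalization(A, B, {"chr1": 1000}, bin_width=100)
        assert table.a == 1          # bin [100, 200) has both
        assert table.b == 1          # bin [0, 100) has A only
        assert table.total == 10

    def test_empty_genome_rejected(self):
        A = PeakSet("A", [Peak("chr1", 0, 10)], "g")
        with pytest.raises(UsageError):
            fisher_colocalization(A, A, {})


class TestPermutation:
    def test_empty_b_gives_p_one(self):
        A = PeakSet("A", [Peak("chr1", 100, 200)], "g")
        B = PeakSet("B", [], "g")
        res = permutation_overlap_test(A, B, {"chr1": 10_000}, n_perm=20, seed=0)
        assert res.observed_shared == 0
        assert res.p_emp == 1.0

    def test_zero_permutations_rejected(self):
        A = PeakSet("A", [Peak("chr1", 100, 200)], "g")
        with pytest.raises(UsageError):
            permutation_overlap_test(A, A, {"chr1": 10_000}, n_perm=0)

    def test_peak_longer_than_chromosome_rejected(self):
        A = PeakSet("A", [Peak("chr1", 0, 20_000)], "g")
        with pytest.raises(UsageError):
            permutation_overlap_test(A, A, {"chr1": 10_000}, n_perm=5)

    def test_null_p_values_uniform_on_support(self):
        """With A itself drawn from the permutation null, p_emp must be
        superuniform and match the uniform CDF at every attained value."""
        sizes = {"chr1": 120_000}
        B = scatter_peaks(60, sizes, seed=999, label="B",
                          width_sampler=lambda rng: 400)
        n_perm = 49
        # a statistic with a wide range keeps tie lumps small relative to
        # the 0.1 tolerance
        widths = [80, 120, 150, 200, 250, 300, 90, 110, 140, 180] * 10
        ps = []
        for rep in range(600):
            # observed A drawn from the permutation null itself:
            # independent uniform placement, lengths preserved
            rng = np.random.default_rng(10_000 + rep)
            peaks = [
                Peak("chr1", s, s + w, f"A{i}")
                for i, (w, s) in enumerate(
                    (w, int(rng.integers(0, sizes["chr1"] - w + 1)))
                    for w in widths
                )
            ]
            A = PeakSet("A", peaks, "synthetic")
            res = permutation_overlap_test(A, B, sizes, n_perm=n_perm, seed=rep)
            ps.append(res.p_emp)
        ps = np.sort(ps)
        for v in np.unique(ps):
            ecdf = np.mean(ps <= v)
            assert abs(ecdf - v) < 0.1


class TestHeatmap:
    def test_uniform_coverage_gives_equal_bins(self):
        anchors = PeakSet("A", [Peak("chr1", 900, 1100)], "g")  # anchor 1000
        signal = PeakSet("S", [Peak("chr1", 500, 1500)], "g")
        hm = heatmap_matrix(anchors, signal, flank=200, n_bins=8)
        assert np.allclose(hm.values, 1.0)

    def test_disjoint_signal_gives_zero_matrix(self):
        anchors = PeakSet("A", [Peak("chr1", 900, 1100)], "g")
        signal = PeakSet("S", [Peak("chr2", 500, 1500)], "g")
        hm = heatmap_matrix(anchors, signal, flank=200, n_bins=8)
        assert np.all(hm.values == 0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_rasterization_oracle(self, seed):
        rng = np.random.default_rng(seed)
        anchors = random_peakset(rng, 12, "A", span=5_000)
        signal = random_peakset(rng, 60, "S", span=5_000)
        flank, n_bins = 300, 7
        hm = heatmap_matrix(anchors, signal, flank, n_bins)
        expected = heatmap_oracle(
            list(anchors), [(p.chrom, p.start, p.end) for p in signal],
            flank, n_bins,
        )
        # implementation rows are reordered; undo for comparison
        restored = np.empty_like(hm.values)
        restored[hm.row_order] = hm.values
        assert np.allclose(restored, expected)

    def test_row_sums_invariant_under_reordering(self):
        rng = np.random.default_rng(3)
        anchors = random_peakset(rng, 10, "A", span=5_000)
        signal = random_peakset(rng, 40, "S", span=5_000)
        hm = heatmap_matrix(anchors, signal, 250, 5)
        sums = hm.values.sum(axis=1)
        assert np.all(np.diff(sums) <= 1e-12)  # sorted descending


class TestJaccard:
    def test_simple_half_overlap(self):
        A = PeakSet("A", [Peak("chr1", 0, 100)], "g")
        B = PeakSet("B", [Peak("chr1", 50, 150)], "g")
        assert jaccard(A, B) == pytest.approx(50 / 150)

    def test_identical_sets(self):
        A = PeakSet("A", [Peak("chr1", 0, 100), Peak("chr2", 5, 50)], "g")
        assert jaccard(A, A) == 1.0
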