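"""Library QC metrics: SPOT, PBC, strand cross-correlation, NSC/RSC,
saturation, checked against direct recomputation on small instances."""

import numpy as np
import pytest

from _oracles import cross_correlation_oracle
from peaklab.errors import UsageError
from peaklab.intervals import Peak, PeakSet
from peaklab.qc import (
    CrossCorrelationProfile,
    TagRecord,
    cross_correlation,
    nsc_rsc,
    pbc,
    saturation_curve,
    spot,
)


def _tag(chrom, five, strand, read_len=20):
    if strand == "+":
        return TagRecord(chrom, five, five + read_len, "+")
    return TagRecord(chrom, five - read_len + 1, five + 1, "-")


class TestSpot:
    def test_all_tags_inside_peaks(self):
        peaks = PeakSet("P", [Peak("chr1", 0, 1000)], "g")
        tags = [_tag("chr1", i * 50, "+") for i in range(10)]
        assert spot(tags, peaks) == 1.0

    def test_no_peaks_gives_zero(self):
        tags = [_tag("chr1", 100, "+")]
        assert spot(tags, PeakSet("P", [], "g")) == 0.0

    def test_minus_strand_uses_five_prime_end(self):
        peaks = PeakSet("P", [Peak("chr1", 90, 110)], "g")
        inside = _tag("chr1", 100, "-")   # 5' end 100, body extends left
        outside = _tag("chr1", 80, "-")   # 5' end 80, body reaches into peak
        assert spot([inside], peaks) == 1.0
        assert spot([outside], peaks) == 0.0

    def test_empty_tags_rejected(self):
        with pytest.raises(UsageError):
            spot([], PeakSet("P", [], "g"))

    def test_invariant_under_tag_order(self):
        rng = np.random.default_rng(0)
        peaks = PeakSet("P", [Peak("chr1", 200, 700)], "g")
        tags = [_tag("chr1", int(x), "+") for x in rng.integers(0, 1000, 50)]
        assert spot(tags, peaks) == spot(tags[::-1], peaks)


class TestPbc:
    def test_duplicate_free_library(self):
        tags = [_tag("chr1", i, "+") for i in range(20)]
        assert pbc(tags) == 1.0

    def test_everything_duplicated_twice(self):
        tags = [_tag("chr1", i, "+") for i in range(10)] * 2
        assert pbc(tags) == 0.0

    def test_strand_distinguishes_positions(self):
        tags = [_tag("chr1", 100, "+"), _tag("chr1", 100, "-")]
        assert pbc(tags) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(UsageError):
            pbc([])


class TestCrossCorrelation:
    def test_constructed_offset_is_recovered(self):
        # + strand 5' ends at x, - strand at exactly x + 150
        rng = np.random.default_rng(0)
        xs = rng.integers(1000, 9000, size=300)
        tags = [_tag("chr1", int(x), "+") for x in xs]
        tags += [_tag("chr1", int(x) + 150, "-") for x in xs]
        prof = cross_correlation(tags, max_shift=300, chrom_sizes={"chr1": 10_000})
        assert prof.argmax_shift == 150

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_pearson_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sizes = {"chr1": 3_000, "chr2": 2_000}
        tags = []
        for chrom, L in sizes.items():
            for x in rng.integers(30, L - 30, size=150):
                tags.append(_tag(chrom, int(x), "+" if rng.random() < 0.5 else "-"))
        max_shift = 80
        prof = cross_correlation(tags, max_shift, chrom_sizes=sizes)
        plus = {c: np.zeros(L) for c, L in sizes.items()}
        minus = {c: np.zeros(L) for c, L in sizes.items()}
        for t in tags:
            (plus if t.strand == "+" else minus)[t.chrom][t.five_prime] += 1
        expected = cross_correlation_oracle(plus, minus, max_shift)
        assert np.allclose(prof.cc, expected, atol=1e-8)

    def test_strand_swap_mirrors_profile(self):
        # swapping strands is the same correlation read with negated shifts:
        # cc_swapped(d) computed directly must equal the oracle of the
        # swapped vectors (small instance sanity check of the convention)
        rng = np.random.default_rng(9)
        L = 2_000
        tags = []
        for x in rng.integers(30, L - 30, size=120):
            tags.append(_tag("chr1", int(x), "+" if rng.random() < 0.5 else "-"))
        swapped = []
        for t in tags:
            if t.strand == "+":
                swapped.append(_tag("chr1", t.five_prime, "-"))
            else:
                swapped.append(_tag("chr1", t.five_prime, "+"))
        prof = cross_correlation(swapped, 50, chrom_sizes={"chr1": L})
        plus = {"chr1": np.zeros(L)}
        minus = {"chr1": np.zeros(L)}
        for t in swapped:
            (plus if t.strand == "+" else minus)[t.chrom][t.five_prime] += 1
        expected = cross_correlation_oracle(plus, minus, 50)
        assert np.allclose(prof.cc, expected, atol=1e-8)

    def test_zero_variance_recorded_as_zero_with_warning(self):
        tags = [_tag("chr1", 100, "+"), _tag("chr1", 300, "+")]
        with pytest.warns(UserWarning):
            prof = cross_correlation(tags, 10, chrom_sizes={"chr1": 1_000})
        assert np.all(prof.cc == 0.0)


class TestNscRsc:
    def test_flat_profile_gives_nsc_one(self):
        prof = CrossCorrelationProfile(np.arange(101), np.full(101, 0.02))
        nsc, rsc = nsc_rsc(prof, read_len=36)
        assert nsc == 1.0
        assert rsc is None  # cc(read_len) == cc_min: undefined

    def test_peaked_profile(self):
        shifts = np.arange(301)
        cc = 0.01 + 0.04 * np.exp(-0.5 * ((shifts - 200) / 20.0) ** 2)
        cc[36] += 0.005  # weak read-length phantom
        prof = CrossCorrelationProfile(shifts, cc)
        nsc, rsc = nsc_rsc(prof, read_len=36)
        assert nsc > 1
        assert rsc is not None and rsc > 1


class TestSaturation:
    def _tags(self, n=2_000, seed=0):
        rng = np.random.default_rng(seed)
        return [
            _tag("chr1", int(x), "+")
            for x in rng.integers(100, 99_900, size=n)
        ]

    def test_full_fraction_is_exactly_one(self):
        curve = saturation_curve(
            self._tags(), fractions=[0.5, 1.0], chrom_sizes={"chr1": 100_000}
        )
        assert curve[-1] == (1.0, 1.0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(UsageError):
            saturation_curve(self._tags(), fractions=[0.0])
        with pytest.raises(UsageError):
            saturation_curve(self._tags(), fractions=[1.2])

    def test_deterministic_under_seed(self):
        tags = self._tags()
        c1 = saturation_curve(tags, seed=5, chrom_sizes={"chr1": 100_000})
        c2 = saturation_curve(tags, seed=5, chrom_sizes={"chr1": 100_000})
        assert c1 == c2
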