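# Methods

This note documents the models and procedures behind `peaklab`, the
parameter choices that matter, the design decisions that were genuinely
open, and what the synthetic-data generators do and do not emulate.

## Coordinates and the overlap rule

All coordinates are 0-based half-open `[start, end)` (BED native); the one
1-based-flavoured field, the narrowPeak summit column, is an offset from
`start` with `-1` meaning "summit unknown". Two intervals overlap iff they
share at least one base: `a.start < b.end and b.start < a.end`. Book-ended
intervals share zero bases and neither overlap nor merge. Every operation
in the package — Venn counting, bin labelling, merging, permutation
overlap counting — uses this single rule.

A peak's *anchor* is its summit when recorded, else the floor midpoint.
Distance computations default to the midpoint (the "center" convention of
TSS-distance profiles); `anchor="summit"` switches every distance-based
operation to summits where available.

## Venn counting under many-to-many overlap

"Peaks common to both sets" is ambiguous when one peak can overlap several:
per-set shared counts (`A_shared`, `B_shared`) need not agree, and neither
equals the number of shared loci. The package therefore reports three
numbers: `A_shared` and `B_shared` (peaks of one set touching ≥1 peak of
the other — these preserve the per-set percentages), and
`common_clusters`, the number of connected components of the interval-
overlap graph over A ∪ B containing members of both sets. For interval
graphs these components are exactly the maximal runs found by one sorted
sweep tracking the running maximum end, which is how they are computed;
a brute-force all-pairs + graph-components oracle confirms the equivalence
in the test suite. `common_clusters` is the number to quote as the
intersection of a two-set Venn figure.

## Fisher co-localization

The test needs a sampling universe; peak calls alone do not define one.
The genome is tiled into non-overlapping bins (last bin per chromosome
truncated) and each bin is labelled positive for a set iff it overlaps any
of the set's peaks by ≥1 bp, giving a 2×2 table over bins. The default bin
width is the **median peak length of the combined sets**, so the universe
scales with peak geometry instead of being an arbitrary constant; the
chosen width is echoed in every report and is configurable for sensitivity
checks. The alternative is one-sided ("greater"): the claim under test is
co-occupancy enrichment, not avoidance.

The p-value is the hypergeometric upper tail summed in log space
(`gammaln`-based log-pmf + `logsumexp`), and reports carry `log10 p`
alongside `p` so that extreme tables remain informative instead of
floor-ing at the smallest representable double. The implementation is
checked against exact integer arithmetic for every 2×2 table with total
≤ 60 at relative error < 1e-9.

The permutation companion preserves each A peak's chromosome and length
and redraws its start uniformly; `p_emp = (1 + #{null ≥ obs})/(1 + n_perm)`
with a seeded generator. No mappability masking is applied (none is
available for a synthetic genome); the null is documented rather than
hidden. Because the overlap count is discrete, empirical p-values are
superuniform with tie lumps; the calibration test uses a wide-range
statistic so the lumps are small against its tolerance.

## Gene assignment and TSS statistics

Single nearest gene by |distance from peak center to TSS|, unassigned
beyond 50 kb (both defaults configurable). Signed distances are
strand-aware: positive = downstream of the TSS in the gene's reading
direction. Equidistant TSSs resolve to the gene with the smaller start
coordinate, then smaller gene id — determinism matters more than the
choice itself. Curated per-gene regulatory-domain extensions (as used by
some annotation servers) are not implementable without the curation data
and are deliberately excluded; reports note this. Because several peaks
can share one nearest gene, reports carry both per-peak and unique-gene
counts.

The promoter window is ±1 kb of any TSS, counted on |distance|. The
feature classification is a simplified three-way scheme — promoter
(±1 kb), gene body (midpoint inside a gene span), intergenic — with no
exon/intron/UTR subdivision; reports label the scheme explicitly.

## Motif enrichment

PWMs are log2-odds matrices against a background base distribution
(default: the genome's own composition), with the conventional
Laplace-style pseudocount scheme (`pseudocount = 0.8`, distributed
proportionally to the background).

The hit threshold per motif is calibrated exactly: the null distribution
of a background w-mer's score is computed by dynamic programming over the
score matrix discretized to 1e-3 log-odds units, and the threshold is the
smallest value whose tail probability is ≤ `p_target` (default 1e-4 per
position). The DP is exact for the discretized matrix — the test suite
checks it against exhaustive 4^w enumeration — while window scanning uses
the raw float scores; the discrepancy is bounded by w·5e-4 log-odds units
and is irrelevant at enrichment scale. Windows are the anchor ±100 bp
(width 201), scanned on both strands; positions covering ambiguous IUPAC
bases score −∞.

Enrichment is presence/absence per window (a window with three sites
counts once), matching how such figures count "regions with the motif".
The background is 10× as many windows as peaks (large enough that the
error in the background rate is second-order), drawn uniformly from the
genome and rejection-sampled so the background GC histogram (0.05-wide
bins) matches the peak windows' — GC matching is what keeps base-
compositional confounding out of the binomial contrast. The test is the
one-sided binomial upper tail at the smoothed background rate
`p0 = (k_bg+1)/(n_bg+2)` (never exactly 0 or 1), computed in log space.
Raw p-values get the figure-style stars (`***` <1e-10, `**` <0.01,
`*` <0.1); Benjamini–Hochberg q-values are reported alongside for modern
practice. Background windows are genome-wide by default; a
promoter-restricted universe can be supplied explicitly.

## Library QC

* **SPOT**: fraction of tag 5′ ends inside caller-supplied peak regions.
  This uses the provided peaks as the signal regions rather than any
  particular peak-calling program's internal regions — self-contained, and
  documented as such.
* **PBC** (PBC1): N1/Nd over distinct (chrom, strand, 5′ end) positions.
* **Strand cross-correlation**: Pearson correlation between per-base
  + strand 5′-end counts and − strand counts shifted left by d, for
  d = 0..max_shift, concatenating per-chromosome overlap segments — shifts
  never cross chromosome boundaries. Counts are raw (not binarized); the
  per-shift inner products come from one FFT cross-correlation per
  chromosome and the marginal moments from prefix sums, so the profile is
  exact up to FFT round-off (verified against direct `corrcoef` on small
  instances). Zero-variance segments record correlation 0 with a warning.
  NSC = cc(argmax)/cc_min; RSC = (cc(argmax) − cc_min)/(cc(read_len) −
  cc_min), reported as missing when the denominator vanishes.
* **Saturation**: without-replacement subsamples at fractions 0.05..1.00
  (default grid), Pearson correlation of 10 kb-binned 5′ coverage against
  the full library. The fraction-1.0 point is the library against itself,
  exactly (1.0, 1.0).

## Synthetic data: what it emulates, what it does not

Generators are pure functions of their seed (NumPy PCG64 via
`default_rng`, no global state) and return truth records sufficient to
compute every downstream expectation.

* **Genome**: i.i.d. bases with per-region GC targets, strand-symmetric.
  The default world uses a 0.35→0.55 GC gradient per chromosome so GC
  matching is a real constraint. No repeats, no mappability structure, no
  dinucleotide composition — passing tests show the statistics behave
  correctly under their stated assumptions, not that real-genome
  confounders are handled.
* **Peak pairs**: an exact `round(overlap_frac · n_B)` of B peaks overlap
  a distinct A peak by ≥1 bp; everything else is mutually disjoint
  (slot-based or rejection placement). Venn truth is therefore exact, not
  statistical. Peak widths are uniform 200–400 bp, typical of
  point-source factors.
* **Genes / promoter geometry**: uniform TSSs, random strands, gene
  lengths 2–20 kb. A chosen share of a peak set is re-anchored to within
  ±500 bp of a TSS; the *remaining* peaks are additionally relocated out
  of every ±1 kb promoter window. Without that second step the measured
  promoter fraction would exceed the planted share by the random
  TSS-proximity rate (~3% at default density) and the truth record would
  not predict the measurement; with it, the planted share is the exact
  promoter fraction. Re-anchored peaks are kept mutually disjoint so
  overlap constructions against the final set remain exact.
* **Motif planting**: sites are sampled from the PFM's column
  distributions (not consensus), written at uniform offsets and strands
  into peak windows at `rate_peak` and into disjoint background windows at
  `rate_bg`. Planted-site detectability therefore depends on the motif's
  information content; the ≥99%-detection generator check uses a
  near-consensus motif, while enrichment-recovery tests use softer motifs
  and assert ranking and significance instead of perfect detection.
* **Tags**: a `signal_frac` share of tags are fragment ends around peak
  anchors (+ strand 5′ near anchor − frag_len/2, − strand near
  anchor + frag_len/2, uniform ±50 bp jitter) so cross-correlation peaks
  at the fragment length; the rest follow a strand-shared regional density
  (gamma-weighted 10 kb tiles) emulating the large-scale accessibility /
  mappability variation that keeps real cross-correlation profiles
  positive at every shift — under strictly uniform noise the profile
  minimum fluctuates around zero and NSC is undefined in practice.
  Pre-amplification 5′ positions are forced distinct, so PBC is governed
  purely by the final duplication step (each tag duplicated once with
  probability `dup_rate`): `pbc = (n − n_dup)/n` exactly, and `dup_rate=0`
  gives PBC 1.0 exactly. Real libraries also collide naturally at high
  depth; that regime is outside what the generator models.

Default world: 3 chromosomes × 2 Mb, two 1,000-peak sets with overlap
fraction 0.42, 300 genes with a 0.70 TSS-proximal share, one planted motif
(rate 0.6 in peaks, 0 in background) among 10 decoys, and 200k tags
(signal fraction 0.3, fragment 200 bp, read 36 bp, duplication 0.1). These
sizes keep every analysis interactive on one CPU while leaving the
statistics far from small-sample noise; the acceptance script runs the
full world in well under a minute.

## Numerical and degenerate-input policy

All tail probabilities (hypergeometric, binomial) are summed in log space
and reported with `log10 p`. Parsers reject anything they cannot represent
(no silent coercion), naming the offending line. Empty peak sets, empty
tag lists, zero-width bins, invalid fractions and rates raise usage errors
rather than producing NaNs. Ties are always broken deterministically
(documented per operation). Pipeline outputs contain no timestamps; a
rerun with the same config and seed is byte-identical.

## Known limitations

* The Fisher universe is a modelling choice; results should be read with
  the reported bin width (and, if in doubt, re-run across widths).
* The three-way feature scheme is coarser than exon-level annotators.
* GC matching controls composition at one scale (window GC in 0.05 bins);
  it does not match dinucleotide content or CpG islands.
* The permutation null has no mappability mask.
* NSC/RSC on very low-enrichment synthetic libraries can be unstable when
  the profile is nearly flat; the metrics are reported with the profile so
  the flatness is visible.
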