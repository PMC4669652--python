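# peaklab

Downstream analysis of ChIP-seq peak sets: everything a regulatory-genomics
study does *after* read mapping and peak calling, as a tested, reusable
Python library with a thin CLI.

ChIP-seq experiments for a DNA-associated protein end in a set of peaks —
scored genomic intervals of read enrichment. The questions that follow are
largely generic: do two factors' peak sets co-localize more than chance
allows? Are the peaks promoter-proximal? Which genes do they regulate?
Which known transcription-factor motifs are enriched in the bound sequence
relative to a matched background? And is the underlying library deep and
complex enough to trust any of it? `peaklab` implements that analysis layer:

* **Co-localization** — Venn counting of two peak sets under the standard
  "at least 1 bp overlap" rule (reported as per-set shared counts *and* as
  symmetric overlap clusters), a one-sided Fisher's exact test on a
  genome-bin contingency table with the hypergeometric tail summed in log
  space, a seeded permutation null, Jaccard similarity, and summit-anchored
  heat-map matrices.
* **TSS / promoter profiling** — signed strand-aware distances from peak
  centers to the nearest transcription start site, promoter fractions
  (±1 kb by default), TSS-distance histograms, and a simplified
  promoter / gene-body / intergenic classification.
* **Gene assignment** — GREAT-style single nearest gene within a maximum
  extension (50 kb by default), with deterministic tie-breaking.
* **Motif enrichment** — known motifs (JASPAR PFM text) scanned in summit
  ±100 bp windows on both strands, with a per-motif hit threshold calibrated
  *exactly* by dynamic programming over the null score distribution, a
  GC-matched random background (rejection sampling against the peak GC
  histogram in 0.05 bins), a one-sided binomial test on the smoothed
  background rate, Benjamini–Hochberg q-values, and figure-style star tiers
  (`***` p<1e-10, `**` p<0.01, `*` p<0.1).
* **Library QC** — SPOT (signal portion of tags), PBC (PCR bottleneck
  coefficient, N1/Nd), strand cross-correlation with NSC/RSC, and a
  subsampling saturation curve over 10 kb coverage bins.
* **Synthetic data** — generators for every input (GC-profiled genome,
  peak pairs with exact constructed overlap counts, genes with exact
  TSS-proximal peak fractions, planted motif sites, tag libraries with known
  fragment length / signal fraction / duplication rate), each returning a
  ground-truth record. The whole pipeline is exercisable with no downloads.

The key statistics in standard notation: two intervals overlap iff
`a.start < b.end and b.start < a.end` (0-based half-open coordinates
throughout). The Fisher table counts genome bins positive for both sets /
one / the other / neither, and `p = P(X >= a)` for
`X ~ Hypergeom(N, a+b, a+c)`. The motif test is
`p = P(X >= k_peak)` for `X ~ Binomial(n_peak, p0)` with
`p0 = (k_bg + 1)/(n_bg + 2)`. QC follows the ENCODE definitions:
`PBC = N1/Nd`, `NSC = cc(argmax)/cc_min`,
`RSC = (cc(argmax) − cc_min)/(cc(read_len) − cc_min)`.

## Worked example

```python
from peaklab.synthetic import generate_world
from peaklab.coloc import colocalize
from peaklab.genes import promoter_fraction
from peaklab.motifs import enrich_motif_set

world = generate_world(seed=1)   # 3 chrom x 2 Mb, 2 x 1,000 peaks, 300 genes

report = colocalize(world.peaks_A, world.peaks_B, world.chrom_sizes,
                    n_perm=200, seed=1)
v = report.venn
print(f"peaks: {v.n_A} (A) vs {v.n_B} (B); "
      f"{v.B_shared} B peaks ({v.pct_B_shared:.1f}%) overlap A by >=1 bp")
print(f"Fisher's exact (genome bins of {report.bin_width} bp): "
      f"log10 p = {report.log10_p_fisher:.1f}; "
      f"permutation p = {report.p_permutation:.4f}")

pf = promoter_fraction(world.peaks_A, world.genes)
print(f"promoter fraction (peak center within 1 kb of a TSS): {pf:.1f}%")

records = enrich_motif_set(world.peaks_A, world.genome,
                           [world.motif] + world.decoys, seed=1)
r = records[0]
print(f"top motif: {r.motif_id}  peak {r.pct_peak:.1f}% vs bg {r.pct_bg:.1f}%  "
      f"p = {r.p_binomial:.2e} {r.stars}")
```

prints

```
peaks: 1000 (A) vs 1000 (B); 420 B peaks (42.0%) overlap A by >=1 bp
Fisher's exact (genome bins of 297 bp): log10 p = -264.7; permutation p = 0.0050
promoter fraction (peak center within 1 kb of a TSS): 70.0%
top motif: PLANTED  peak 28.9% vs bg 5.8%  p = 5.13e-116 ***
```

The world was built with a 42% constructed overlap fraction and a 70%
TSS-proximal peak share, so the first and third lines read back the
generator truth exactly; the Fisher and binomial lines show how decisively
the tests detect that structure at this scale.

## Command line

```bash
peaklab simulate --seed 3 --out world/          # write a synthetic study
peaklab venn world/peaks_A.narrowPeak world/peaks_B.narrowPeak
peaklab coloc A.narrowPeak B.narrowPeak genome.sizes --n-perm 200
peaklab annotate peaks.narrowPeak genes.bed
peaklab motif peaks.narrowPeak genome.fa motifs.jaspar
peaklab qc tags.tagAlign peaks.narrowPeak genome.sizes
peaklab run --config run.yaml                   # the full bundle
```

`run` writes TSV/JSON reports plus a provenance block (seed, parameters,
version); reruns with the same config are byte-identical. Exit codes:
0 ok, 2 config error, 3 data error.

Supported formats: BED3/BED6/narrowPeak, stranded gene BED, tagAlign,
FASTA + chromosome-sizes table, JASPAR PFM text, bedGraph output.

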