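"""Genomic interval primitives and peak-set arithmetic.

All coordinates are 0-based, half-open ``[start, end)`` — the native BED
convention. Any 1-based input is converted at the parse boundary, never here.

The central rule throughout the package is the "at least 1 bp overlap"
criterion: two intervals on the same chromosome overlap iff
``a.start < b.end and b.start < a.end``. Book-ended intervals (``a.end ==
b.start``) share zero bases and do *not* overlap; :func:`merge` keeps them
separate for the same reason.

Venn counting between two peak sets is reported three ways, because "peaks
common to both" is ambiguous under many-to-many overlap:

* ``A_shared`` / ``B_shared`` — peaks of one set touching >=1 peak of the other;
* ``common_clusters`` — connected components of the overlap graph over the
  combined sets that contain members of both. This symmetric count is the one
  to quote as the intersection of a two-set Venn diagram.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import UsageError

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "GeneModel",
    "GeneIndex",
    "VennCounts",
    "overlaps",
    "venn_counts",
    "merge",
    "tss_distance",
    "classify_feature",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise UsageError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise UsageError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """A scored ChIP-seq peak; optionally carries a summit offset.

    ``summit_offset`` follows the narrowPeak convention: offset of the point
    of maximal signal from ``start``, with ``-1`` meaning "summit unknown".
    ``anchor`` is the summit when known, else the interval midpoint.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    signal: float = 0.0
    pvalue: float = -1.0
    qvalue: float = -1.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise UsageError(
                f"peak {self.name!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.summit_offset < -1:
            raise UsageError("summit_offset must be >= -1")
        if self.summit_offset >= self.end - self.start:
            raise UsageError(
                f"peak {self.name!r}: summit_offset {self.summit_offset} "
                f"outside interval of length {self.end - self.start}"
            )

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def anchor(self) -> int:
        """Summit position if known, else the interval midpoint."""
        if self.summit_offset >= 0:
            return self.start + self.summit_offset
        return self.midpoint

    def moved_to(self, start: int) -> "Peak":
        """Copy of this peak translated to a new start (same length)."""
        return replace(self, start=start, end=start + (self.end - self.start))


@dataclass(frozen=True)
class PeakSet:
    """An ordered, normalized collection of peaks from one genome.

    Normalization (applied on construction) sorts by ``(chrom, start, end)``;
    zero-length members are impossible by :class:`Peak` invariants.
    """

    label: str
    peaks: tuple[Peak, ...]
    genome_id: str = ""

    def __init__(self, label: str, peaks: Iterable[Peak], genome_id: str = ""):
        ordered = tuple(
            sorted(peaks, key=lambda p: (p.chrom, p.start, p.end, p.name))
        )
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "peaks", ordered)
        object.__setattr__(self, "genome_id", genome_id)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene span; the TSS is the 5' end on the coding strand."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise UsageError(f"gene {self.gene_id!r}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise UsageError(
                f"gene {self.gene_id!r}: require 0 <= start < end"
            )

    @property
    def tss(self) -> int:
        """0-based TSS: ``start`` on +, ``end - 1`` on -."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class VennCounts:
    """Two-set peak overlap bookkeeping under the >=1 bp rule."""

    n_A: int
    n_B: int
    A_shared: int
    B_shared: int
    common_clusters: int

    @property
    def only_A(self) -> int:
        return self.n_A - self.A_shared

    @property
    def only_B(self) -> int:
        return self.n_B - self.B_shared

    @property
    def pct_A_shared(self) -> float:
        return 100.0 * self.A_shared / self.n_A if self.n_A else 0.0

    @property
    def pct_B_shared(self) -> float:
        return 100.0 * self.B_shared / self.n_B if self.n_B else 0.0


def overlaps(a: GenomicInterval | Peak, b: GenomicInterval | Peak) -> bool:
    """>=1 bp overlap: same chromosome and strictly intersecting half-open spans."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


class _ChromIndex:
    """Start-sorted intervals of one chromosome with a prefix-max of ends.

    Supports O(log n) "does [s, e) overlap anything here?" queries: among
    intervals with start < e, overlap exists iff the largest end exceeds s.
    """

    def __init__(self, spans: Sequence[tuple[int, int]]):
        spans = sorted(spans)
        self.starts = np.fromiter((s for s, _ in spans), dtype=np.int64, count=len(spans))
        ends = np.fromiter((e for _, e in spans), dtype=np.int64, count=len(spans))
        self.prefix_max_end = np.maximum.accumulate(ends) if len(spans) else ends

    def any_overlap(self, start: int, end: int) -> bool:
        idx = int(np.searchsorted(self.starts, end, side="left"))
        return idx > 0 and int(self.prefix_max_end[idx - 1]) > start

    def any_overlap_many(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.starts, ends, side="left")
        hit = idx > 0
        hit[hit] = self.prefix_max_end[idx[hit] - 1] > starts[hit]
        return hit


def _build_index(peaks: Iterable[Peak]) -> dict[str, _ChromIndex]:
    per: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        per.setdefault(p.chrom, []).append((p.start, p.end))
    return {c: _ChromIndex(v) for c, v in per.items()}


def shared_mask(query: Sequence[Peak], target: Iterable[Peak]) -> np.ndarray:
    """Boolean per query peak: overlaps >=1 target peak (the >=1 bp rule)."""
    index = _build_index(target)
    out = np.zeros(len(query), dtype=bool)
    per: dict[str, list[int]] = {}
    for i, p in enumerate(query):
        per.setdefault(p.chrom, []).append(i)
    for chrom, idxs in per.items():
        ci = index.get(chrom)
        if ci is None:
            continue
        starts = np.array([query[i].start for i in idxs], dtype=np.int64)
        ends = np.array([query[i].end for i in idxs], dtype=np.int64)
        out[np.array(idxs)] = ci.any_overlap_many(starts, ends)
    return out


def venn_counts(A: PeakSet, B: PeakSet) -> VennCounts:
    """Two-set Venn bookkeeping by linear sweep over the sorted union.

    ``common_clusters`` counts connected components of the interval-overlap
    graph over A u B that contain peaks from both sets; for interval graphs
    the components are exactly the maximal runs found by a single sweep
    tracking the running maximum end.
    """
    if A.genome_id != B.genome_id:
        raise UsageError(
            f"peak sets from different genomes: {A.genome_id!r} vs {B.genome_id!r}"
        )
    a_shared = int(shared_mask(A.peaks, B.peaks).sum())
    b_shared = int(shared_mask(B.peaks, A.peaks).sum())

    events = sorted(
        [(p.chrom, p.start, p.end, 0) for p in A.peaks]
        + [(p.chrom, p.start, p.end, 1) for p in B.peaks]
    )
    clusters = 0
    cur_chrom: str | None = None
    cur_end = -1
    seen = [False, False]
    for chrom, start, end, which in events:
        if chrom != cur_chrom or start >= cur_end:
            if all(seen):
                clusters += 1
            cur_chrom, cur_end, seen = chrom, end, [False, False]
        else:
            cur_end = max(cur_end, end)
        seen[which] = True
    if all(seen):
        clusters += 1
    return VennCounts(len(A), len(B), a_shared, b_shared, clusters)


def merge(intervals: Iterable[GenomicInterval | Peak]) -> tuple[GenomicInterval, ...]:
    """Maximal disjoint intervals covering the input.

    Book-ended intervals stay separate: merging requires >=1 shared base,
    consistent with the overlap rule used everywhere else.
    """
    items = sorted((iv.chrom, iv.start, iv.end) for iv in intervals)
    out: list[GenomicInterval] = []
    for chrom, start, end in items:
        if out and out[-1].chrom == chrom and start < out[-1].end:
            if end > out[-1].end:
                out[-1] = GenomicInterval(chrom, out[-1].start, end)
        else:
            out.append(GenomicInterval(chrom, start, end))
    return tuple(out)


def total_bases(intervals: Iterable[GenomicInterval | Peak]) -> int:
    """Number of distinct bases covered by the input."""
    return sum(len(iv) for iv in merge(intervals))


def tss_distance(peak: Peak, gene: GeneModel, anchor: str = "midpoint") -> int:
    """Signed distance from a peak's center to a gene's TSS.

    Positive = downstream of the TSS in the gene's reading direction,
    negative = upstream. ``anchor`` is ``"midpoint"`` (default, the peak
    center) or ``"summit"`` (summit when known, else midpoint).
    """
    if peak.chrom != gene.chrom:
        raise UsageError(
            f"peak on {peak.chrom} vs gene on {gene.chrom}: "
            "TSS distance is only defined within one chromosome"
        )
    pos = peak.anchor if anchor == "summit" else peak.midpoint
    d = pos - gene.tss
    return d if gene.strand == "+" else -d


class GeneIndex:
    """Per-chromosome gene index for nearest-TSS and span-containment queries.

    Nearest-TSS ties (two TSSs equidistant from the query) are broken toward
    the gene with the smaller start coordinate, then smaller gene_id, so
    results are deterministic.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: tuple[GeneModel, ...] = tuple(genes)
        self._tss: dict[str, np.ndarray] = {}
        self._tss_order: dict[str, list[int]] = {}
        self._spans: dict[str, _ChromIndex] = {}
        per: dict[str, list[int]] = {}
        for i, g in enumerate(self.genes):
            per.setdefault(g.chrom, []).append(i)
        for chrom, idxs in per.items():
            order = sorted(idxs, key=lambda i: (self.genes[i].tss,
                                                self.genes[i].start,
                                                self.genes[i].gene_id))
            self._tss_order[chrom] = order
            self._tss[chrom] = np.array(
                [self.genes[i].tss for i in order], dtype=np.int64
            )
            self._spans[chrom] = _ChromIndex(
                [(self.genes[i].start, self.genes[i].end) for i in idxs]
            )

    def __len__(self) -> int:
        return len(self.genes)

    def nearest_tss(self, chrom: str, pos: int) -> tuple[GeneModel, int] | None:
        """Gene with TSS closest to ``pos`` (by absolute distance), or None.

        Returns ``(gene, |pos - tss|)``; the caller derives the signed,
        strand-aware distance via :func:`tss_distance` if needed.
        """
        tss = self._tss.get(chrom)
        if tss is None or len(tss) == 0:
            return None
        j = int(np.searchsorted(tss, pos))
        best: tuple[int, int, str, int] | None = None  # (|d|, start, id, idx)
        for k in (j - 1, j):
            if 0 <= k < len(tss):
                d = abs(pos - int(tss[k]))
                # sweep outward over equal-TSS runs and the mirror-image side
                for kk in self._tie_candidates(chrom, pos, d):
                    g = self.genes[self._tss_order[chrom][kk]]
                    key = (d, g.start, g.gene_id, kk)
                    if best is None or key < best:
                        best = key
        if best is None:
            return None
        gene = self.genes[self._tss_order[chrom][best[3]]]
        return gene, best[0]

    def _tie_candidates(self, chrom: str, pos: int, d: int) -> list[int]:
        """Indices (into the sorted-TSS order) of all genes at distance d."""
        tss = self._tss[chrom]
        out: list[int] = []
        for target in {pos - d, pos + d}:
            lo = int(np.searchsorted(tss, target, side="left"))
            hi = int(np.searchsorted(tss, target, side="right"))
            out.extend(range(lo, hi))
        return out

    def nearest_tss_distance(self, chrom: str, pos: int) -> int | None:
        """Absolute distance to the nearest TSS, or None if no gene on chrom."""
        hit = self.nearest_tss(chrom, pos)
        return None if hit is None else hit[1]

    def signed_nearest_distance(self, chrom: str, pos: int) -> int | None:
        """Signed strand-aware distance to the nearest TSS (None if no gene)."""
        hit = self.nearest_tss(chrom, pos)
        if hit is None:
            return None
        gene, _ = hit
        d = pos - gene.tss
        return d if gene.strand == "+" else -d

    def covers(self, chrom: str, pos: int) -> bool:
        """True iff ``pos`` lies inside some gene span on ``chrom``."""
        span = self._spans.get(chrom)
        return span is not None and span.any_overlap(pos, pos + 1)


def classify_feature(
    peak: Peak,
    genes: GeneIndex | Iterable[GeneModel],
    promoter_window: int = 1000,
) -> str:
    """Assign a peak to ``promoter`` / ``gene_body`` / ``intergenic``.

    Promoter means the peak midpoint lies within ``promoter_window`` bp of
    the nearest TSS (either side); gene_body means the midpoint falls inside
    some gene span; everything else is intergenic. A simplified three-way
    scheme (no exon/intron/UTR subdivision) — reports flag it as such.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    pos = peak.midpoint
    d = index.nearest_tss_distance(peak.chrom, pos)
    if d is not None and d <= promoter_window:
        return "promoter"
    if index.covers(peak.chrom, pos):
        return "gene_body"
    return "intergenic"
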