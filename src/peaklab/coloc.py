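"""Co-localization statistics for two peak sets.

The headline statistic is a one-sided Fisher's exact test on a genome-bin
contingency table: the genome is tiled into non-overlapping bins (last bin
per chromosome truncated) and each bin is labelled positive for a set iff it
overlaps >=1 of the set's peaks by >=1 bp. Bins are the sampling units; the
default bin width is the median peak length of the combined sets, so the
universe scales with the data rather than being an arbitrary constant. The
hypergeometric tail is summed in log space so extreme tables report a finite
log10 p instead of a floating-point floor.

A seeded permutation test (peaks of A re-placed uniformly per chromosome,
lengths preserved) provides a model-free companion null, and a summit-
anchored heat-map matrix gives the per-peak view of the shared signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import UsageError
from .intervals import (
    GenomicInterval,
    Peak,
    PeakSet,
    VennCounts,
    merge,
    shared_mask,
    venn_counts,
)
from .qc import TagRecord

__all__ = [
    "ContingencyTable2x2",
    "OverlapReport",
    "HeatmapMatrix",
    "fisher_colocalization",
    "fisher_pvalue",
    "permutation_overlap_test",
    "heatmap_matrix",
    "jaccard",
    "colocalize",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Genome-bin contingency table: both / A only / B only / neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise UsageError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def hypergeom_tail_logp(a: int, K: int, n: int, N: int) -> float:
    """log P(X >= a) for X ~ Hypergeometric(N, K, n), summed in log space."""
    k_lo = max(0, K + n - N)
    k_hi = min(K, n)
    if a <= k_lo:
        return 0.0
    if a > k_hi:
        return float("-inf")
    ks = np.arange(a, k_hi + 1)
    log_pmf = (
        gammaln(K + 1) - gammaln(ks + 1) - gammaln(K - ks + 1)
        + gammaln(N - K + 1) - gammaln(n - ks + 1) - gammaln(N - K - n + ks + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(logsumexp(log_pmf))


def fisher_pvalue(table: ContingencyTable2x2) -> tuple[float, float]:
    """One-sided (greater) Fisher's exact p for the table.

    Returns ``(p, log10_p)``; ``log10_p`` stays informative when ``p``
    underflows.
    """
    N = table.total
    if N == 0:
        raise UsageError("empty contingency table")
    logp = hypergeom_tail_logp(table.a, table.a + table.b, table.a + table.c, N)
    return float(min(1.0, np.exp(logp))), logp / np.log(10.0)


def _bin_flags(
    peaks: Iterable[Peak], chrom: str, n_bins: int, bin_width: int
) -> np.ndarray:
    """Boolean per bin: >=1 bp overlap with any peak on this chromosome."""
    flags = np.zeros(n_bins, dtype=bool)
    for p in peaks:
        if p.chrom != chrom:
            continue
        first = p.start // bin_width
        last = (p.end - 1) // bin_width
        flags[first : min(last, n_bins - 1) + 1] = True
    return flags


def default_bin_width(A: PeakSet, B: PeakSet) -> int:
    """Median peak length of the combined sets (>= 1)."""
    lengths = [p.end - p.start for p in A] + [p.end - p.start for p in B]
    if not lengths:
        raise UsageError("cannot choose a bin width from two empty peak sets")
    return max(1, int(np.median(lengths)))


def fisher_colocalization(
    A: PeakSet,
    B: PeakSet,
    genome_sizes: dict[str, int],
    bin_width: int | None = None,
) -> tuple[ContingencyTable2x2, float]:
    """Fisher's exact co-localization test over genome bins.

    Tiles every chromosome into ``bin_width`` bins (default: median combined
    peak length), labels bins positive per set under the >=1 bp rule, and
    tests the 2x2 table with the one-sided "greater" alternative.
    """
    if not genome_sizes:
        raise UsageError("genome_sizes must not be empty")
    if bin_width is None:
        bin_width = default_bin_width(A, B)
    if bin_width < 1:
        raise UsageError("bin_width must be >= 1")
    a = b = c = d = 0
    a_by = A.by_chrom()
    b_by = B.by_chrom()
    for chrom, size in genome_sizes.items():
        n_bins = (size + bin_width - 1) // bin_width
        fa = _bin_flags(a_by.get(chrom, ()), chrom, n_bins, bin_width)
        fb = _bin_flags(b_by.get(chrom, ()), chrom, n_bins, bin_width)
        a += int((fa & fb).sum())
        b += int((fa & ~fb).sum())
        c += int((~fa & fb).sum())
        d += int((~fa & ~fb).sum())
    table = ContingencyTable2x2(a, b, c, d)
    p, _ = fisher_pvalue(table)
    return table, p


@dataclass(frozen=True)
class PermutationResult:
    observed_shared: int
    null_mean: float
    null_sd: float
    p_emp: float
    n_permutations: int
    seed: int


def permutation_overlap_test(
    A: PeakSet,
    B: PeakSet,
    genome_sizes: dict[str, int],
    n_perm: int,
    seed: int = 0,
) -> PermutationResult:
    """Empirical overlap null: A's peaks re-placed uniformly per chromosome.

    Each permutation keeps every A peak on its own chromosome with its own
    length, drawing a new start uniformly. The statistic is the number of A
    peaks overlapping >=1 B peak; ``p_emp = (1 + #{null >= obs}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise UsageError("n_perm must be >= 1")
    for p in A:
        if p.chrom not in genome_sizes:
            raise UsageError(f"peak chromosome {p.chrom!r} not in genome_sizes")
        if (p.end - p.start) > genome_sizes[p.chrom]:
            raise UsageError(
                f"peak {p.name!r} longer than chromosome {p.chrom}"
            )
    observed = int(shared_mask(A.peaks, B.peaks).sum())

    # per-chromosome sorted B index reused across permutations
    b_by = B.by_chrom()
    b_index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, items in b_by.items():
        spans = sorted((p.start, p.end) for p in items)
        starts = np.array([s for s, _ in spans], dtype=np.int64)
        ends = np.maximum.accumulate(np.array([e for _, e in spans], dtype=np.int64))
        b_index[chrom] = (starts, ends)

    a_chrom = [p.chrom for p in A]
    a_len = np.array([p.end - p.start for p in A], dtype=np.int64)
    room = np.array(
        [genome_sizes[c] - l + 1 for c, l in zip(a_chrom, a_len)], dtype=np.int64
    )
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        new_start = (rng.random(len(A)) * room).astype(np.int64)
        new_end = new_start + a_len
        hits = 0
        for j, chrom in enumerate(a_chrom):
            idx = b_index.get(chrom)
            if idx is None:
                continue
            starts, prefix_max_end = idx
            k = int(np.searchsorted(starts, new_end[j], side="left"))
            if k > 0 and prefix_max_end[k - 1] > new_start[j]:
                hits += 1
        null[i] = hits
    p_emp = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return PermutationResult(
        observed_shared=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=0)),
        p_emp=p_emp,
        n_permutations=n_perm,
        seed=seed,
    )


@dataclass(frozen=True)
class HeatmapMatrix:
    """Per-anchor coverage density across +/-flank, rows sorted by total."""

    values: np.ndarray          # (n_anchors, n_bins), row-reordered
    row_order: np.ndarray       # original anchor indices, descending row sum
    anchor_names: tuple[str, ...]
    flank: int
    n_bins: int


def heatmap_matrix(
    anchors: PeakSet,
    signal: PeakSet | Sequence[TagRecord],
    flank: int,
    n_bins: int,
) -> HeatmapMatrix:
    """Signal coverage in ``n_bins`` bins across each anchor's +/-flank window.

    The window is ``[anchor - flank, anchor + flank)`` centred on the summit
    (midpoint when no summit is recorded). Bin values are mean per-base
    coverage of the signal intervals; windows running past a chromosome edge
    are zero-padded. Rows are ordered by descending total.
    """
    if flank <= 0:
        raise UsageError("flank must be > 0")
    if n_bins < 1:
        raise UsageError("n_bins must be >= 1")
    if isinstance(signal, PeakSet):
        sig_items: list[tuple[str, int, int]] = [
            (p.chrom, p.start, p.end) for p in signal
        ]
    else:
        sig_items = [(t.chrom, t.start, t.end) for t in signal]

    # coverage arrays only over the span each chromosome actually needs
    need: dict[str, int] = {}
    for p in anchors:
        need[p.chrom] = max(need.get(p.chrom, 0), p.anchor + flank)
    for chrom, s, e in sig_items:
        if chrom in need:
            need[chrom] = max(need[chrom], e)
    cov: dict[str, np.ndarray] = {c: np.zeros(L + 1) for c, L in need.items()}
    for chrom, s, e in sig_items:
        arr = cov.get(chrom)
        if arr is None:
            continue
        arr[min(s, len(arr) - 1)] += 1
        arr[min(e, len(arr) - 1)] -= 1
    cov = {c: np.cumsum(arr)[:-1] for c, arr in cov.items()}

    width = 2 * flank
    edges = np.floor(np.arange(n_bins + 1) * width / n_bins).astype(int)
    values = np.zeros((len(anchors), n_bins))
    for i, p in enumerate(anchors):
        lo = p.anchor - flank
        window = np.zeros(width)
        arr = cov[p.chrom]
        src_lo, src_hi = max(0, lo), min(len(arr), lo + width)
        if src_hi > src_lo:
            window[src_lo - lo : src_hi - lo] = arr[src_lo:src_hi]
        for k in range(n_bins):
            seg = window[edges[k] : edges[k + 1]]
            values[i, k] = seg.mean() if len(seg) else 0.0
    order = np.argsort(-values.sum(axis=1), kind="stable")
    return HeatmapMatrix(
        values=values[order],
        row_order=order,
        anchor_names=tuple(anchors[int(i)].name for i in order),
        flank=flank,
        n_bins=n_bins,
    )


def jaccard(A: PeakSet, B: PeakSet) -> float:
    """Shared base pairs / union base pairs of the two merged sets."""
    ma = merge(A)
    mb = merge(B)
    union = sum(len(iv) for iv in merge(list(ma) + list(mb)))
    if union == 0:
        return 0.0
    inter = 0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in mb:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for iv in ma:
        for jv in by_chrom.get(iv.chrom, ()):
            lo = max(iv.start, jv.start)
            hi = min(iv.end, jv.end)
            if hi > lo:
                inter += hi - lo
    return inter / union


@dataclass(frozen=True)
class OverlapReport:
    venn: VennCounts
    pct_A_shared: float
    pct_B_shared: float
    jaccard: float
    table: ContingencyTable2x2
    bin_width: int
    p_fisher: float
    log10_p_fisher: float
    p_permutation: float | None
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        v = self.venn
        return {
            "n_A": v.n_A,
            "n_B": v.n_B,
            "A_shared": v.A_shared,
            "B_shared": v.B_shared,
            "only_A": v.only_A,
            "only_B": v.only_B,
            "common_clusters": v.common_clusters,
            "pct_A_shared": self.pct_A_shared,
            "pct_B_shared": self.pct_B_shared,
            "jaccard": self.jaccard,
            "contingency": {
                "a": self.table.a, "b": self.table.b,
                "c": self.table.c, "d": self.table.d,
            },
            "bin_width": self.bin_width,
            "p_fisher": self.p_fisher,
            "log10_p_fisher": self.log10_p_fisher,
            "p_permutation": self.p_permutation,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def colocalize(
    A: PeakSet,
    B: PeakSet,
    genome_sizes: dict[str, int],
    bin_width: int | None = None,
    n_perm: int = 0,
    seed: int = 0,
) -> OverlapReport:
    """Full co-localization report: Venn counts, Jaccard, Fisher table and p,
    and (when ``n_perm > 0``) the permutation companion p."""
    v = venn_counts(A, B)
    if bin_width is None:
        bin_width = default_bin_width(A, B)
    table, p = fisher_colocalization(A, B, genome_sizes, bin_width)
    _, log10p = fisher_pvalue(table)
    p_perm = None
    if n_perm > 0:
        p_perm = permutation_overlap_test(A, B, genome_sizes, n_perm, seed).p_emp
    return OverlapReport(
        venn=v,
        pct_A_shared=v.pct_A_shared,
        pct_B_shared=v.pct_B_shared,
        jaccard=jaccard(A, B),
        table=table,
        bin_width=bin_width,
        p_fisher=p,
        log10_p_fisher=log10p,
        p_permutation=p_perm,
        n_permutations=n_perm,
        seed=seed,
    )
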