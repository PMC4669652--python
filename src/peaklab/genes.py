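"""Nearest-gene association and TSS/promoter statistics.

Follows the GREAT-style "single nearest gene" rule: a peak is associated
with the gene whose TSS is closest to the peak's center, provided that
distance does not exceed the maximum extension (50 kb by default); beyond
that the peak is left unassigned. Distances are signed and strand-aware
(negative = upstream of the gene). The peak "center" is the interval
midpoint by default, or the recorded summit via ``anchor="summit"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UsageError
from .intervals import GeneIndex, GeneModel, Peak, PeakSet

__all__ = [
    "GeneAssignment",
    "assign_nearest_gene",
    "assign_all",
    "promoter_fraction",
    "tss_histogram",
    "DEFAULT_TSS_BIN_EDGES",
]

MAX_EXTENSION_DEFAULT = 50_000
PROMOTER_WINDOW_DEFAULT = 1_000

#: Mirrors the conventional TSS-distance profile: +/- 1 kb / 5 kb / 10 kb /
#: 50 kb with open-ended outer bins.
DEFAULT_TSS_BIN_EDGES = (
    -50_000, -10_000, -5_000, -1_000, 0, 1_000, 5_000, 10_000, 50_000,
)


@dataclass(frozen=True)
class GeneAssignment:
    peak_name: str
    gene_id: str | None
    distance: int | None  # signed, strand-aware; None iff unassigned
    within_50kb: bool

    def __post_init__(self) -> None:
        if (self.gene_id is None) != (self.distance is None):
            raise UsageError("gene_id and distance must be both set or both None")


def _anchor_pos(peak: Peak, anchor: str) -> int:
    if anchor == "summit":
        return peak.anchor
    if anchor == "midpoint":
        return peak.midpoint
    raise UsageError(f"anchor must be 'midpoint' or 'summit', got {anchor!r}")


def assign_nearest_gene(
    peak: Peak,
    genes: GeneIndex | Iterable[GeneModel],
    max_extension: int = MAX_EXTENSION_DEFAULT,
    anchor: str = "midpoint",
) -> GeneAssignment:
    """Single-nearest-gene assignment within ``max_extension`` bp of the TSS.

    Equidistant TSSs resolve deterministically to the gene with the smaller
    start coordinate (then smaller gene_id).
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    pos = _anchor_pos(peak, anchor)
    hit = index.nearest_tss(peak.chrom, pos)
    if hit is None or hit[1] > max_extension:
        return GeneAssignment(peak.name, None, None, False)
    gene, _ = hit
    d = pos - gene.tss
    signed = d if gene.strand == "+" else -d
    return GeneAssignment(peak.name, gene.gene_id, signed, True)


def assign_all(
    peaks: PeakSet,
    genes: GeneIndex | Iterable[GeneModel],
    max_extension: int = MAX_EXTENSION_DEFAULT,
    anchor: str = "midpoint",
) -> list[GeneAssignment]:
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [assign_nearest_gene(p, index, max_extension, anchor) for p in peaks]


def assignments_frame(assignments: Sequence[GeneAssignment]) -> pd.DataFrame:
    """Tabular view (peak, gene, distance, within_50kb) for TSV export."""
    return pd.DataFrame(
        {
            "peak": [a.peak_name for a in assignments],
            "gene": [a.gene_id if a.gene_id is not None else "." for a in assignments],
            "distance": [a.distance if a.distance is not None else "" for a in assignments],
            "within_50kb": [int(a.within_50kb) for a in assignments],
        }
    )


def unique_gene_count(assignments: Sequence[GeneAssignment]) -> int:
    """Distinct genes hit by >=1 peak (the per-gene companion to per-peak
    counts, since several peaks may share one nearest gene)."""
    return len({a.gene_id for a in assignments if a.gene_id is not None})


def promoter_fraction(
    peaks: PeakSet,
    genes: GeneIndex | Iterable[GeneModel],
    window: int = PROMOTER_WINDOW_DEFAULT,
    anchor: str = "midpoint",
) -> float:
    """Percentage of peaks whose center lies within ``window`` bp of any TSS."""
    if len(peaks) == 0:
        raise UsageError("promoter_fraction requires a non-empty peak set")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    hits = 0
    for p in peaks:
        d = index.nearest_tss_distance(p.chrom, _anchor_pos(p, anchor))
        if d is not None and d <= window:
            hits += 1
    return 100.0 * hits / len(peaks)


def tss_histogram(
    peaks: PeakSet,
    genes: GeneIndex | Iterable[GeneModel],
    bin_edges: Sequence[int] = DEFAULT_TSS_BIN_EDGES,
    anchor: str = "midpoint",
) -> pd.DataFrame:
    """Histogram of signed nearest-TSS distances.

    Bins are ``(-inf, e0), [e0, e1), ..., [e_last, inf)``, so out-of-range
    mass lands in the open end bins and counts always sum to the number of
    peaks. Peaks on chromosomes without genes are counted in an ``unplaced``
    row (distance undefined).
    """
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise UsageError("bin_edges must be strictly increasing")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    dists = []
    unplaced = 0
    for p in peaks:
        d = index.signed_nearest_distance(p.chrom, _anchor_pos(p, anchor))
        if d is None:
            unplaced += 1
        else:
            dists.append(d)
    full_edges = np.array([-np.inf] + edges + [np.inf])
    counts, _ = np.histogram(dists, bins=full_edges)
    labels = (
        [f"<{edges[0]}"]
        + [f"[{a},{b})" for a, b in zip(edges, edges[1:])]
        + [f">={edges[-1]}"]
    )
    frame = pd.DataFrame({"bin": labels, "count": counts})
    if unplaced:
        frame = pd.concat(
            [frame, pd.DataFrame({"bin": ["unplaced"], "count": [unplaced]})],
            ignore_index=True,
        )
    return frame
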