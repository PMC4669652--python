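"""Synthetic-data generators with exact ground truth.

Every input the analyses consume can be generated here with known truth, so
the whole pipeline is exercisable without any download:

* a genome of i.i.d. bases with region-specific GC targets (GC gradients are
  what makes the GC-matched background sampler non-trivial);
* a pair of peak sets with an exact, constructed number of >=1 bp overlaps;
* genes with uniform TSSs and a peak set re-anchored so an exact share of
  peaks is TSS-proximal;
* motif sites planted into peak and background windows at known rates;
* tag libraries with known fragment length, signal fraction, and PCR
  duplication rate.

All generators are pure functions of their seed (NumPy PCG64 via
``default_rng``; no global RNG state), and each returns a truth record
sufficient to compute every downstream expectation without re-deriving it
from the generated output.

The default desk-scale world is 3 chromosomes x 2 Mb, 300 genes, two
1,000-peak sets and 200k tags — small enough for interactive runs, large enough
for the statistics to be out of the small-sample regime.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import GenerationError, UsageError
from .genome import Genome
from .intervals import GeneModel, Peak, PeakSet
from .motifs import PFM
from .qc import TagRecord

__all__ = [
    "DEFAULT_CHROM_SIZES",
    "generate_genome",
    "generate_peak_pair",
    "place_matched_set",
    "generate_genes",
    "plant_motifs",
    "generate_tags",
    "generate_world",
    "World",
]


class _DisjointIntervals:
    """Per-chromosome sorted disjoint intervals with O(log n) conflict checks.

    Intervals added through :meth:`add` must not overlap existing ones (the
    caller checks with :meth:`conflicts` first); :meth:`add_merging` relaxes
    that by merging, used to seed the structure from possibly-overlapping
    peak windows.
    """

    def __init__(self) -> None:
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}

    def conflicts(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        ends = self._ends[chrom]
        i = bisect_left(starts, end)
        if i < len(starts) and starts[i] < end:
            return True
        return i > 0 and ends[i - 1] > start

    def add(self, chrom: str, start: int, end: int) -> None:
        starts = self._starts.setdefault(chrom, [])
        ends = self._ends.setdefault(chrom, [])
        i = bisect_left(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)

    def add_merging(self, chrom: str, start: int, end: int) -> None:
        starts = self._starts.setdefault(chrom, [])
        ends = self._ends.setdefault(chrom, [])
        i = bisect_left(starts, start)
        # swallow neighbours that overlap [start, end)
        while i > 0 and ends[i - 1] > start:
            i -= 1
            start = min(start, starts[i])
            end = max(end, ends[i])
            del starts[i], ends[i]
        while i < len(starts) and starts[i] < end:
            end = max(end, ends[i])
            del starts[i], ends[i]
        starts.insert(i, start)
        ends.insert(i, end)

DEFAULT_CHROM_SIZES: dict[str, int] = {
    "chr1": 2_000_000,
    "chr2": 2_000_000,
    "chr3": 2_000_000,
}

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)


def _check_sizes(chrom_sizes: Mapping[str, int]) -> None:
    if not chrom_sizes:
        raise UsageError("chrom_sizes must not be empty")
    for c, L in chrom_sizes.items():
        if L < 10_000:
            raise UsageError(f"chromosome {c} must be >= 10 kb, got {L}")


def generate_genome(
    chrom_sizes: Mapping[str, int] | None = None,
    gc_profile: Mapping[str, Sequence[float]] | float = 0.42,
    seed: int = 0,
) -> Genome:
    """i.i.d. genome with per-region GC targets.

    ``gc_profile`` is either a single genome-wide GC target or a mapping
    chromosome -> list of per-region targets (the chromosome is split into
    that many equal regions). Strand-symmetric: G vs C and A vs T are
    equiprobable within their class. Deterministic under ``seed``.
    """
    chrom_sizes = dict(chrom_sizes or DEFAULT_CHROM_SIZES)
    _check_sizes(chrom_sizes)
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    for chrom, length in chrom_sizes.items():
        if isinstance(gc_profile, Mapping):
            targets = list(gc_profile.get(chrom, [0.42]))
        else:
            targets = [float(gc_profile)]
        for t in targets:
            if not (0 < t < 1):
                raise UsageError(f"GC target {t} outside (0, 1)")
        bounds = np.linspace(0, length, len(targets) + 1).astype(int)
        parts = []
        for t, lo, hi in zip(targets, bounds[:-1], bounds[1:]):
            n = hi - lo
            probs = np.array([(1 - t) / 2, t / 2, t / 2, (1 - t) / 2])
            codes = rng.choice(4, size=n, p=probs)
            parts.append(_LETTERS[codes].tobytes().decode("ascii"))
        seqs[chrom] = "".join(parts)
    return Genome(seqs)


def default_width_sampler(rng: np.random.Generator) -> int:
    """Peak widths uniform on [200, 400] bp — typical point-source peaks."""
    return int(rng.integers(200, 401))


@dataclass(frozen=True)
class PeakPairTruth:
    seed: int
    n_A: int
    n_B: int
    overlap_frac: float
    n_overlapping: int          # constructed A-B overlapping pairs
    overlapping_A: tuple[int, ...]  # indices into the returned (sorted) A set
    overlapping_B: tuple[int, ...]


def generate_peak_pair(
    n_A: int,
    n_B: int,
    overlap_frac: float,
    chrom_sizes: Mapping[str, int] | None = None,
    width_sampler: Callable[[np.random.Generator], int] | None = None,
    seed: int = 0,
    genome_id: str = "synthetic",
) -> tuple[PeakSet, PeakSet, PeakPairTruth]:
    """Two peak sets with an exact constructed overlap count.

    ``round(overlap_frac * n_B)`` B peaks are placed to overlap a *distinct*
    A peak by >=1 bp; every other peak (of either set) is placed disjoint
    from everything else. Placement uses non-adjacent genome slots wide
    enough for any overlapping pair, so the truth counts are exact:
    ``A_shared = B_shared = common_clusters = n_overlapping``.
    """
    chrom_sizes = dict(chrom_sizes or DEFAULT_CHROM_SIZES)
    _check_sizes(chrom_sizes)
    if not (0 <= overlap_frac <= 1):
        raise UsageError("overlap_frac must lie in [0, 1]")
    if n_A < 1 or n_B < 1:
        raise UsageError("both sets must contain at least one peak")
    n_ov = round(overlap_frac * n_B)
    if n_ov > n_A:
        raise UsageError(
            f"cannot overlap {n_ov} B peaks with distinct A peaks (n_A={n_A})"
        )
    rng = np.random.default_rng(seed)
    sampler = width_sampler or default_width_sampler

    w_max = 400 if width_sampler is None else None
    widths_A = [sampler(rng) for _ in range(n_A)]
    widths_B = [sampler(rng) for _ in range(n_B)]
    if w_max is None:
        w_max = max(widths_A + widths_B)
    slot = 3 * w_max + 10

    chroms = sorted(chrom_sizes)
    slot_counts = {c: chrom_sizes[c] // slot for c in chroms}
    total_slots = sum(slot_counts.values())
    n_groups = n_A + n_B - n_ov  # one slot per overlap pair or lone peak
    if n_groups > total_slots:
        raise GenerationError(
            f"insufficient genome space: need {n_groups} slots of {slot} bp, "
            f"have {total_slots}"
        )
    chosen = rng.choice(total_slots, size=n_groups, replace=False)
    slot_origin = []
    offset = 0
    for c in chroms:
        slot_origin.append((offset, offset + slot_counts[c], c))
        offset += slot_counts[c]

    def slot_start(global_idx: int) -> tuple[str, int]:
        for lo, hi, c in slot_origin:
            if lo <= global_idx < hi:
                return c, (global_idx - lo) * slot
        raise AssertionError("slot index out of range")

    peaks_A: list[Peak] = []
    peaks_B: list[Peak] = []
    pair_names: list[tuple[str, str]] = []
    g = 0
    for i in range(n_ov):
        chrom, s0 = slot_start(int(chosen[g])); g += 1
        wa, wb = widths_A[i], widths_B[i]
        a0 = s0 + w_max
        b0 = int(rng.integers(a0 - wb + 1, a0 + wa))  # guarantees >=1 bp overlap
        name_a, name_b = f"A_ov{i}", f"B_ov{i}"
        peaks_A.append(Peak(chrom, a0, a0 + wa, name_a))
        peaks_B.append(Peak(chrom, b0, b0 + wb, name_b))
        pair_names.append((name_a, name_b))
    for i in range(n_ov, n_A):
        chrom, s0 = slot_start(int(chosen[g])); g += 1
        peaks_A.append(Peak(chrom, s0 + w_max, s0 + w_max + widths_A[i], f"A_{i}"))
    for i in range(n_ov, n_B):
        chrom, s0 = slot_start(int(chosen[g])); g += 1
        peaks_B.append(Peak(chrom, s0 + w_max, s0 + w_max + widths_B[i], f"B_{i}"))

    A = PeakSet("A", peaks_A, genome_id)
    B = PeakSet("B", peaks_B, genome_id)
    name_to_idx_A = {p.name: i for i, p in enumerate(A.peaks)}
    name_to_idx_B = {p.name: i for i, p in enumerate(B.peaks)}
    truth = PeakPairTruth(
        seed=seed,
        n_A=n_A,
        n_B=n_B,
        overlap_frac=overlap_frac,
        n_overlapping=n_ov,
        overlapping_A=tuple(name_to_idx_A[a] for a, _ in pair_names),
        overlapping_B=tuple(name_to_idx_B[b] for _, b in pair_names),
    )
    return A, B, truth


def scatter_peaks(
    n: int,
    chrom_sizes: Mapping[str, int] | None = None,
    width_sampler: Callable[[np.random.Generator], int] | None = None,
    seed: int = 0,
    genome_id: str = "synthetic",
    label: str = "scatter",
) -> PeakSet:
    """``n`` mutually disjoint peaks placed uniformly at random."""
    chrom_sizes = dict(chrom_sizes or DEFAULT_CHROM_SIZES)
    _check_sizes(chrom_sizes)
    rng = np.random.default_rng(seed)
    sampler = width_sampler or default_width_sampler
    chroms = sorted(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    occupied = _DisjointIntervals()
    peaks = []
    for i in range(n):
        w = sampler(rng)
        for _ in range(10_000):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            start = int(rng.integers(0, chrom_sizes[chrom] - w + 1))
            if not occupied.conflicts(chrom, start, start + w):
                occupied.add(chrom, start, start + w)
                peaks.append(Peak(chrom, start, start + w, f"{label}_{i}"))
                break
        else:
            raise GenerationError("insufficient genome space for scatter_peaks")
    return PeakSet(label, peaks, genome_id)


def place_matched_set(
    A: PeakSet,
    n_B: int,
    overlap_frac: float,
    chrom_sizes: Mapping[str, int] | None = None,
    width_sampler: Callable[[np.random.Generator], int] | None = None,
    seed: int = 0,
) -> tuple[PeakSet, PeakPairTruth]:
    """A new peak set built *against an existing one* with exact overlap count.

    ``round(overlap_frac * n_B)`` B peaks each overlap a distinct A peak by
    >=1 bp and nothing else; the remainder are disjoint from everything.
    Requires A's peaks to be mutually disjoint (the generators here always
    produce such sets). Unlike :func:`generate_peak_pair` this leaves A
    untouched, so truths already attached to A (e.g. TSS-proximal planting)
    remain valid.
    """
    chrom_sizes = dict(chrom_sizes or DEFAULT_CHROM_SIZES)
    _check_sizes(chrom_sizes)
    if not (0 <= overlap_frac <= 1):
        raise UsageError("overlap_frac must lie in [0, 1]")
    n_ov = round(overlap_frac * n_B)
    if n_ov > len(A):
        raise UsageError(
            f"cannot overlap {n_ov} B peaks with distinct A peaks (n_A={len(A)})"
        )
    rng = np.random.default_rng(seed)
    sampler = width_sampler or default_width_sampler
    occupied = _DisjointIntervals()
    for p in A:
        occupied.add_merging(p.chrom, p.start, p.end)
    chroms = sorted(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    targets = rng.choice(len(A), size=n_ov, replace=False)
    peaks_B: list[Peak] = []
    pairs: list[tuple[int, str]] = []
    for k, ti in enumerate(targets):
        a = A[int(ti)]
        wb = sampler(rng)
        L = chrom_sizes[a.chrom]
        lo = max(0, a.start - wb + 1)
        hi = min(L - wb, a.end - 1)
        if hi < lo:
            raise GenerationError(
                f"no room to overlap peak {a.name!r} on {a.chrom}"
            )
        placed = False
        for _ in range(100):
            b0 = int(rng.integers(lo, hi + 1))
            # must touch only its target A peak: temporarily ignore a's span
            conflict = False
            if b0 < a.start and occupied.conflicts(a.chrom, b0, a.start):
                conflict = True
            if b0 + wb > a.end and occupied.conflicts(a.chrom, a.end, b0 + wb):
                conflict = True
            if not conflict:
                placed = True
                break
        if not placed:
            # crowded neighbourhood: nest the partner inside its target,
            # which can never touch anything else
            wb = min(wb, a.end - a.start)
            b0 = int(rng.integers(a.start, a.end - wb + 1))
        name = f"B_ov{k}"
        peaks_B.append(Peak(a.chrom, b0, b0 + wb, name))
        occupied.add_merging(a.chrom, b0, b0 + wb)
        pairs.append((int(ti), name))
    for i in range(n_ov, n_B):
        wb = sampler(rng)
        for _ in range(10_000):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            b0 = int(rng.integers(0, chrom_sizes[chrom] - wb + 1))
            if not occupied.conflicts(chrom, b0, b0 + wb):
                occupied.add(chrom, b0, b0 + wb)
                peaks_B.append(Peak(chrom, b0, b0 + wb, f"B_{i}"))
                break
        else:
            raise GenerationError("insufficient genome space for the B set")

    B = PeakSet("B", peaks_B, A.genome_id)
    name_to_idx_B = {p.name: i for i, p in enumerate(B.peaks)}
    truth = PeakPairTruth(
        seed=seed,
        n_A=len(A),
        n_B=n_B,
        overlap_frac=overlap_frac,
        n_overlapping=n_ov,
        overlapping_A=tuple(int(ti) for ti, _ in pairs),
        overlapping_B=tuple(name_to_idx_B[nm] for _, nm in pairs),
    )
    return B, truth


@dataclass(frozen=True)
class GeneTruth:
    seed: int
    n_genes: int
    tss_proximal_frac: float
    proximal_peaks: tuple[str, ...]  # names of the re-anchored peaks


def generate_genes(
    n_genes: int,
    chrom_sizes: Mapping[str, int] | None = None,
    tss_proximal_peaks: PeakSet | None = None,
    tss_proximal_frac: float = 0.0,
    seed: int = 0,
    proximal_window: int = 500,
    clearance_window: int = 1_000,
) -> tuple[list[GeneModel], PeakSet | None, GeneTruth]:
    """Genes with uniform TSS positions; optional exact TSS-proximal planting.

    When a peak set is supplied, ``round(tss_proximal_frac * n)`` of its
    peaks are re-anchored so their midpoint lies within ``proximal_window``
    bp of some TSS; the remaining peaks are relocated, if necessary, to at
    least ``clearance_window`` bp from every TSS. The planted share is then
    the exact promoter fraction at the +/-1 kb window, which is what makes
    the truth record sufficient for downstream checks.
    """
    chrom_sizes = dict(chrom_sizes or DEFAULT_CHROM_SIZES)
    _check_sizes(chrom_sizes)
    if n_genes < 1:
        raise UsageError("n_genes must be >= 1")
    if not (0 <= tss_proximal_frac <= 1):
        raise UsageError("tss_proximal_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    genes: list[GeneModel] = []
    tss_by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    for i in range(n_genes):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        L = chrom_sizes[chrom]
        length = int(rng.integers(2_000, 20_001))
        strand = "+" if rng.random() < 0.5 else "-"
        tss = int(rng.integers(clearance_window + length, L - clearance_window - length))
        if strand == "+":
            start, end = tss, tss + length
        else:
            start, end = tss - length + 1, tss + 1
        genes.append(GeneModel(f"gene{i}", chrom, strand, start, end))
        tss_by_chrom[chrom].append(tss)
    tss_sorted = {c: np.array(sorted(v), dtype=np.int64) for c, v in tss_by_chrom.items()}

    def near_tss(chrom: str, pos: int, window: int) -> bool:
        arr = tss_sorted[chrom]
        if len(arr) == 0:
            return False
        j = int(np.searchsorted(arr, pos))
        for k in (j - 1, j):
            if 0 <= k < len(arr) and abs(pos - int(arr[k])) <= window:
                return True
        return False

    if tss_proximal_peaks is None:
        return genes, None, GeneTruth(seed, n_genes, tss_proximal_frac, ())

    peaks = list(tss_proximal_peaks.peaks)
    n = len(peaks)
    n_prox = round(tss_proximal_frac * n)
    order = rng.permutation(n)
    proximal_idx = set(int(i) for i in order[:n_prox])
    occupied = _DisjointIntervals()  # keeps the output set mutually disjoint
    out: list[Peak] = []
    for i, p in enumerate(peaks):
        width = p.end - p.start
        if i in proximal_idx:
            # midpoint within +/- proximal_window of a random TSS on a
            # chromosome that has genes
            for _ in range(10_000):
                chrom = chroms[int(rng.choice(len(chroms), p=weights))]
                if len(tss_sorted[chrom]) == 0:
                    continue
                tss = int(rng.choice(tss_sorted[chrom]))
                mid = tss + int(rng.integers(-proximal_window, proximal_window + 1))
                start = mid - width // 2
                if (0 <= start and start + width <= chrom_sizes[chrom]
                        and not occupied.conflicts(chrom, start, start + width)):
                    occupied.add(chrom, start, start + width)
                    out.append(Peak(chrom, start, start + width, p.name))
                    break
            else:
                raise GenerationError("could not place a TSS-proximal peak")
        else:
            chrom, start = p.chrom, p.start
            mid = start + width // 2
            tries = 0
            while (near_tss(chrom, mid, clearance_window)
                   or occupied.conflicts(chrom, start, start + width)):
                tries += 1
                if tries > 10_000:
                    raise GenerationError("could not clear a peak from promoters")
                chrom = chroms[int(rng.choice(len(chroms), p=weights))]
                start = int(rng.integers(0, chrom_sizes[chrom] - width + 1))
                mid = start + width // 2
            occupied.add(chrom, start, start + width)
            out.append(Peak(chrom, start, start + width, p.name))
    new_set = PeakSet(tss_proximal_peaks.label, out, tss_proximal_peaks.genome_id)
    truth = GeneTruth(
        seed,
        n_genes,
        tss_proximal_frac,
        tuple(peaks[i].name for i in sorted(proximal_idx)),
    )
    return genes, new_set, truth


@dataclass(frozen=True)
class MotifPlantTruth:
    seed: int
    rate_peak: float
    rate_bg: float
    peak_windows: tuple[tuple[str, int, int], ...]
    bg_windows: tuple[tuple[str, int, int], ...]
    planted_peak: tuple[bool, ...]
    planted_bg: tuple[bool, ...]


def _sample_site(pfm: PFM, rng: np.random.Generator) -> str:
    probs = pfm.column_probs()
    return "".join(
        "ACGT"[int(rng.choice(4, p=probs[:, j]))] for j in range(pfm.width)
    )


_COMP = str.maketrans("ACGT", "TGCA")


def plant_motifs(
    genome: Genome,
    peaks: PeakSet,
    pfm: PFM,
    rate_peak: float,
    rate_bg: float,
    seed: int = 0,
    flank: int = 100,
    n_bg_windows: int | None = None,
) -> tuple[Genome, MotifPlantTruth]:
    """Write motif sites into peak windows and random non-peak windows.

    Each peak window (anchor +/- flank) receives, with probability
    ``rate_peak``, one site drawn from the PFM's column distributions at a
    uniform offset on a uniform strand; background windows (disjoint from
    all peak windows, ``n_bg_windows`` of them, default = number of peaks)
    are planted at ``rate_bg``. Collisions between background windows are
    retried a bounded number of times. Returns the modified genome and the
    truth (window coordinates and planted flags).
    """
    for r in (rate_peak, rate_bg):
        if not (0 <= r <= 1):
            raise UsageError("planting rates must lie in [0, 1]")
    width = 2 * flank + 1
    if pfm.width >= width:
        raise UsageError("motif width must be smaller than the window width")
    rng = np.random.default_rng(seed)
    seqs = {c: bytearray(genome.sequence(c), "ascii") for c in genome.chroms}
    sizes = genome.sizes

    p_windows: list[tuple[str, int, int]] = []
    occupied = _DisjointIntervals()
    for p in peaks:
        a = p.anchor
        start = max(0, min(a - flank, sizes[p.chrom] - width))
        p_windows.append((p.chrom, start, start + width))
        occupied.add_merging(p.chrom, start, start + width)

    n_bg = n_bg_windows if n_bg_windows is not None else len(peaks)
    chroms = sorted(genome.chroms)
    weights = np.array([sizes[c] - width + 1 for c in chroms], dtype=float)
    weights /= weights.sum()
    b_windows: list[tuple[str, int, int]] = []
    for _ in range(n_bg):
        for _try in range(10_000):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            start = int(rng.integers(0, sizes[chrom] - width + 1))
            if not occupied.conflicts(chrom, start, start + width):
                b_windows.append((chrom, start, start + width))
                occupied.add(chrom, start, start + width)
                break
        else:
            raise GenerationError("could not place a background window")

    def plant(window: tuple[str, int, int]) -> None:
        chrom, start, end = window
        site = _sample_site(pfm, rng)
        if rng.random() < 0.5:
            site = site.translate(_COMP)[::-1]
        offset = int(rng.integers(0, width - pfm.width + 1))
        seqs[chrom][start + offset : start + offset + pfm.width] = site.encode()

    planted_peak = []
    for w in p_windows:
        hit = rng.random() < rate_peak
        planted_peak.append(hit)
        if hit:
            plant(w)
    planted_bg = []
    for w in b_windows:
        hit = rng.random() < rate_bg
        planted_bg.append(hit)
        if hit:
            plant(w)

    new_genome = Genome({c: s.decode("ascii") for c, s in seqs.items()})
    truth = MotifPlantTruth(
        seed=seed,
        rate_peak=rate_peak,
        rate_bg=rate_bg,
        peak_windows=tuple(p_windows),
        bg_windows=tuple(b_windows),
        planted_peak=tuple(planted_peak),
        planted_bg=tuple(planted_bg),
    )
    return new_genome, truth


@dataclass(frozen=True)
class TagTruth:
    seed: int
    n_requested: int
    n_emitted: int
    signal_frac: float
    frag_len: int
    read_len: int
    dup_rate: float
    n_duplicated: int

    @property
    def expected_pbc(self) -> float:
        """Exact PBC implied by the duplication bookkeeping.

        Pre-amplification 5' positions are distinct by construction, so the
        distinct-position count equals ``n_requested`` and the singletons are
        exactly the non-duplicated tags.
        """
        return (self.n_requested - self.n_duplicated) / self.n_requested


def generate_tags(
    peaks: PeakSet,
    signal_frac: float,
    n_tags: int,
    frag_len: int,
    read_len: int,
    dup_rate: float,
    chrom_sizes: Mapping[str, int] | None = None,
    seed: int = 0,
    jitter: int = 50,
    background_bin: int = 10_000,
    background_shape: float = 0.5,
) -> tuple[list[TagRecord], TagTruth]:
    """Tag library with known signal structure and duplication rate.

    A ``signal_frac`` share of tags are fragment ends around peak anchors: a
    + strand tag's 5' end sits near ``anchor - frag_len/2`` and a - strand
    tag's near ``anchor + frag_len/2`` (uniform jitter of +/- ``jitter``
    bp), so the strand cross-correlation peaks at ``frag_len``. The
    remaining tags are background noise drawn from a strand-shared regional
    density (gamma-weighted ``background_bin`` bins) — the large-scale
    accessibility/mappability structure that keeps real cross-correlation
    profiles positive at every shift.

    Pre-amplification 5' positions are forced distinct (rejection on the
    (chrom, strand, position) key), so library complexity is governed purely
    by the final step: each emitted tag is duplicated once with probability
    ``dup_rate``, making ``pbc == (n - n_dup) / n`` exact.
    """
    chrom_sizes = dict(chrom_sizes or DEFAULT_CHROM_SIZES)
    _check_sizes(chrom_sizes)
    if not (0 <= signal_frac <= 1) or not (0 <= dup_rate <= 1):
        raise UsageError("signal_frac and dup_rate must lie in [0, 1]")
    if n_tags < 1:
        raise UsageError("n_tags must be >= 1")
    if frag_len < read_len:
        raise UsageError("frag_len must be >= read_len")
    for c, L in chrom_sizes.items():
        if frag_len >= L:
            raise GenerationError(f"frag_len {frag_len} exceeds chromosome {c}")
    if signal_frac > 0 and len(peaks) == 0:
        raise UsageError("signal tags require a non-empty peak set")
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)

    # regional background density: gamma weights on background_bin tiles,
    # shared by both strands
    bin_chrom: list[int] = []
    bin_start: list[int] = []
    bin_len: list[int] = []
    for ci, c in enumerate(chroms):
        L = chrom_sizes[c]
        for s in range(0, L, background_bin):
            bin_chrom.append(ci)
            bin_start.append(s)
            bin_len.append(min(background_bin, L - s))
    bin_chrom_a = np.array(bin_chrom)
    bin_start_a = np.array(bin_start)
    bin_len_a = np.array(bin_len)
    gamma = rng.gamma(background_shape, 1.0, size=len(bin_len))
    bin_weights = gamma * bin_len_a
    bin_weights /= bin_weights.sum()

    anchors = np.array([p.anchor for p in peaks], dtype=np.int64) if len(peaks) else None
    peak_chrom_idx = (
        np.array([chroms.index(p.chrom) for p in peaks]) if len(peaks) else None
    )
    half = frag_len // 2

    seen: set[tuple[int, bool, int]] = set()
    out_chrom: list[int] = []
    out_five: list[int] = []
    out_minus: list[bool] = []
    guard = 0
    while len(out_five) < n_tags:
        guard += 1
        if guard > 1_000:
            raise GenerationError(
                "could not draw enough distinct tag positions; "
                "the genome is saturated at this depth"
            )
        k = n_tags - len(out_five)
        minus = rng.random(k) < 0.5
        is_sig = rng.random(k) < signal_frac
        ci = np.empty(k, dtype=np.int64)
        five = np.empty(k, dtype=np.int64)
        n_sig = int(is_sig.sum())
        if n_sig:
            pi = rng.integers(0, len(peaks), size=n_sig)
            jit = rng.integers(-jitter, jitter + 1, size=n_sig)
            offs = np.where(minus[is_sig], half, -half)
            ci[is_sig] = peak_chrom_idx[pi]
            five[is_sig] = anchors[pi] + offs + jit
        n_noise = k - n_sig
        if n_noise:
            bi = rng.choice(len(bin_weights), size=n_noise, p=bin_weights)
            off = (rng.random(n_noise) * bin_len_a[bi]).astype(np.int64)
            ci[~is_sig] = bin_chrom_a[bi]
            five[~is_sig] = bin_start_a[bi] + off
        for j in range(k):
            c = int(ci[j])
            L = chrom_sizes[chroms[c]]
            f = max(read_len - 1, min(int(five[j]), L - read_len))
            key = (c, bool(minus[j]), f)
            if key in seen:
                continue
            seen.add(key)
            out_chrom.append(c)
            out_five.append(f)
            out_minus.append(bool(minus[j]))

    tags = []
    for c, f, m in zip(out_chrom, out_five, out_minus):
        chrom = chroms[c]
        if m:
            tags.append(TagRecord(chrom, f - read_len + 1, f + 1, "-"))
        else:
            tags.append(TagRecord(chrom, f, f + read_len, "+"))

    dup_mask = rng.random(len(tags)) < dup_rate
    duplicated = [t for t, m in zip(tags, dup_mask) if m]
    all_tags = tags + duplicated
    truth = TagTruth(
        seed=seed,
        n_requested=n_tags,
        n_emitted=len(all_tags),
        signal_frac=signal_frac,
        frag_len=frag_len,
        read_len=read_len,
        dup_rate=dup_rate,
        n_duplicated=len(duplicated),
    )
    return all_tags, truth


@dataclass
class World:
    """A complete synthetic study: genome, peak sets, genes, motifs, tags."""

    seed: int
    genome: Genome
    chrom_sizes: dict[str, int]
    peaks_A: PeakSet
    peaks_B: PeakSet
    pair_truth: PeakPairTruth
    genes: list[GeneModel]
    gene_truth: GeneTruth
    motif: PFM
    decoys: list[PFM]
    plant_truth: MotifPlantTruth
    tags: list[TagRecord]
    tag_truth: TagTruth


def _random_pfm(rng: np.random.Generator, motif_id: str, width: int = 8,
                sharpness: float = 20.0) -> PFM:
    """An information-rich random motif: one dominant base per column."""
    counts = np.zeros((4, width), dtype=np.int64)
    for j in range(width):
        dom = int(rng.integers(0, 4))
        counts[:, j] = 1
        counts[dom, j] = int(sharpness)
    return PFM(motif_id, motif_id, counts)


def generate_world(
    seed: int = 0,
    chrom_sizes: Mapping[str, int] | None = None,
    n_A: int = 1_000,
    n_B: int = 1_000,
    overlap_frac: float = 0.42,
    n_genes: int = 300,
    tss_proximal_frac: float = 0.70,
    rate_peak: float = 0.6,
    rate_bg: float = 0.0,
    n_decoys: int = 10,
    n_tags: int = 200_000,
    signal_frac: float = 0.3,
    frag_len: int = 200,
    read_len: int = 36,
    dup_rate: float = 0.1,
    gc_profile: Mapping[str, Sequence[float]] | float | None = None,
) -> World:
    """The default desk-scale study world used by the pipeline and tests.

    Child generators get independent seeds derived from ``seed`` via
    ``SeedSequence.spawn`` semantics (simple fixed offsets, documented and
    stable across platforms).
    """
    chrom_sizes = dict(chrom_sizes or DEFAULT_CHROM_SIZES)
    if gc_profile is None:
        # mild GC gradient per chromosome: 0.35 -> 0.55 over 8 regions
        gc_profile = {
            c: list(np.linspace(0.35, 0.55, 8)) for c in chrom_sizes
        }
    genome = generate_genome(chrom_sizes, gc_profile, seed=seed)
    # Order matters: genes re-anchor A for TSS proximity first, then B is
    # constructed against the *final* A so both truths hold simultaneously.
    A0 = scatter_peaks(n_A, chrom_sizes, seed=seed + 1, label="A")
    genes, A_placed, gene_truth = generate_genes(
        n_genes, chrom_sizes, A0, tss_proximal_frac, seed=seed + 2
    )
    assert A_placed is not None
    B, pair_truth = place_matched_set(
        A_placed, n_B, overlap_frac, chrom_sizes, seed=seed + 1
    )
    rng = np.random.default_rng(seed + 3)
    motif = _random_pfm(rng, "PLANTED")
    decoys = [_random_pfm(rng, f"DECOY{i}") for i in range(n_decoys)]
    genome, plant_truth = plant_motifs(
        genome, A_placed, motif, rate_peak, rate_bg, seed=seed + 4,
        n_bg_windows=10 * len(A_placed),
    )
    tags, tag_truth = generate_tags(
        A_placed, signal_frac, n_tags, frag_len, read_len, dup_rate,
        chrom_sizes, seed=seed + 5,
    )
    return World(
        seed=seed,
        genome=genome,
        chrom_sizes=chrom_sizes,
        peaks_A=A_placed,
        peaks_B=B,
        pair_truth=pair_truth,
        genes=genes,
        gene_truth=gene_truth,
        motif=motif,
        decoys=decoys,
        plant_truth=plant_truth,
        tags=tags,
        tag_truth=tag_truth,
    )
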