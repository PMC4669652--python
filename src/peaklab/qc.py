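"""ENCODE-style ChIP-seq library quality metrics.

Implements the standard post-alignment diagnostics computed from a tag
(aligned-read) library:

* SPOT — signal portion of tags: fraction of tag 5' ends falling inside the
  supplied peak regions;
* PBC — PCR bottleneck coefficient (PBC1 variant): N1/Nd, where Nd is the
  number of distinct (chrom, strand, 5' end) positions and N1 the number of
  positions seen exactly once;
* strand cross-correlation — Pearson correlation between per-base + strand
  and shifted - strand 5' end counts, concatenated across chromosomes, from
  which NSC (cc_max / cc_min) and RSC ((cc_max - cc_min) / (cc_readlen -
  cc_min)) are derived. Values above 1 indicate acceptable enrichment;
* saturation — Pearson correlation of binned coverage (10 kb bins) between a
  random subsample of the tags and the full library, across a grid of
  sampling fractions.

Shifted correlations never cross chromosome boundaries: for shift d the
overlapping segments ``plus[0 : L-d]`` and ``minus[d : L]`` of each
chromosome are concatenated and correlated. Inner products over all shifts
are obtained with one FFT cross-correlation per chromosome; marginal sums
come from prefix sums, so the profile is exact up to FFT round-off.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from .errors import UsageError
from .intervals import PeakSet, merge

__all__ = [
    "TagRecord",
    "CrossCorrelationProfile",
    "QCReport",
    "spot",
    "pbc",
    "cross_correlation",
    "nsc_rsc",
    "saturation_curve",
]


@dataclass(frozen=True)
class TagRecord:
    """One aligned tag; the 5' end is ``start`` on + and ``end - 1`` on -."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise UsageError(f"tag strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise UsageError(f"bad tag span [{self.start}, {self.end})")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class CrossCorrelationProfile:
    shifts: np.ndarray  # 0..max_shift
    cc: np.ndarray      # Pearson correlation per shift

    @property
    def argmax_shift(self) -> int:
        return int(self.shifts[int(np.argmax(self.cc))])

    @property
    def cc_max(self) -> float:
        return float(self.cc.max())

    @property
    def cc_min(self) -> float:
        return float(self.cc.min())

    def cc_at(self, shift: int) -> float:
        idx = int(np.searchsorted(self.shifts, shift))
        if idx >= len(self.shifts) or self.shifts[idx] != shift:
            raise UsageError(f"shift {shift} not in profile")
        return float(self.cc[idx])


@dataclass(frozen=True)
class QCReport:
    n_tags: int
    spot: float
    pbc: float
    nsc: float
    rsc: float | None
    argmax_shift: int
    saturation: list[tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "n_tags": self.n_tags,
            "spot": self.spot,
            "pbc": self.pbc,
            "nsc": self.nsc,
            "rsc": self.rsc,
            "argmax_shift": self.argmax_shift,
            "saturation": [[f, r] for f, r in self.saturation],
        }


def _five_prime_arrays(tags: Sequence[TagRecord]) -> tuple[list[str], np.ndarray, np.ndarray]:
    chroms = [t.chrom for t in tags]
    pos = np.fromiter((t.five_prime for t in tags), dtype=np.int64, count=len(tags))
    minus = np.fromiter((t.strand == "-" for t in tags), dtype=bool, count=len(tags))
    return chroms, pos, minus


def spot(tags: Sequence[TagRecord], peaks: PeakSet) -> float:
    """Fraction of tags whose 5' end lies inside a peak interval."""
    if len(tags) == 0:
        raise UsageError("SPOT requires at least one tag")
    merged = merge(peaks)
    starts: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    for iv in merged:
        starts.setdefault(iv.chrom, []).append(iv.start)
        ends.setdefault(iv.chrom, []).append(iv.end)
    index = {
        c: (np.array(starts[c], dtype=np.int64), np.array(ends[c], dtype=np.int64))
        for c in starts
    }
    inside = 0
    for t in tags:
        idx = index.get(t.chrom)
        if idx is None:
            continue
        s, e = idx
        j = int(np.searchsorted(s, t.five_prime, side="right")) - 1
        if j >= 0 and t.five_prime < e[j]:
            inside += 1
    return inside / len(tags)


def pbc(tags: Sequence[TagRecord]) -> float:
    """PBC1 = N1/Nd over distinct (chrom, strand, 5' end) positions."""
    if len(tags) == 0:
        raise UsageError("PBC requires at least one tag")
    counts = Counter((t.chrom, t.strand, t.five_prime) for t in tags)
    n_distinct = len(counts)
    n_single = sum(1 for c in counts.values() if c == 1)
    return n_single / n_distinct


def _strand_count_vectors(
    tags: Sequence[TagRecord], chrom_sizes: dict[str, int] | None
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    per: dict[str, list[tuple[int, bool]]] = {}
    for t in tags:
        per.setdefault(t.chrom, []).append((t.five_prime, t.strand == "-"))
    out = {}
    for chrom, items in per.items():
        pos = np.array([p for p, _ in items], dtype=np.int64)
        neg = np.array([m for _, m in items], dtype=bool)
        if chrom_sizes is not None:
            length = chrom_sizes[chrom]
        else:
            length = int(pos.max()) + 1
        plus = np.bincount(pos[~neg], minlength=length).astype(float)
        minus = np.bincount(pos[neg], minlength=length).astype(float)
        out[chrom] = (plus, minus)
    return out


def cross_correlation(
    tags: Sequence[TagRecord],
    max_shift: int,
    bin: int = 1,
    chrom_sizes: dict[str, int] | None = None,
) -> CrossCorrelationProfile:
    """Strand cross-correlation profile for shifts 0..max_shift.

    For each shift d the Pearson correlation is computed between the + strand
    5'-end count vector and the - strand vector shifted left by d,
    concatenating the per-chromosome overlap segments. ``bin > 1`` aggregates
    counts into bins of that many bases first (shifts are then in bins).
    A zero-variance segment yields correlation 0 with a warning.
    """
    if len(tags) == 0:
        raise UsageError("cross-correlation requires at least one tag")
    if max_shift < 1:
        raise UsageError("max_shift must be >= 1")
    vectors = _strand_count_vectors(tags, chrom_sizes)
    if bin > 1:
        binned = {}
        for chrom, (plus, minus) in vectors.items():
            nb = (len(plus) + bin - 1) // bin
            pad = nb * bin - len(plus)
            plus = np.pad(plus, (0, pad)).reshape(nb, bin).sum(axis=1)
            minus = np.pad(minus, (0, pad)).reshape(nb, bin).sum(axis=1)
            binned[chrom] = (plus, minus)
        vectors = binned

    shifts = np.arange(max_shift + 1)
    n = np.zeros(max_shift + 1)
    sx = np.zeros(max_shift + 1)
    sy = np.zeros(max_shift + 1)
    sxx = np.zeros(max_shift + 1)
    syy = np.zeros(max_shift + 1)
    sxy = np.zeros(max_shift + 1)
    for plus, minus in vectors.values():
        L = len(plus)
        if L < 2:
            continue
        d_hi = min(max_shift, L - 1)
        d = shifts[: d_hi + 1]
        cp = np.concatenate([[0.0], np.cumsum(plus)])
        cp2 = np.concatenate([[0.0], np.cumsum(plus**2)])
        cm = np.concatenate([[0.0], np.cumsum(minus)])
        cm2 = np.concatenate([[0.0], np.cumsum(minus**2)])
        n[: d_hi + 1] += L - d
        sx[: d_hi + 1] += cp[L - d]               # sum plus[0 : L-d]
        sxx[: d_hi + 1] += cp2[L - d]
        sy[: d_hi + 1] += cm[L] - cm[d]           # sum minus[d : L]
        syy[: d_hi + 1] += cm2[L] - cm2[d]
        # sum_i plus[i] * minus[i + d] for all d at once via FFT
        conv = fftconvolve(minus, plus[::-1])
        sxy[: d_hi + 1] += conv[L - 1 : L + d_hi]
    cc = np.zeros(max_shift + 1)
    valid = n > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        safe_n = np.where(n > 0, n, 1)
        cov = sxy - sx * sy / safe_n
        var_x = np.maximum(sxx - sx**2 / safe_n, 0.0)
        var_y = np.maximum(syy - sy**2 / safe_n, 0.0)
        denom = np.sqrt(var_x * var_y)
        r = np.where(valid & (denom > 0), cov / np.where(denom > 0, denom, 1), 0.0)
    if (valid & (denom <= 1e-12)).any():
        warnings.warn(
            "zero-variance count vector at some shifts; correlation recorded as 0",
            stacklevel=2,
        )
    return CrossCorrelationProfile(shifts=shifts, cc=np.clip(r, -1.0, 1.0))


def nsc_rsc(
    profile: CrossCorrelationProfile, read_len: int
) -> tuple[float, float | None]:
    """NSC = cc(argmax)/cc_min; RSC = (cc(argmax)-cc_min)/(cc(read_len)-cc_min).

    RSC is undefined (returned as None) when the read-length correlation
    equals the profile minimum.
    """
    cc_max = profile.cc_max
    cc_min = profile.cc_min
    cc_read = profile.cc_at(read_len)
    nsc = cc_max / cc_min if cc_min != 0 else float("inf") if cc_max > 0 else 1.0
    if cc_read == cc_min:
        return nsc, None
    return nsc, (cc_max - cc_min) / (cc_read - cc_min)


def _binned_coverage(
    chroms: list[str],
    pos: np.ndarray,
    mask: np.ndarray,
    chrom_order: list[str],
    n_bins: dict[str, int],
    bin_width: int,
) -> np.ndarray:
    chrom_codes = {c: i for i, c in enumerate(chrom_order)}
    offsets = np.cumsum([0] + [n_bins[c] for c in chrom_order])
    total = int(offsets[-1])
    sel = np.flatnonzero(mask)
    flat = np.empty(len(sel), dtype=np.int64)
    for k, i in enumerate(sel):
        c = chroms[i]
        flat[k] = offsets[chrom_codes[c]] + pos[i] // bin_width
    return np.bincount(flat, minlength=total).astype(float)


def saturation_curve(
    tags: Sequence[TagRecord],
    fractions: Sequence[float] | None = None,
    bin_width: int = 10_000,
    seed: int = 0,
    chrom_sizes: dict[str, int] | None = None,
) -> list[tuple[float, float]]:
    """Subsampling saturation: Pearson r of binned 5'-end coverage between a
    without-replacement subsample and the full library, per fraction.

    Default fraction grid is 0.05, 0.10, ..., 1.00. Fraction 1.0 compares
    the library with itself (r = 1 exactly).
    """
    if len(tags) == 0:
        raise UsageError("saturation requires at least one tag")
    if fractions is None:
        fractions = [round(0.05 * k, 2) for k in range(1, 21)]
    for f in fractions:
        if not (0 < f <= 1):
            raise UsageError(f"sampling fraction {f} outside (0, 1]")
    chroms, pos, _ = _five_prime_arrays(tags)
    order = sorted(set(chroms))
    if chrom_sizes is None:
        max_pos: dict[str, int] = {}
        for c, p in zip(chroms, pos):
            max_pos[c] = max(max_pos.get(c, 0), int(p))
        sizes = {c: max_pos[c] + 1 for c in order}
    else:
        sizes = chrom_sizes
        order = sorted(sizes)
    n_bins = {c: (sizes[c] + bin_width - 1) // bin_width for c in order}

    all_mask = np.ones(len(tags), dtype=bool)
    full = _binned_coverage(chroms, pos, all_mask, order, n_bins, bin_width)
    rng = np.random.default_rng(seed)
    out: list[tuple[float, float]] = []
    for f in fractions:
        if f == 1.0:
            out.append((1.0, 1.0))
            continue
        k = max(1, int(round(f * len(tags))))
        idx = rng.choice(len(tags), size=k, replace=False)
        mask = np.zeros(len(tags), dtype=bool)
        mask[idx] = True
        sub = _binned_coverage(chroms, pos, mask, order, n_bins, bin_width)
        if full.std() == 0 or sub.std() == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(sub, full)[0, 1])
        out.append((float(f), r))
    return out


def qc_report(
    tags: Sequence[TagRecord],
    peaks: PeakSet,
    read_len: int,
    max_shift: int = 500,
    fractions: Sequence[float] | None = None,
    bin_width: int = 10_000,
    seed: int = 0,
    chrom_sizes: dict[str, int] | None = None,
) -> QCReport:
    """All QC metrics in one report."""
    profile = cross_correlation(tags, max_shift, chrom_sizes=chrom_sizes)
    nsc, rsc = nsc_rsc(profile, read_len)
    sat = saturation_curve(tags, fractions, bin_width, seed, chrom_sizes)
    return QCReport(
        n_tags=len(tags),
        spot=spot(tags, peaks),
        pbc=pbc(tags),
        nsc=nsc,
        rsc=rsc,
        argmax_shift=profile.argmax_shift,
        saturation=sat,
    )
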