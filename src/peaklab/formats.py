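"""Readers and writers for the plain-text formats the pipeline touches.

Supported: BED3/BED6, ENCODE 10-column narrowPeak, stranded "gene BED"
(BED6 with the gene id in the name column), tagAlign (6-column BED for
aligned reads), JASPAR PFM text, chromosome sizes tables, and fixed-step
bedGraph output for binned coverage. Everything is strict: a line a parser
cannot represent raises :class:`~peaklab.errors.FormatError` naming the line.

Coordinates are 0-based half-open on disk and in memory (BED native); the
narrowPeak summit column is an offset from ``start`` with ``-1`` = unknown.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import FormatError
from .intervals import GeneModel, Peak, PeakSet
from .motifs import PFM
from .qc import TagRecord

_DIALECT_COLUMNS = {"bed3": 3, "bed6": 6, "narrowPeak": 10}


def _int_field(token: str, what: str, line_number: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(f"non-integer {what}: {token!r}", line_number) from None


def _float_field(token: str, what: str, line_number: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"non-numeric {what}: {token!r}", line_number) from None


def parse_bed_line(line: str, dialect: str, line_number: int = 1) -> Peak:
    """Parse one BED3/BED6/narrowPeak line into a :class:`Peak`."""
    if dialect not in _DIALECT_COLUMNS:
        raise FormatError(f"unknown BED dialect {dialect!r}", line_number)
    fields = line.rstrip("\n").split("\t")
    need = _DIALECT_COLUMNS[dialect]
    if len(fields) < need:
        raise FormatError(
            f"{dialect} needs {need} columns, found {len(fields)}", line_number
        )
    chrom = fields[0]
    if not chrom:
        raise FormatError("empty chromosome name", line_number)
    start = _int_field(fields[1], "start", line_number)
    end = _int_field(fields[2], "end", line_number)
    if start < 0:
        raise FormatError(f"negative start: {start}", line_number)
    if start >= end:
        raise FormatError(f"start >= end: [{start}, {end})", line_number)

    name, score, strand = ".", 0.0, "."
    signal, pvalue, qvalue, summit = 0.0, -1.0, -1.0, -1
    if need >= 6:
        name = fields[3]
        score = _float_field(fields[4], "score", line_number)
        strand = fields[5]
        if strand not in ("+", "-", "."):
            raise FormatError(f"bad strand: {strand!r}", line_number)
    if need == 10:
        signal = _float_field(fields[6], "signalValue", line_number)
        pvalue = _float_field(fields[7], "pValue", line_number)
        qvalue = _float_field(fields[8], "qValue", line_number)
        summit = _int_field(fields[9], "summit offset", line_number)
        if summit < -1:
            raise FormatError(f"summit offset < -1: {summit}", line_number)
        if summit >= end - start:
            raise FormatError(
                f"summit offset {summit} outside peak of length {end - start}",
                line_number,
            )
    return Peak(chrom, start, end, name, score, strand,
                signal, pvalue, qvalue, summit)


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def format_bed_line(peak: Peak, dialect: str) -> str:
    """Inverse of :func:`parse_bed_line` for the same dialect."""
    if dialect not in _DIALECT_COLUMNS:
        raise FormatError(f"unknown BED dialect {dialect!r}")
    fields = [peak.chrom, str(peak.start), str(peak.end)]
    if dialect in ("bed6", "narrowPeak"):
        fields += [peak.name, _fmt(peak.score), peak.strand]
    if dialect == "narrowPeak":
        fields += [_fmt(peak.signal), _fmt(peak.pvalue), _fmt(peak.qvalue),
                   str(peak.summit_offset)]
    return "\t".join(fields)


def read_peaks(path: str, dialect: str = "narrowPeak",
               label: str = "", genome_id: str = "") -> PeakSet:
    """Read a whole peak file; comment (#) and empty lines are skipped."""
    peaks = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            peaks.append(parse_bed_line(raw, dialect, ln))
    return PeakSet(label or path, peaks, genome_id)


def write_peaks(peaks: Iterable[Peak], path: str, dialect: str = "narrowPeak") -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(format_bed_line(p, dialect) + "\n")


# -- gene BED ---------------------------------------------------------------

def parse_gene_bed_line(line: str, line_number: int = 1) -> GeneModel:
    """Stranded BED6 gene record: chrom, start, end, gene_id, score, strand."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise FormatError(
            f"gene BED needs 6 columns, found {len(fields)}", line_number
        )
    start = _int_field(fields[1], "start", line_number)
    end = _int_field(fields[2], "end", line_number)
    if start < 0 or start >= end:
        raise FormatError(f"bad gene span [{start}, {end})", line_number)
    strand = fields[5]
    if strand not in ("+", "-"):
        raise FormatError(f"gene strand must be + or -, got {strand!r}", line_number)
    return GeneModel(fields[3], fields[0], strand, start, end)


def read_genes(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            genes.append(parse_gene_bed_line(raw, ln))
    return genes


def write_genes(genes: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# -- tagAlign ---------------------------------------------------------------

def parse_tagalign_line(line: str, line_number: int = 1) -> TagRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise FormatError(
            f"tagAlign needs 6 columns, found {len(fields)}", line_number
        )
    start = _int_field(fields[1], "start", line_number)
    end = _int_field(fields[2], "end", line_number)
    if start < 0 or start >= end:
        raise FormatError(f"bad tag span [{start}, {end})", line_number)
    strand = fields[5]
    if strand not in ("+", "-"):
        raise FormatError(f"tag strand must be + or -, got {strand!r}", line_number)
    return TagRecord(fields[0], start, end, strand)


def read_tagalign(path: str) -> Iterator[TagRecord]:
    """Stream TagRecords from a tagAlign file."""
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            yield parse_tagalign_line(raw, ln)


def write_tagalign(tags: Iterable[TagRecord], path: str) -> None:
    with open(path, "w") as fh:
        for i, t in enumerate(tags):
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\tr{i}\t0\t{t.strand}\n")


# -- chromosome sizes -------------------------------------------------------

def read_sizes(path: str) -> dict[str, int]:
    """``chrom\\tlength`` table (first two columns of a .fai also work)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = raw.split("\t")
            if len(fields) < 2:
                raise FormatError("sizes table needs 2 columns", ln)
            length = _int_field(fields[1], "length", ln)
            if length <= 0:
                raise FormatError(f"non-positive length {length}", ln)
            sizes[fields[0]] = length
    if not sizes:
        raise FormatError("empty sizes table")
    return sizes


# -- JASPAR PFM -------------------------------------------------------------

_BASES = "ACGT"


def parse_jaspar_pfm(text_block: str) -> PFM:
    """Parse one JASPAR PFM record.

    Expected shape::

        >MA0001.1 NAME
        A  [ 4  0 19 ]
        C  [16  0  0 ]
        G  [ 0 20  1 ]
        T  [ 0  0  0 ]

    Bare space-separated count rows (without brackets) are also accepted.
    """
    lines = [ln.strip() for ln in text_block.strip().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise FormatError("JASPAR record must start with a '>' header")
    header = lines[0][1:].split(None, 1)
    if not header or not header[0]:
        raise FormatError("JASPAR header missing motif id")
    motif_id = header[0]
    name = header[1].strip() if len(header) > 1 else motif_id

    rows: dict[str, list[int]] = {}
    for ln, raw in enumerate(lines[1:], start=2):
        base, _, rest = raw.partition(" ")
        base = base.upper()
        if base not in _BASES:
            raise FormatError(f"unexpected base row label {base!r}", ln)
        if base in rows:
            raise FormatError(f"duplicate base row {base}", ln)
        tokens = rest.replace("[", " ").replace("]", " ").split()
        counts = []
        for tok in tokens:
            try:
                value = float(tok)
            except ValueError:
                raise FormatError(f"non-numeric count {tok!r}", ln) from None
            if value < 0 or value != int(value):
                raise FormatError(f"counts must be non-negative integers: {tok}", ln)
            counts.append(int(value))
        rows[base] = counts

    missing = [b for b in _BASES if b not in rows]
    if missing:
        raise FormatError(f"missing base row(s): {', '.join(missing)}")
    widths = {len(rows[b]) for b in _BASES}
    if len(widths) != 1:
        raise FormatError(f"unequal row lengths: {sorted(widths)}")
    width = widths.pop()
    if width == 0:
        raise FormatError("motif has zero width")
    counts = np.array([rows[b] for b in _BASES], dtype=np.int64)
    if (counts.sum(axis=0) == 0).any():
        bad = int(np.flatnonzero(counts.sum(axis=0) == 0)[0])
        raise FormatError(f"all-zero count column at position {bad}")
    return PFM(motif_id=motif_id, name=name, counts=counts)


def read_motif_library(path: str) -> list[PFM]:
    """Read a file of concatenated JASPAR PFM records."""
    with open(path) as fh:
        text = fh.read()
    blocks = [">" + b for b in text.split(">") if b.strip()]
    if not blocks:
        raise FormatError(f"no motif records in {path}")
    return [parse_jaspar_pfm(b) for b in blocks]


def write_motif_library(motifs: Sequence[PFM], path: str) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id} {m.name}\n")
            for b, row in zip(_BASES, m.counts):
                fh.write(f"{b} [ " + " ".join(str(int(c)) for c in row) + " ]\n")


# -- bedGraph ---------------------------------------------------------------

def write_bedgraph(
    path: str,
    binned: dict[str, np.ndarray],
    bin_width: int,
    sizes: dict[str, int],
    name: str = "coverage",
) -> None:
    """Fixed-step bedGraph of per-bin values (last bin truncated to the
    chromosome end); zero bins are omitted, as is conventional."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for chrom, values in binned.items():
            length = sizes[chrom]
            for i, v in enumerate(values):
                if v == 0:
                    continue
                start = i * bin_width
                end = min(start + bin_width, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{_fmt(float(v))}\n")
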