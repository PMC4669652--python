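"""In-memory genome sequence container.

Synthetic genomes at desk scale (a few Mb) fit comfortably in memory, so the
package keeps sequences as plain uppercase strings keyed by chromosome.
On-disk FASTA is read through :mod:`pyfaidx` and written wrapped at 60
columns; a ``chrom\\tlength`` sizes table travels alongside.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .errors import UsageError

_WRAP = 60


class Genome:
    """Chromosome name -> uppercase sequence, with fetch/GC helpers."""

    def __init__(self, seqs: Mapping[str, str]):
        if not seqs:
            raise UsageError("genome must contain at least one chromosome")
        self._seqs: dict[str, str] = {c: s.upper() for c, s in seqs.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(path, as_raw=True, sequence_always_upper=True)
        try:
            return cls({name: str(fa[name][:]) for name in fa.keys()})
        finally:
            fa.close()

    def to_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                fh.write(f">{chrom}\n")
                seq = self._seqs[chrom]
                for i in range(0, len(seq), _WRAP):
                    fh.write(seq[i : i + _WRAP] + "\n")

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    @property
    def sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def sequence(self, chrom: str) -> str:
        try:
            return self._seqs[chrom]
        except KeyError:
            raise UsageError(f"unknown chromosome {chrom!r}") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``[start, end)``, clipped to the chromosome."""
        seq = self.sequence(chrom)
        return seq[max(0, start) : min(len(seq), end)]

    def gc_fraction(self, chrom: str, start: int, end: int) -> float:
        """G+C fraction of a window (denominator is the window width)."""
        window = self.fetch(chrom, start, end)
        if not window:
            return 0.0
        return (window.count("G") + window.count("C")) / len(window)


def gc_fraction(seq: str) -> float:
    """G+C fraction of a sequence string (0.0 for the empty string)."""
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def write_sizes(sizes: Mapping[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def base_composition(genome: Genome | Mapping[str, str]) -> dict[str, float]:
    """Genome-wide A/C/G/T frequencies (ambiguous bases excluded)."""
    seqs: Iterable[str]
    seqs = genome._seqs.values() if isinstance(genome, Genome) else genome.values()
    counts = {b: 0 for b in "ACGT"}
    for s in seqs:
        u = s.upper()
        for b in "ACGT":
            counts[b] += u.count(b)
    total = sum(counts.values())
    if total == 0:
        raise UsageError("genome contains no unambiguous bases")
    return {b: c / total for b, c in counts.items()}
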