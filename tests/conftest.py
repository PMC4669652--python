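import numpy as np
import pytest

from peaklab.intervals import GenomicInterval, Peak, PeakSet, GeneModel


def random_peakset(
    rng: np.random.Generator,
    n: int,
    label: str = "S",
    genome_id: str = "test",
    chroms=("chr1", "chr2"),
    span: int = 10_000,
    max_len: int = 120,
) -> PeakSet:
    peaks = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        peaks.append(Peak(chrom, start, start + length, f"{label}{i}"))
    return PeakSet(label, peaks, genome_id)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=5_000, max_len=200):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def random_genes(rng, n, chroms=("chr1", "chr2"), span=100_000):
    genes = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(500, 5_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i}", chrom, strand, start, start + length))
    return genes


@pytest.fixture(scope="session")
def mini_world():
    """A small synthetic study reused by pipeline-level tests."""
    from peaklab.synthetic import generate_world

    return generate_world(
        seed=0,
        chrom_sizes={"chr1": 300_000, "chr2": 300_000},
        n_A=80,
        n_B=80,
        overlap_frac=0.4,
        n_genes=40,
        tss_proximal_frac=0.5,
        n_decoys=2,
        n_tags=8_000,
        signal_frac=0.3,
    )
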