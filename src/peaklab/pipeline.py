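"""End-to-end orchestration: two peak sets in, full report bundle out.

``run_analysis`` composes the library stages — co-localization, TSS/promoter
profiling, nearest-gene assignment, motif enrichment, QC — on files
referenced by a flat key-value config, writing deterministic TSV/JSON
reports plus a provenance block (seed, every effective parameter, package
version) so a run is self-describing. Outputs carry no timestamps: two runs
with the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass

import pandas as pd
import yaml

from . import __version__
from .coloc import colocalize, heatmap_matrix
from .errors import ConfigError, FormatError, UsageError
from .formats import (
    read_genes,
    read_motif_library,
    read_peaks,
    read_sizes,
    read_tagalign,
)
from .genes import (
    DEFAULT_TSS_BIN_EDGES,
    assign_all,
    assignments_frame,
    promoter_fraction,
    tss_histogram,
    unique_gene_count,
)
from .genome import Genome
from .intervals import GeneIndex, classify_feature
from .motifs import enrich_motif_set
from .qc import qc_report

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for a full analysis run.

    Every field has a documented default; the effective values are echoed
    into ``provenance.json`` so no run depends on implicit state.
    """

    peaks_a: str = ""
    peaks_b: str = ""
    genome_fasta: str = ""
    chrom_sizes: str = ""
    genes: str = ""
    motif_library: str = ""
    tags: str = ""
    out_dir: str = "peaklab_out"
    seed: int = 0
    # analysis parameters
    promoter_window: int = 1_000
    max_extension: int = 50_000
    motif_flank: int = 100
    motif_p_target: float = 1e-4
    bg_multiplier: int = 10
    pseudocount: float = 0.8
    coloc_bin_width: int = 0     # 0 = median combined peak length
    n_permutations: int = 200
    heatmap_flank: int = 2_000
    heatmap_bins: int = 40
    qc_read_len: int = 36
    qc_max_shift: int = 500
    saturation_bin_width: int = 10_000
    anchor: str = "midpoint"
    peak_dialect: str = "narrowPeak"
    render_png: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as e:
            raise ConfigError(f"cannot read config {path}: {e}") from e
        if not isinstance(raw, dict):
            raise ConfigError("config must be a flat key-value mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        required = {
            "peaks_a": self.peaks_a,
            "peaks_b": self.peaks_b,
            "chrom_sizes": self.chrom_sizes,
        }
        for key, path in required.items():
            if not path:
                raise ConfigError(f"config key {key!r} is required")
        optional = {
            "genome_fasta": self.genome_fasta,
            "genes": self.genes,
            "motif_library": self.motif_library,
            "tags": self.tags,
        }
        for key, path in {**required, **optional}.items():
            if path and not os.path.exists(path):
                raise ConfigError(f"{key} path does not exist: {path}")
        if self.motif_library and not self.genome_fasta:
            raise ConfigError("motif enrichment needs genome_fasta")
        if self.anchor not in ("midpoint", "summit"):
            raise ConfigError("anchor must be 'midpoint' or 'summit'")


def _write_json(path: str, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_tsv(path: str, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def run_analysis(config: RunConfig) -> dict:
    """Run every configured stage; returns the bundle as a dict of results.

    Stages whose inputs are not configured (no genes file, no motif library,
    no tag file) are skipped and recorded as skipped in the provenance block.
    Any stage error aborts the run naming the stage.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)  # noqa: E731
    bundle: dict = {}
    stages_run: list[str] = []

    def stage(name: str):
        logger.info("stage: %s", name)
        stages_run.append(name)

    try:
        stage("load")
        sizes = read_sizes(config.chrom_sizes)
        A = read_peaks(config.peaks_a, config.peak_dialect, label="A",
                       genome_id="run")
        B = read_peaks(config.peaks_b, config.peak_dialect, label="B",
                       genome_id="run")
    except FormatError as e:
        raise FormatError(f"[load] {e}") from e

    stage("coloc")
    report = colocalize(
        A, B, sizes,
        bin_width=config.coloc_bin_width or None,
        n_perm=config.n_permutations,
        seed=config.seed,
    )
    bundle["coloc"] = report
    _write_json(out("coloc.json"), report.to_dict())

    stage("heatmap")
    hm = heatmap_matrix(A, B, config.heatmap_flank, config.heatmap_bins)
    bundle["heatmap"] = hm
    hm_frame = pd.DataFrame(
        hm.values, columns=[f"bin{i}" for i in range(hm.n_bins)]
    )
    hm_frame.insert(0, "anchor", list(hm.anchor_names))
    _write_tsv(out("heatmap.tsv"), hm_frame)
    if config.render_png:
        from .plotting import render_heatmap

        render_heatmap(hm, out("heatmap.png"))

    if config.genes:
        stage("annotate")
        genes = read_genes(config.genes)
        index = GeneIndex(genes)
        assignments = assign_all(A, index, config.max_extension, config.anchor)
        _write_tsv(out("assignments.tsv"), assignments_frame(assignments))
        hist = tss_histogram(A, index, DEFAULT_TSS_BIN_EDGES, config.anchor)
        _write_tsv(out("tss_histogram.tsv"), hist)
        if config.render_png:
            from .plotting import render_tss_histogram

            render_tss_histogram(hist, out("tss_histogram.png"))
        features = pd.Series(
            [classify_feature(p, index, config.promoter_window) for p in A]
        ).value_counts().sort_index()
        annotate = {
            "promoter_fraction_pct": promoter_fraction(
                A, index, config.promoter_window, config.anchor
            ),
            "n_assigned": sum(a.gene_id is not None for a in assignments),
            "n_unique_genes": unique_gene_count(assignments),
            "feature_counts": features.to_dict(),
            "feature_scheme": "simplified promoter/gene_body/intergenic",
            "regulatory_domain_curation": "not applied (no curated domains)",
        }
        bundle["annotate"] = annotate
        _write_json(out("annotate.json"), annotate)

    if config.motif_library:
        stage("motif")
        genome = Genome.from_fasta(config.genome_fasta)
        library = read_motif_library(config.motif_library)
        records = enrich_motif_set(
            A, genome, library,
            flank=config.motif_flank,
            p_target=config.motif_p_target,
            bg_multiplier=config.bg_multiplier,
            pseudocount=config.pseudocount,
            seed=config.seed,
        )
        bundle["motif"] = records
        _write_tsv(out("motif_enrichment.tsv"), pd.DataFrame(
            {
                "motif_id": [r.motif_id for r in records],
                "name": [r.name for r in records],
                "n_peak": [r.n_peak for r in records],
                "k_peak": [r.k_peak for r in records],
                "pct_peak": [round(r.pct_peak, 4) for r in records],
                "n_bg": [r.n_bg for r in records],
                "k_bg": [r.k_bg for r in records],
                "pct_bg": [round(r.pct_bg, 4) for r in records],
                "p_binomial": [r.p_binomial for r in records],
                "q_bh": [r.q_bh for r in records],
                "stars": [r.stars for r in records],
            }
        ))

    if config.tags:
        stage("qc")
        tags = list(read_tagalign(config.tags))
        qc = qc_report(
            tags, A,
            read_len=config.qc_read_len,
            max_shift=config.qc_max_shift,
            bin_width=config.saturation_bin_width,
            seed=config.seed,
            chrom_sizes=sizes,
        )
        bundle["qc"] = qc
        _write_json(out("qc.json"), qc.to_dict())

    stage("provenance")
    provenance = {
        "package": "peaklab",
        "version": __version__,
        "seed": config.seed,
        "stages": stages_run,
        "parameters": {k: v for k, v in asdict(config).items()},
    }
    bundle["provenance"] = provenance
    _write_json(out("provenance.json"), provenance)
    return bundle


def count_fold_enriched(
    fold_table: list[tuple[str, float]], threshold: float = 1.5
) -> tuple[int, int]:
    """Count entries with fold change >= threshold (inclusive boundary).

    Mirrors the validation arithmetic of checking how many of a panel of
    candidate targets show at least a given fold increase in binding.
    """
    if not fold_table:
        raise UsageError("fold table must not be empty")
    for gene, fold in fold_table:
        if fold < 0:
            raise UsageError(f"negative fold change for {gene!r}")
    n_pass = sum(1 for _, fold in fold_table if fold >= threshold)
    return n_pass, len(fold_table)
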