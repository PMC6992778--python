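"""End-to-end pipeline driver: annotation -> assignment -> counting -> QC
-> priming diagnostics, with a manifest recording inputs, parameters, seed
and output checksums so deterministic stages can be verified on re-run."""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genome_annotation import derive_introns, parse_gtf, write_intervals
from .polya_diagnostics import (
    intersect_intronic,
    motif_position_histogram,
    polya_read_fraction,
    scan_polya,
    three_prime_enrichment,
    write_tracts_bed,
)
from .qc_metrics import QCConfig, detection_gain, filter_matrix, region_fractions
from .umi_quant import (
    GeneIndex,
    assign_reads,
    assignments_frame,
    count_umis,
    read_sam,
    reads_from_frame,
    write_mtx,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    gtf: str
    reads: str  # SAM with barcode/UMI in names or tags
    outdir: str
    genome: str | None = None  # FASTA; enables the polyA diagnostic
    mode: str = "nucleus"  # cell | nucleus
    seed: int = 0
    stranded: bool = False
    exon_priority: bool = False
    min_genes_cellmode: int = 400
    min_genes_nucleusmode: int = 300
    min_cells_per_gene: int = 10
    polya_min_len: int = 5
    polya_flank: int = 20
    read_length: int = 60

    def validate(self) -> None:
        for name in ("gtf", "reads", "genome"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")
        if self.mode not in ("cell", "nucleus"):
            raise ValueError("mode must be 'cell' or 'nucleus'")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write matrices plus QC/priming reports.

    Returns the manifest (also written as ``manifest.json``).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.digest()
    manifest: dict = {
        "config": asdict(config),
        "config_hash": cfg_hash,
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "outputs": {},
    }

    genes = [derive_introns(g) for g in parse_gtf(config.gtf)]
    write_intervals(genes, "exon", outdir / "exons.bed")
    write_intervals(genes, "intron", outdir / "introns.bed")
    manifest["stages"]["annotation"] = {"n_genes": len(genes)}

    index = GeneIndex(genes)
    reads = list(read_sam(config.reads))
    assignments = assignments_frame(
        assign_reads(reads, index, config.stranded, config.exon_priority)
    )
    fractions = region_fractions(assignments)
    manifest["stages"]["assignment"] = {
        "n_reads": len(assignments),
        "region_fractions": fractions,
    }

    gene_ids = sorted(g.gene_id for g in genes)
    cells = sorted(assignments["cell"].unique())
    exon_mat = count_umis(assignments, "exon_only", gene_ids, cells)
    both_mat = count_umis(assignments, "exon_plus_intron", gene_ids, cells)
    write_mtx(exon_mat, outdir / "counts_exon")
    write_mtx(both_mat, outdir / "counts_exon_intron")

    qc_config = QCConfig(
        min_genes_cellmode=config.min_genes_cellmode,
        min_genes_nucleusmode=config.min_genes_nucleusmode,
        min_cells_per_gene=config.min_cells_per_gene,
    )
    filtered = filter_matrix(both_mat, qc_config, config.mode)
    write_mtx(filtered, outdir / "counts_filtered")
    _ratios, mean_gain, n_inf = detection_gain(exon_mat, both_mat)
    qc_report = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "mode": config.mode,
        "n_cells_raw": len(both_mat.cell_barcodes),
        "n_cells_filtered": len(filtered.cell_barcodes),
        "n_genes_filtered": len(filtered.gene_ids),
        "region_fractions": fractions,
        "mean_detection_gain": mean_gain,
        "cells_without_exon_detection": n_inf,
    }
    (outdir / "qc_report.json").write_text(json.dumps(qc_report, indent=2))
    manifest["stages"]["qc"] = qc_report

    if config.genome is not None:
        tracts = scan_polya(config.genome, config.polya_min_len)
        write_tracts_bed(tracts, outdir / "polya_tracts.bed")
        intronic = reads_from_frame(assignments[assignments["region"] == "intronic"])
        hits = intersect_intronic(tracts, intronic, flank=config.polya_flank)
        hist = motif_position_histogram(
            hits, read_len=config.read_length, flank=config.polya_flank
        )
        enrichment = three_prime_enrichment(hist)
        priming_report = {
            "config_hash": cfg_hash,
            "n_tracts": len(tracts),
            "n_intronic_reads": len(intronic),
            "polya_read_fraction": polya_read_fraction(hits, intronic)
            if intronic
            else None,
            # finite ratio, or None when one half of the axis is empty
            "three_prime_enrichment": enrichment if math.isfinite(enrichment) else None,
            "three_prime_mass_share": (
                float(hist.counts[(hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2 > hist.read_len / 2].sum() / hist.total)
                if hist.total
                else None
            ),
        }
        (outdir / "priming_report.json").write_text(json.dumps(priming_report, indent=2))
        pd.DataFrame(
            {
                "bin_start": hist.bin_edges[:-1].astype(int),
                "bin_end": hist.bin_edges[1:].astype(int),
                "count": hist.counts,
            }
        ).to_csv(outdir / "priming_histogram.tsv", sep="\t", index=False)
        manifest["stages"]["priming"] = priming_report

    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _checksum(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
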