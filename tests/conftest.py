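from dataclasses import dataclass

import pandas as pd
import pytest

from nucquant.genome_annotation import GeneModel, GenomicInterval, derive_introns
from nucquant.synthetic_data import SimulationConfig, simulate, truth_reads
from nucquant.umi_quant import (
    CountMatrix,
    GeneIndex,
    assign_reads,
    assignments_frame,
    count_umis,
    read_sam,
    write_sam,
)


def make_gene(gene_id, span, exons, chrom="chr1", strand="+", biotype=""):
    """Construct a GeneModel from plain (start, end) tuples, introns derived."""
    gene = GeneModel(
        gene_id=gene_id,
        span=GenomicInterval(chrom, *span, strand),
        exons=[GenomicInterval(chrom, s, e, strand) for s, e in exons],
        biotype=biotype,
    )
    return derive_introns(gene)


@dataclass
class PipelineRun:
    """A nucleus-mode simulation pushed through the full pipeline."""

    data: object
    assignments: pd.DataFrame
    exon_matrix: CountMatrix
    both_matrix: CountMatrix


@pytest.fixture(scope="session")
def nucleus_run(tmp_path_factory) -> PipelineRun:
    """500 nuclei at study-condition defaults (~721 mean UMIs, 50% intronic
    reads, 40% internal priming), written to SAM and re-read, assigned and
    counted in both modes. Built once per session; several recovery tests
    share it."""
    config = SimulationConfig(seed=20, n_cells=500)
    data = simulate(config)
    sam = tmp_path_factory.mktemp("nucleus_sim") / "reads.sam"
    write_sam(truth_reads(data.truth), data.chrom_lengths, sam)
    reads = list(read_sam(sam))
    index = GeneIndex(data.genes)
    assignments = assignments_frame(assign_reads(reads, index))
    gene_ids = sorted(g.gene_id for g in data.genes)
    cells = sorted(assignments["cell"].unique())
    exon_matrix = count_umis(assignments, "exon_only", gene_ids, cells)
    both_matrix = count_umis(assignments, "exon_plus_intron", gene_ids, cells)
    return PipelineRun(data, assignments, exon_matrix, both_matrix)
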