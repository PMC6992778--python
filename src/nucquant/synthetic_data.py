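"""Synthetic genomes, annotations, and barcoded aligned reads with known truth.

The generator emulates the two library types being compared: "cell" mode
(whole-cell droplet RNA-seq; mostly exonic reads, ~7% intronic,
mitochondrial/ribosomal genes enriched, mean 1474 UMIs per cell) and
"nucleus" mode (single-nucleus RNA-seq; ~50% intronic reads from unspliced
transcripts, lncRNA genes enriched, mean 721 UMIs per nucleus). It plants
polyA tracts inside introns and emits a configurable fraction of intronic
reads with their 3' ends at a tract, mimicking internal priming. Optional
two-species mixing and doublet barcodes support barnyard-style doublet
estimation.

Everything is deterministic under the config seed, and a per-read truth
table records cell, gene, UMI, region, priming flag, and species, so each
pipeline stage can be checked against the generated ground truth.

Geometry guarantees that make truth recovery exact rather than
approximate: background sequence carries no A/T run at the polyA scan
threshold (runs are capped at 4 bp) unless ``tract_free_background`` is
off; genes do not overlap; every gene has at least two introns; tracts
live only in the first intron, primed reads are placed at those tracts,
and non-primed intronic reads go to later introns, out of flanking reach
of any tract.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .genome_annotation import GeneModel, GenomicInterval, derive_introns
from .polya_diagnostics import PolyATract
from .umi_quant import AlignedRead, reads_from_frame

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulatedData",
    "make_genome_and_annotation",
    "simulate_expression",
    "simulate_reads",
    "simulate",
    "truth_reads",
    "write_fasta",
    "write_gtf",
    "write_truth",
    "write_fastq_pairs",
]

BASES = np.array(list("ACGT"))

# study-condition defaults per library mode
MODE_DEFAULTS = {
    "cell": {"mean_umis_per_cell": 1474.0, "intronic_fraction": 0.07},
    "nucleus": {"mean_umis_per_cell": 721.0, "intronic_fraction": 0.50},
}


@dataclass
class SimulationConfig:
    seed: int
    mode: str = "nucleus"  # cell | nucleus
    n_chroms: int = 2
    chrom_length: int = 150_000
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (3, 5)
    n_cells: int = 100
    mean_umis_per_cell: float | None = None  # mode default if None
    intronic_fraction: float | None = None  # mode default if None
    internal_priming_rate: float = 0.4
    tracts_per_gene: int = 2
    tract_length: tuple[int, int] = (8, 15)
    lncRNA_fraction: float = 0.15
    lnc_enrichment: float = 4.0
    mito_fraction: float = 0.05
    ribo_fraction: float = 0.10
    cyto_enrichment: float = 4.0
    doublet_rate: float = 0.0
    species_mixing_fraction: float = 0.0
    read_length: int = 60
    flank: int = 20
    duplicate_mean: float = 0.3  # extra PCR reads per molecule (Poisson)
    n_populations: int = 1
    population_de_fraction: float = 0.3
    population_effect: float = 8.0
    tract_free_background: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODE_DEFAULTS:
            raise ValueError("mode must be 'cell' or 'nucleus'")
        for name in (
            "internal_priming_rate",
            "lncRNA_fraction",
            "mito_fraction",
            "ribo_fraction",
            "doublet_rate",
            "species_mixing_fraction",
            "population_de_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def mean_umis(self) -> float:
        if self.mean_umis_per_cell is not None:
            return self.mean_umis_per_cell
        return MODE_DEFAULTS[self.mode]["mean_umis_per_cell"]

    @property
    def intronic_frac(self) -> float:
        if self.intronic_fraction is not None:
            return self.intronic_fraction
        return MODE_DEFAULTS[self.mode]["intronic_fraction"]

    def rng(self, stage: int) -> np.random.Generator:
        """Independent, reproducible stream per pipeline stage."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stage]))


@dataclass
class SimulatedData:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    tracts: list[PolyATract]
    gene_meta: pd.DataFrame  # gene_id, biotype, chrom, strand
    counts: pd.DataFrame  # true molecules, genes x cell indices
    cell_meta: pd.DataFrame  # cell_index, barcode, population, species
    truth: pd.DataFrame  # one row per emitted read

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def _random_background(rng: np.random.Generator, length: int, cap_runs: bool) -> str:
    seq = "".join(BASES[rng.integers(0, 4, size=length)])
    if cap_runs:
        # break every A/T homopolymer at 4 bp so no background polyA tract
        # reaches the scan threshold of 5
        seq = re.sub(r"A{5,}", lambda m: _break_run(m.group(0), "G"), seq)
        seq = re.sub(r"T{5,}", lambda m: _break_run(m.group(0), "C"), seq)
    return seq


def _break_run(run: str, filler: str) -> str:
    out = []
    for i, ch in enumerate(run):
        out.append(filler if (i + 1) % 5 == 0 else ch)
    return "".join(out)


def _biotype_labels(rng: np.random.Generator, config: SimulationConfig) -> list[str]:
    n = config.n_genes
    n_lnc = int(round(config.lncRNA_fraction * n))
    n_mito = int(round(config.mito_fraction * n))
    n_ribo = int(round(config.ribo_fraction * n))
    labels = (
        ["lncRNA"] * n_lnc
        + ["mitochondrial"] * n_mito
        + ["ribosomal"] * n_ribo
        + ["protein_coding"] * (n - n_lnc - n_mito - n_ribo)
    )
    rng.shuffle(labels)
    return labels


def make_genome_and_annotation(config: SimulationConfig):
    """Build the toy genome, gene models (introns derived), planted polyA
    tracts, and gene metadata.

    Genes are laid out sequentially without overlap; the first intron of
    each gene carries ``tracts_per_gene`` planted tracts on the gene's
    transcribed strand (A-runs for + genes, T-runs for - genes) with >=
    ``read_length + flank`` clearance to the intron boundaries.
    """
    rng = config.rng(0)
    rlen, flank = config.read_length, config.flank
    exon_len_range = (max(100, rlen + 20), 220)
    intron_len_range = (max(300, rlen + 2 * flank + 40), 520)
    tract_slot = 200  # spacing between planted tracts in the first intron
    first_intron_len = 2 * (rlen + flank + 20) + config.tracts_per_gene * tract_slot

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    biotypes = _biotype_labels(rng, config)
    genes: list[GeneModel] = []
    tracts: list[PolyATract] = []
    planted: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chrom_names}
    gene_tracts: dict[str, list[PolyATract]] = {}

    cursor = {c: 500 for c in chrom_names}
    chrom_cycle = 0
    for g in range(config.n_genes):
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        if n_exons < 3:
            raise ValueError("genes need >= 3 exons so tract-free introns exist")
        strand = "+" if rng.random() < 0.5 else "-"
        exon_lens = rng.integers(*exon_len_range, size=n_exons)
        intron_lens = rng.integers(*intron_len_range, size=n_exons - 1)
        intron_lens[0] = first_intron_len
        length = int(exon_lens.sum() + intron_lens.sum())

        chrom = chrom_names[chrom_cycle % config.n_chroms]
        tried = 0
        while cursor[chrom] + length + 500 > config.chrom_length:
            chrom_cycle += 1
            tried += 1
            if tried > config.n_chroms:
                raise ValueError(
                    "genes do not fit on the configured chromosomes; "
                    "increase chrom_length or n_chroms"
                )
            chrom = chrom_names[chrom_cycle % config.n_chroms]
        start = cursor[chrom]
        exons = []
        pos = start
        first_intron: GenomicInterval | None = None
        for i in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[i]), strand))
            pos += int(exon_lens[i])
            if i < n_exons - 1:
                if i == 0:
                    first_intron = GenomicInterval(
                        chrom, pos, pos + int(intron_lens[i]), strand
                    )
                pos += int(intron_lens[i])
        span = GenomicInterval(chrom, start, pos, strand)
        gid = f"G{g:04d}"
        gene = GeneModel(
            gene_id=gid,
            span=span,
            exons=exons,
            gene_name=f"{biotypes[g][:3].upper()}{g}",
            biotype=biotypes[g],
        )
        derive_introns(gene)
        genes.append(gene)
        cursor[chrom] = pos + 500
        chrom_cycle += 1

        # plant polyA tracts in the first intron
        assert first_intron is not None
        gene_tracts[gid] = []
        base = "A" if strand == "+" else "T"
        offset0 = rlen + flank + 20
        for t in range(config.tracts_per_gene):
            tlen = int(rng.integers(config.tract_length[0], config.tract_length[1] + 1))
            tstart = first_intron.start + offset0 + t * tract_slot
            tract = PolyATract(GenomicInterval(chrom, tstart, tstart + tlen, strand))
            tracts.append(tract)
            gene_tracts[gid].append(tract)
            planted[chrom].append((tstart, tlen, base))

    genome: dict[str, str] = {}
    for chrom in chrom_names:
        seq = list(_random_background(rng, config.chrom_length, config.tract_free_background))
        for tstart, tlen, base in planted[chrom]:
            seq[tstart : tstart + tlen] = base * tlen
            # guard bases so the planted run cannot merge with background
            seq[tstart - 1] = "G" if base == "A" else "C"
            seq[tstart + tlen] = "G" if base == "A" else "C"
        genome[chrom] = "".join(seq)

    gene_meta = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "gene_name": [g.gene_name for g in genes],
            "biotype": [g.biotype for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
        }
    ).set_index("gene_id")
    return genome, genes, tracts, gene_meta, gene_tracts


def simulate_expression(config: SimulationConfig, gene_meta: pd.DataFrame):
    """Draw true per-cell molecule counts (gamma-poisson).

    Biotype enrichment mimics compartment sampling: nucleus mode up-weights
    lncRNA genes, cell mode up-weights mitochondrial/ribosomal genes. With
    ``n_populations > 1``, a fraction of genes is perturbed per population
    so cell populations have distinct reference profiles.
    """
    rng = config.rng(1)
    n_genes = len(gene_meta)
    base = rng.gamma(0.7, 1.0, size=n_genes) + 0.01
    biotype = gene_meta["biotype"].to_numpy()
    if config.mode == "nucleus":
        base[biotype == "lncRNA"] *= config.lnc_enrichment
    else:
        base[np.isin(biotype, ["mitochondrial", "ribosomal"])] *= config.cyto_enrichment

    pop_weights = []
    n_de = int(round(config.population_de_fraction * n_genes))
    de_genes = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], int)
    for p in range(config.n_populations):
        w = base.copy()
        if config.n_populations > 1 and n_de:
            up = de_genes[p::config.n_populations]
            w[up] *= config.population_effect
        pop_weights.append(w / w.sum())

    populations = rng.integers(0, config.n_populations, size=config.n_cells)
    totals = rng.gamma(8.0, config.mean_umis / 8.0, size=config.n_cells)
    counts = np.empty((n_genes, config.n_cells), dtype=np.int64)
    overdisp = rng.gamma(2.0, 0.5, size=(n_genes, config.n_cells))
    for c in range(config.n_cells):
        rate = pop_weights[populations[c]] * totals[c] * overdisp[:, c]
        counts[:, c] = rng.poisson(rate)

    # barcodes: unique random 12-mers; doublet barcodes shared by two cells,
    # sized so doublets are the configured fraction of observed barcodes
    n_doublets = int(round(config.doublet_rate * config.n_cells / (1 + config.doublet_rate)))
    n_barcodes = config.n_cells - n_doublets
    barcodes: list[str] = []
    seen: set[str] = set()
    while len(barcodes) < n_barcodes:
        b = "".join(BASES[rng.integers(0, 4, size=12)])
        if b not in seen:
            seen.add(b)
            barcodes.append(b)
    cell_barcodes = list(barcodes)
    for d in range(n_doublets):
        cell_barcodes.append(barcodes[d])  # cell n_barcodes+d shares barcode d

    species = np.where(
        rng.random(config.n_cells) < config.species_mixing_fraction, "speciesB", "speciesA"
    )
    cell_meta = pd.DataFrame(
        {
            "cell_index": np.arange(config.n_cells),
            "barcode": cell_barcodes,
            "population": populations,
            "species": species,
        }
    )
    counts_df = pd.DataFrame(
        counts, index=gene_meta.index, columns=np.arange(config.n_cells)
    )
    return counts_df, cell_meta


def _random_umis(rng: np.random.Generator, n: int) -> np.ndarray:
    codes = rng.integers(0, 4, size=(n, 8))
    return np.array(["".join(BASES[row]) for row in codes])


def simulate_reads(
    config: SimulationConfig,
    genes: list[GeneModel],
    gene_tracts: dict[str, list[PolyATract]],
    counts: pd.DataFrame,
    cell_meta: pd.DataFrame,
) -> pd.DataFrame:
    """Emit aligned reads for every true molecule; returns the truth table.

    Each molecule yields ``1 + Poisson(duplicate_mean)`` identical reads
    sharing (cell, UMI, position). Region and priming are drawn per
    molecule: intronic with probability ``intronic_frac``; of intronic
    molecules, primed with probability ``internal_priming_rate``. Primed
    reads end at a planted tract of the gene; non-primed intronic reads are
    placed in tract-free introns; exonic reads fall inside a single exon.
    """
    rng = config.rng(2)
    rlen = config.read_length
    gene_by_id = {g.gene_id: g for g in genes}
    barcode = cell_meta.set_index("cell_index")["barcode"]
    species = cell_meta.set_index("cell_index")["species"]

    frames = []
    for gid, row in counts.iterrows():
        gene = gene_by_id[gid]
        cells = np.repeat(row.index.to_numpy(), row.to_numpy())
        n_mol = cells.size
        if n_mol == 0:
            continue
        if config.intronic_frac > 0 and len(gene.introns or []) < 2:
            logger.warning(
                "gene %s lacks tract-free introns; skipped under intronic "
                "fraction %.2f",
                gid,
                config.intronic_frac,
            )
            continue
        umis = _random_umis(rng, n_mol)
        intronic = rng.random(n_mol) < config.intronic_frac
        primed = intronic & (rng.random(n_mol) < config.internal_priming_rate)

        starts = np.empty(n_mol, dtype=np.int64)
        # exonic molecules: uniform start inside a uniformly chosen exon
        ex_idx = np.flatnonzero(~intronic)
        if ex_idx.size:
            exon_choice = rng.integers(0, len(gene.exons), size=ex_idx.size)
            for k, exon in enumerate(gene.exons):
                sel = ex_idx[exon_choice == k]
                starts[sel] = rng.integers(exon.start, exon.end - rlen + 1, size=sel.size)
        # non-primed intronic molecules: uniform inside a tract-free intron
        free_introns = gene.introns[1:]
        un_idx = np.flatnonzero(intronic & ~primed)
        if un_idx.size:
            intron_choice = rng.integers(0, len(free_introns), size=un_idx.size)
            for k, intron in enumerate(free_introns):
                sel = un_idx[intron_choice == k]
                starts[sel] = rng.integers(
                    intron.start, intron.end - rlen + 1, size=sel.size
                )
        # primed molecules: 3' end overlapping a planted tract
        pr_idx = np.flatnonzero(primed)
        if pr_idx.size:
            tlist = gene_tracts[gid]
            tract_choice = rng.integers(0, len(tlist), size=pr_idx.size)
            overlap = rng.integers(1, 5, size=pr_idx.size)  # 1-4 bp into tract
            for k, tract in enumerate(tlist):
                sel = pr_idx[tract_choice == k]
                u = overlap[tract_choice == k]
                if gene.strand == "+":
                    # read 3' end = genomic end, u bases into the tract
                    starts[sel] = tract.interval.start + u - rlen
                else:
                    # read 3' end = genomic start
                    starts[sel] = tract.interval.end - u

        dup = 1 + rng.poisson(config.duplicate_mean, size=n_mol)
        rep = np.repeat(np.arange(n_mol), dup)
        frames.append(
            pd.DataFrame(
                {
                    "cell_index": cells[rep],
                    "gene": gid,
                    "umi": umis[rep],
                    "region": np.where(intronic[rep], "intronic", "exonic"),
                    "primed": primed[rep],
                    "chrom": gene.chrom,
                    "start": starts[rep],
                    "end": starts[rep] + rlen,
                    "strand": gene.strand,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "cell_index", "gene", "umi", "region", "primed",
                "chrom", "start", "end", "strand", "cell", "species",
            ]
        )
    truth = pd.concat(frames, ignore_index=True)
    truth["cell"] = truth["cell_index"].map(barcode)
    truth["species"] = truth["cell_index"].map(species)
    # coordinate-sorted, like an aligner's output
    truth = truth.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return truth


def simulate(config: SimulationConfig) -> SimulatedData:
    """Run the full generator: genome, annotation, expression, reads."""
    genome, genes, tracts, gene_meta, gene_tracts = make_genome_and_annotation(config)
    counts, cell_meta = simulate_expression(config, gene_meta)
    truth = simulate_reads(config, genes, gene_tracts, counts, cell_meta)
    return SimulatedData(config, genome, genes, tracts, gene_meta, counts, cell_meta, truth)


def truth_reads(truth: pd.DataFrame) -> list[AlignedRead]:
    """Materialize the truth table as aligned read records."""
    return reads_from_frame(truth)


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gtf(genes: list[GeneModel], path) -> None:
    """Emit gene and exon features (1-based closed, per GTF convention)."""
    with open(path, "w") as fh:
        for gene in genes:
            attr = (
                f'gene_id "{gene.gene_id}"; gene_name "{gene.gene_name}"; '
                f'gene_biotype "{gene.biotype}";'
            )
            fh.write(
                f"{gene.chrom}\tnucquant_sim\tgene\t{gene.span.start + 1}\t"
                f"{gene.span.end}\t.\t{gene.strand}\t.\t{attr}\n"
            )
            for exon in gene.exons:
                fh.write(
                    f"{gene.chrom}\tnucquant_sim\texon\t{exon.start + 1}\t"
                    f"{exon.end}\t.\t{gene.strand}\t.\t{attr}\n"
                )


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_fastq_pairs(truth: pd.DataFrame, genome: dict[str, str], path1, path2) -> int:
    """Emit the reads as a barcoded read pair: R1 = barcode + UMI, R2 = the
    read sequence from the genome (reverse-complemented for - strand)."""
    comp = str.maketrans("ACGTN", "TGCAN")
    n = 0
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for i, row in enumerate(truth.itertuples()):
            r1 = f"{row.cell}{row.umi}"
            seq = genome[row.chrom][row.start : row.end]
            if row.strand == "-":
                seq = seq.translate(comp)[::-1]
            f1.write(f"@read{i}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@read{i}/2\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n
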