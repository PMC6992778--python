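"""Feature assignment of aligned reads and UMI-deduplicated counting.

Each aligned read (an interval on the reference, carrying a cell barcode
and UMI) is assigned to a gene and a region class:

* ``exonic``  — overlaps exon intervals of exactly one gene;
* ``intronic`` — overlaps intron intervals of exactly one gene and exons
  of none;
* ``ambiguous`` — overlaps features of two or more distinct genes;
* ``intergenic`` — overlaps nothing.

Counting collapses reads to distinct (cell, gene, UMI) molecules. In
``exon_plus_intron`` mode a gene's count is the number of distinct UMIs
over its exonic and intronic reads together, so a UMI seen in both regions
of the same gene counts once; this is the intron-inclusive quantification
that raises gene detection in single-nucleus libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import pysam
import scipy.io
import scipy.sparse as sp
from intervaltree import IntervalTree

from .genome_annotation import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedRead",
    "FeatureAssignment",
    "CountMatrix",
    "GeneIndex",
    "REGIONS",
    "assign_read",
    "assign_reads",
    "assignments_frame",
    "reads_from_frame",
    "count_umis",
    "merge_matrices",
    "write_mtx",
    "read_mtx",
    "read_sam",
    "write_sam",
]

REGIONS = ("exonic", "intronic", "ambiguous", "intergenic")


@dataclass(frozen=True)
class AlignedRead:
    cell_barcode: str
    umi: str
    interval: GenomicInterval
    species: str | None = None
    is_primary: bool = True

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class FeatureAssignment:
    read: AlignedRead
    gene_id: str | None
    region: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if (self.gene_id is None) != (self.region in ("ambiguous", "intergenic")):
            raise ValueError("gene_id must be set iff region is exonic/intronic")


class GeneIndex:
    """Interval index over gene exon and intron features, per chromosome."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._exons: dict[str, IntervalTree] = {}
        self._introns: dict[str, IntervalTree] = {}
        self._warned: set[str] = set()
        for gene in genes:
            if gene.introns is None:
                raise ValueError(
                    f"introns of {gene.gene_id!r} not derived; run derive_introns"
                )
            etree = self._exons.setdefault(gene.chrom, IntervalTree())
            itree = self._introns.setdefault(gene.chrom, IntervalTree())
            for iv in gene.exons:
                etree[iv.start : iv.end] = (gene.gene_id, gene.strand)
            for iv in gene.introns:
                itree[iv.start : iv.end] = (gene.gene_id, gene.strand)

    def overlapping(self, read: AlignedRead, stranded: bool):
        """Gene id sets with exonic / intronic overlap for the read."""
        iv = read.interval
        exonic: set[str] = set()
        intronic: set[str] = set()
        etree = self._exons.get(iv.chrom)
        itree = self._introns.get(iv.chrom)
        if etree is None and itree is None:
            if iv.chrom not in self._warned:
                self._warned.add(iv.chrom)
                logger.warning("read on unknown chromosome %r -> intergenic", iv.chrom)
            return exonic, intronic
        for hit in etree.overlap(iv.start, iv.end) if etree else ():
            gid, strand = hit.data
            if not stranded or strand == iv.strand:
                exonic.add(gid)
        for hit in itree.overlap(iv.start, iv.end) if itree else ():
            gid, strand = hit.data
            if not stranded or strand == iv.strand:
                intronic.add(gid)
        return exonic, intronic


def assign_read(
    read: AlignedRead,
    index: GeneIndex,
    stranded: bool = False,
    exon_priority: bool = False,
) -> FeatureAssignment:
    """Assign one read to (gene, region).

    Within one gene exon overlap takes precedence over intron overlap.
    Across genes the default is conservative: any second gene with feature
    overlap makes the read ambiguous. With ``exon_priority``, a single
    exonically-overlapped gene wins over other genes' introns.
    """
    exonic, intronic = index.overlapping(read, stranded)
    genes = exonic | intronic
    if not genes:
        return FeatureAssignment(read, None, "intergenic")
    if len(genes) == 1:
        gid = next(iter(genes))
        return FeatureAssignment(read, gid, "exonic" if gid in exonic else "intronic")
    if exon_priority and len(exonic) == 1:
        return FeatureAssignment(read, next(iter(exonic)), "exonic")
    return FeatureAssignment(read, None, "ambiguous")


def assign_reads(
    reads: Iterable[AlignedRead],
    index: GeneIndex,
    stranded: bool = False,
    exon_priority: bool = False,
) -> Iterator[FeatureAssignment]:
    for read in reads:
        if not read.is_primary:
            continue
        yield assign_read(read, index, stranded, exon_priority)


def assignments_frame(assignments: Iterable[FeatureAssignment]) -> pd.DataFrame:
    """Tabulate assignments: one row per read with barcode, UMI, gene, region."""
    rows = [
        (a.read.cell_barcode, a.read.umi, a.gene_id, a.region,
         a.read.chrom, a.read.interval.start, a.read.interval.end, a.read.strand)
        for a in assignments
    ]
    return pd.DataFrame(
        rows,
        columns=["cell", "umi", "gene", "region", "chrom", "start", "end", "strand"],
    )


def reads_from_frame(df: pd.DataFrame) -> list[AlignedRead]:
    """Materialize a read table (columns cell, umi, chrom, start, end,
    strand, optionally species) as :class:`AlignedRead` records."""
    has_species = "species" in df.columns
    return [
        AlignedRead(
            row.cell,
            row.umi,
            GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
            species=getattr(row, "species", None) if has_species else None,
        )
        for row in df.itertuples()
    ]


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with its counting mode."""

    gene_ids: list[str]
    cell_barcodes: list[str]
    counts: sp.csr_matrix
    mode: str  # exon_only | exon_plus_intron

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_barcodes)):
            raise ValueError("count matrix shape does not match id lists")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.toarray(), index=self.gene_ids, columns=self.cell_barcodes
        )


def count_umis(
    assignments: Iterable[FeatureAssignment] | pd.DataFrame,
    mode: str = "exon_plus_intron",
    gene_ids: list[str] | None = None,
    cell_barcodes: list[str] | None = None,
) -> CountMatrix:
    """Count distinct UMIs per (gene, cell) over the admitted regions.

    ``mode='exon_only'`` admits exonic reads; ``'exon_plus_intron'`` admits
    exonic and intronic. Ambiguous and intergenic reads contribute nothing.
    Optional ``gene_ids``/``cell_barcodes`` fix the axis order (genes or
    cells without any admitted read appear as zero rows/columns).
    """
    if mode == "exon_only":
        admitted = {"exonic"}
    elif mode == "exon_plus_intron":
        admitted = {"exonic", "intronic"}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not isinstance(assignments, pd.DataFrame):
        assignments = assignments_frame(assignments)
    df = assignments[assignments["region"].isin(admitted)]
    # distinct (cell, gene, UMI) molecules; region membership collapses here
    mol = df.drop_duplicates(["cell", "gene", "umi"])
    counts = mol.groupby(["gene", "cell"], sort=True).size()
    if gene_ids is None:
        gene_ids = sorted(df["gene"].unique())
    if cell_barcodes is None:
        cell_barcodes = sorted(df["cell"].unique())
    gi = {g: i for i, g in enumerate(gene_ids)}
    ci = {c: i for i, c in enumerate(cell_barcodes)}
    rows, cols, data = [], [], []
    for (g, c), n in counts.items():
        if g in gi and c in ci:
            rows.append(gi[g])
            cols.append(ci[c])
            data.append(n)
    mat = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(gene_ids), len(cell_barcodes)), dtype=np.int64
    )
    return CountMatrix(list(gene_ids), list(cell_barcodes), mat, mode)


def merge_matrices(
    matrices: list[CountMatrix], suffixes: list[str] | None = None
) -> CountMatrix:
    """Merge runs: gene set is the union, missing entries are zero, columns
    are concatenated in input order. Duplicate barcodes across runs are an
    error unless per-run ``suffixes`` disambiguate them."""
    if not matrices:
        raise ValueError("nothing to merge")
    mode = matrices[0].mode
    if any(m.mode != mode for m in matrices):
        raise ValueError("cannot merge matrices with different counting modes")
    if suffixes is not None and len(suffixes) != len(matrices):
        raise ValueError("need one suffix per matrix")
    barcodes: list[str] = []
    for i, m in enumerate(matrices):
        bc = m.cell_barcodes
        if suffixes is not None:
            bc = [f"{b}{suffixes[i]}" for b in bc]
        barcodes.extend(bc)
    from collections import Counter

    dup = {b for b, n in Counter(barcodes).items() if n > 1}
    if dup:
        raise ValueError(f"duplicate barcodes across runs: {sorted(dup)[:10]}")
    genes = sorted(set().union(*(m.gene_ids for m in matrices)))
    gi = {g: i for i, g in enumerate(genes)}
    blocks = []
    for m in matrices:
        lift = sp.csr_matrix(
            (np.ones(len(m.gene_ids)), ([gi[g] for g in m.gene_ids], range(len(m.gene_ids)))),
            shape=(len(genes), len(m.gene_ids)),
        )
        blocks.append(lift @ m.counts)
    merged = sp.hstack(blocks, format="csr").astype(np.int64)
    return CountMatrix(genes, barcodes, merged, mode)


def write_mtx(matrix: CountMatrix, prefix) -> None:
    """Write MatrixMarket coordinate file plus gene and barcode lists:
    ``<prefix>.mtx``, ``<prefix>.genes.tsv``, ``<prefix>.barcodes.tsv``."""
    prefix = str(prefix)
    scipy.io.mmwrite(prefix + ".mtx", matrix.counts, field="integer")
    with open(prefix + ".genes.tsv", "w") as fh:
        fh.writelines(g + "\n" for g in matrix.gene_ids)
    with open(prefix + ".barcodes.tsv", "w") as fh:
        fh.writelines(b + "\n" for b in matrix.cell_barcodes)


def read_mtx(prefix, mode: str = "exon_plus_intron") -> CountMatrix:
    prefix = str(prefix)
    mat = sp.csr_matrix(scipy.io.mmread(prefix + ".mtx"))
    with open(prefix + ".genes.tsv") as fh:
        genes = [line.strip() for line in fh if line.strip()]
    with open(prefix + ".barcodes.tsv") as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match id files "
            f"({len(genes)} genes, {len(barcodes)} barcodes)"
        )
    return CountMatrix(genes, barcodes, mat.astype(np.int64), mode)


SPECIES_TAG = "ZS"


def read_sam(path) -> Iterator[AlignedRead]:
    """Read aligned records; barcode/UMI from ``cb_umi_serial`` read names
    or CB/UB tags. Secondary/supplementary alignments are flagged
    non-primary; unmapped records are dropped."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.has_tag("CB") and rec.has_tag("UB"):
                cb, umi = rec.get_tag("CB"), rec.get_tag("UB")
            else:
                parts = rec.query_name.split("_")
                if len(parts) < 2:
                    raise ValueError(
                        f"read name {rec.query_name!r} carries no barcode/UMI"
                    )
                cb, umi = parts[0], parts[1]
            iv = GenomicInterval(
                rec.reference_name,
                rec.reference_start,
                rec.reference_end,
                "-" if rec.is_reverse else "+",
            )
            species = rec.get_tag(SPECIES_TAG) if rec.has_tag(SPECIES_TAG) else None
            yield AlignedRead(
                cb,
                umi,
                iv,
                species=species,
                is_primary=not (rec.is_secondary or rec.is_supplementary),
            )


def write_sam(reads: Iterable[AlignedRead], chrom_lengths: dict[str, int], path) -> int:
    """Write reads as a plain-text SAM file with full-match CIGARs.

    Barcode and UMI are embedded in the read name (``cb_umi_serial``);
    species, when set, goes into the ``ZS`` tag.
    """
    n = 0
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unsorted\n")
        for c, ln in chrom_lengths.items():
            out.write(f"@SQ\tSN:{c}\tLN:{int(ln)}\n")
        for i, r in enumerate(reads):
            flag = 16 if r.strand == "-" else 0
            length = len(r.interval)
            tags = f"\t{SPECIES_TAG}:Z:{r.species}" if r.species is not None else ""
            out.write(
                f"{r.cell_barcode}_{r.umi}_{i}\t{flag}\t{r.chrom}\t"
                f"{r.interval.start + 1}\t255\t{length}M\t*\t0\t0\t*\t*{tags}\n"
            )
            n += 1
    return n
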