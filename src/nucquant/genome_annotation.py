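"""Gene annotation parsing and strand-aware intron derivation.

Droplet 3'-tagged RNA-seq of nuclei samples unspliced transcripts, so a
large share of reads fall in introns. Standard annotations (e.g. GENCODE)
carry gene and exon features but no intron features; introns are derived
here by subtracting the per-gene exon union from the gene span on the same
strand. The remainder intervals are the gene's introns, and exon + intron
intervals tile the span exactly.

Coordinates are 0-based half-open internally; GTF's 1-based closed
convention is converted at the I/O boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "GtfError",
    "merge_intervals",
    "subtract_intervals",
    "parse_gtf",
    "derive_introns",
    "write_intervals",
    "read_bed",
]

STRANDS = ("+", "-")


class GtfError(ValueError):
    """Raised for malformed or inconsistent GTF input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene's span, merged exon union, and derived introns.

    ``exons`` is the union over all transcripts of the gene. ``introns`` is
    ``None`` until :func:`derive_introns` runs; afterwards exons and introns
    are disjoint and tile the span.
    """

    gene_id: str
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    introns: list[GenomicInterval] | None = None
    gene_name: str = ""
    biotype: str = ""

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    def has_introns(self) -> bool:
        return bool(self.introns)


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or adjacent same-chrom/strand intervals.

    Input intervals must all share chrom and strand (as a gene's exons do).
    """
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = replace(last, end=iv.end)
        else:
            merged.append(iv)
    return merged


def subtract_intervals(
    span: GenomicInterval, blocks: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Return ``span`` minus a merged, sorted block list (interval algebra)."""
    out: list[GenomicInterval] = []
    cursor = span.start
    for b in blocks:
        if b.start > cursor:
            out.append(replace(span, start=cursor, end=b.start))
        cursor = max(cursor, b.end)
    if cursor < span.end:
        out.append(replace(span, start=cursor, end=span.end))
    return out


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    if "gene_id" not in attrs:
        raise GtfError(f"line {lineno}: no gene_id in attribute field {attr_field!r}")
    return attrs


def parse_gtf(path) -> list[GeneModel]:
    """Parse gene and exon features from a GTF file into :class:`GeneModel`\\ s.

    Exons of each gene are merged into their union; introns are left
    underived. GTF 1-based closed coordinates become 0-based half-open.

    Raises :class:`GtfError` on an exon whose ``gene_id`` has no gene line,
    an exon outside its gene's span, or a malformed attribute field.
    """
    genes: dict[str, GeneModel] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    exon_lines: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature not in ("gene", "exon"):
                continue
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise GtfError(f"line {lineno}: {exc}") from exc
            attrs = _parse_attributes(attr, lineno)
            gid = attrs["gene_id"]
            if feature == "gene":
                if gid in genes:
                    raise GtfError(f"line {lineno}: duplicate gene line for {gid!r}")
                genes[gid] = GeneModel(
                    gene_id=gid,
                    span=iv,
                    gene_name=attrs.get("gene_name", gid),
                    biotype=attrs.get("gene_biotype", attrs.get("gene_type", "")),
                )
            else:
                exons.setdefault(gid, []).append(iv)
                exon_lines.setdefault(gid, lineno)
    for gid, ivs in exons.items():
        if gid not in genes:
            raise GtfError(
                f"line {exon_lines[gid]}: exon references gene_id {gid!r} "
                "with no gene feature line"
            )
        gene = genes[gid]
        for iv in ivs:
            if iv.chrom != gene.chrom or iv.strand != gene.strand:
                raise GtfError(
                    f"exon of {gid!r} on {iv.chrom}{iv.strand} does not match "
                    f"gene on {gene.chrom}{gene.strand}"
                )
            if iv.start < gene.span.start or iv.end > gene.span.end:
                raise GtfError(
                    f"exon [{iv.start}, {iv.end}) of {gid!r} outside gene span "
                    f"[{gene.span.start}, {gene.span.end})"
                )
        gene.exons = merge_intervals(ivs)
    return list(genes.values())


def derive_introns(gene: GeneModel) -> GeneModel:
    """Populate ``gene.introns`` as span minus the exon union.

    Idempotent; a single-exon gene covering its span gets an empty intron
    list. Returns the same (mutated) object for chaining.
    """
    exons = merge_intervals(gene.exons)
    gene.exons = exons
    gene.introns = subtract_intervals(gene.span, exons)
    return gene


def write_intervals(genes: list[GeneModel], which: str, path) -> int:
    """Write exon or intron intervals of ``genes`` as BED6, one line per
    interval, named by gene_id. Returns the number of records written."""
    if which not in ("exon", "intron"):
        raise ValueError("which must be 'exon' or 'intron'")
    n = 0
    with open(path, "w") as fh:
        for gene in genes:
            ivs = gene.exons if which == "exon" else gene.introns
            if which == "intron" and ivs is None:
                raise ValueError(f"introns of {gene.gene_id!r} not derived")
            for iv in ivs or []:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gene.gene_id}\t.\t{iv.strand}\n"
                )
                n += 1
    return n


def read_bed(path) -> list[tuple[str, GenomicInterval]]:
    """Read BED6 back into (name, interval) pairs."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            out.append((name, GenomicInterval(chrom, int(start), int(end), strand.strip())))
    return out
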