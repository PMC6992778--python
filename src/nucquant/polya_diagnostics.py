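"""Genomic polyA tract detection and internal-priming diagnostics.

Oligo-dT priming can initiate reverse transcription at genomically encoded
A-rich stretches instead of the true polyA tail ("internal priming"),
which produces intronic reads whose 3' ends sit next to a polyA tract.
The diagnostic: scan the genome for maximal runs of >= 5 adenines (A-runs
on the forward strand, T-runs standing for A-runs on the reverse strand),
extend intronic reads by 20 bp on each side, intersect strand-specifically,
and histogram the tract 3'-end positions relative to the read. Internal
priming shows as enrichment of tract positions toward the read 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from intervaltree import IntervalTree

from .genome_annotation import GenomicInterval
from .umi_quant import AlignedRead

__all__ = [
    "PolyATract",
    "PrimingHistogram",
    "scan_polya",
    "scan_sequence",
    "intersect_intronic",
    "polya_read_fraction",
    "motif_position_histogram",
    "three_prime_enrichment",
    "write_tracts_bed",
]

MIN_TRACT_LEN = 5


@dataclass(frozen=True)
class PolyATract:
    """A maximal A-run (+) or T-run (-) on the reference."""

    interval: GenomicInterval

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def length(self) -> int:
        return len(self.interval)


def scan_sequence(
    chrom: str, sequence: str, min_len: int = MIN_TRACT_LEN, forward_only: bool = False
) -> list[PolyATract]:
    """Maximal runs of >= ``min_len`` A's (+) and T's (-) in one sequence.

    Case-insensitive; N (or any other letter) breaks a run. Implemented as
    a single linear run-length scan, so merged 5-mers appear exactly once.
    """
    seq = sequence.upper()
    targets = {"A": "+"} if forward_only else {"A": "+", "T": "-"}
    tracts: list[PolyATract] = []
    n = len(seq)
    i = 0
    while i < n:
        base = seq[i]
        if base in targets:
            j = i + 1
            while j < n and seq[j] == base:
                j += 1
            if j - i >= min_len:
                tracts.append(
                    PolyATract(GenomicInterval(chrom, i, j, targets[base]))
                )
            i = j
        else:
            i += 1
    return tracts


def scan_polya(
    genome, min_len: int = MIN_TRACT_LEN, forward_only: bool = False
) -> list[PolyATract]:
    """Scan a genome (FASTA path or chrom->sequence mapping) for polyA
    tracts. Raises on an empty genome."""
    if isinstance(genome, Mapping):
        items = genome.items()
    else:
        items = ((rec.id, str(rec.seq)) for rec in SeqIO.parse(str(genome), "fasta"))
    tracts: list[PolyATract] = []
    n_seqs = 0
    for chrom, seq in items:
        n_seqs += 1
        tracts.extend(scan_sequence(chrom, seq, min_len, forward_only))
    if n_seqs == 0:
        raise ValueError("empty FASTA: no sequences to scan")
    return tracts


def _tract_index(tracts: Iterable[PolyATract]) -> dict[tuple[str, str], IntervalTree]:
    index: dict[tuple[str, str], IntervalTree] = {}
    for t in tracts:
        tree = index.setdefault((t.chrom, t.strand), IntervalTree())
        tree[t.interval.start : t.interval.end] = t
    return index


def intersect_intronic(
    tracts: Iterable[PolyATract],
    intronic_reads: list[AlignedRead],
    flank: int = 20,
    stranded: bool = True,
) -> list[tuple[AlignedRead, PolyATract]]:
    """Intersect reads, extended by ``flank`` bp on each side, with tracts.

    A hit requires same chromosome, interval overlap with the extended read
    and — when ``stranded`` — matching tract and read strand. Callers
    pre-filter reads to the intronic region class.
    """
    index = _tract_index(tracts)
    hits: list[tuple[AlignedRead, PolyATract]] = []
    for read in intronic_reads:
        lo = max(0, read.interval.start - flank)
        hi = read.interval.end + flank
        strands = (read.strand,) if stranded else ("+", "-")
        for strand in strands:
            tree = index.get((read.chrom, strand))
            if tree is None:
                continue
            for hit in sorted(tree.overlap(lo, hi)):
                hits.append((read, hit.data))
    return hits


def polya_read_fraction(
    hits: list[tuple[AlignedRead, PolyATract]], reads: list[AlignedRead]
) -> float:
    """Fraction of reads with at least one tract hit (each read once)."""
    if not reads:
        raise ValueError("no reads")
    with_hit = {id(r) for r, _t in hits}
    return sum(1 for r in reads if id(r) in with_hit) / len(reads)


@dataclass
class PrimingHistogram:
    """Histogram of tract 3'-end offsets relative to read 5' ends.

    Offsets are measured in read orientation: 0 is the read 5' end and
    ``read_len`` its 3' end; the axis covers ``[-flank, read_len + flank]``.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    read_len: int
    flank: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def tract_offset(read: AlignedRead, tract: PolyATract) -> int:
    """Offset of the tract's 3' end from the read's 5' end, in read
    orientation. For a + read the tract 3' end is its genomic end; for a
    - read it is its genomic start and the axis is mirrored."""
    if read.strand == "+":
        return tract.interval.end - read.interval.start
    return read.interval.end - tract.interval.start


def motif_position_histogram(
    hits: list[tuple[AlignedRead, PolyATract]],
    read_len: int = 60,
    flank: int = 20,
    bin_width: int = 5,
) -> PrimingHistogram:
    """Bin tract 3'-end offsets over ``[-flank, read_len + flank]``."""
    offsets = np.array([tract_offset(r, t) for r, t in hits], dtype=float)
    edges = np.arange(-flank, read_len + flank + bin_width, bin_width, dtype=float)
    # clip so every intersecting tract lands in a bin even if its 3' end
    # pokes past the extended window
    if offsets.size:
        offsets = np.clip(offsets, edges[0], edges[-1] - 1e-9)
    counts, _ = np.histogram(offsets, bins=edges)
    return PrimingHistogram(edges, counts, read_len, flank)


def three_prime_enrichment(hist: PrimingHistogram) -> float:
    """Ratio of histogram mass in the 3' half to the 5' half of the axis.

    The axis midpoint is ``read_len / 2``; a value far above 1 indicates
    tracts piling up at read 3' ends, the internal-priming signature.
    Returns ``inf`` when the 5' half is empty but the 3' half is not.
    """
    mid = hist.read_len / 2
    centers = (hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2
    mass3 = hist.counts[centers > mid].sum()
    mass5 = hist.counts[centers <= mid].sum()
    if mass5 == 0:
        return float("inf") if mass3 > 0 else float("nan")
    return float(mass3 / mass5)


def write_tracts_bed(tracts: Iterable[PolyATract], path) -> int:
    n = 0
    with open(path, "w") as fh:
        for i, t in enumerate(tracts):
            fh.write(
                f"{t.chrom}\t{t.interval.start}\t{t.interval.end}\t"
                f"polyA_{i}\t{t.length}\t{t.strand}\n"
            )
            n += 1
    return n
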