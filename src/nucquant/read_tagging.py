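"""Barcode whitelisting, read-pair tagging, and 3' polyA trimming.

In bead-barcoded droplet libraries read 1 carries the 12 bp cell barcode
followed by the 8 bp UMI and read 2 carries the cDNA fragment. Tagging
fuses each pair into a single record whose name embeds barcode and UMI
(``cb_umi_serial``), keeping only barcodes on a whitelist of barcodes with
at least ``min_reads`` reads (default 30,000, the depth expected of a real
cell rather than an ambient-RNA bead).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

__all__ = [
    "TaggedRead",
    "Whitelist",
    "TaggingStats",
    "count_barcodes",
    "build_whitelist",
    "tag_pairs",
    "trim_polya",
    "write_tagged_fastq",
]

CB_LEN = 12
UMI_LEN = 8


@dataclass(frozen=True)
class TaggedRead:
    cell_barcode: str
    umi: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if len(self.cell_barcode) != CB_LEN:
            raise ValueError(f"cell barcode must be {CB_LEN} bp")
        if len(self.umi) != UMI_LEN:
            raise ValueError(f"UMI must be {UMI_LEN} bp")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError("qualities length must match sequence length")


@dataclass
class Whitelist:
    barcodes: frozenset[str]
    min_reads: int

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.barcodes

    def __len__(self) -> int:
        return len(self.barcodes)


@dataclass
class TaggingStats:
    """Read conservation tallies: kept + filtered + skipped = input pairs."""

    kept: int = 0
    filtered: int = 0
    skipped_short: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.filtered + self.skipped_short


def count_barcodes(fastq1, cb_len: int = CB_LEN) -> Counter:
    """Count reads per cell barcode from read-1 FASTQ."""
    counts: Counter = Counter()
    with open(fastq1) as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            counts[seq[:cb_len]] += 1
    return counts


def build_whitelist(barcode_counts, min_reads: int = 30000) -> Whitelist:
    """Keep barcodes seen in at least ``min_reads`` reads.

    Barcodes containing N are excluded (ambiguous bead identity). An empty
    input yields an empty whitelist with a warning, not an error.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be non-negative")
    if not barcode_counts:
        logger.warning("empty barcode count input; whitelist is empty")
        return Whitelist(frozenset(), min_reads)
    kept = frozenset(
        b for b, n in barcode_counts.items() if n >= min_reads and "N" not in b
    )
    return Whitelist(kept, min_reads)


def tag_pairs(
    fastq1,
    fastq2,
    whitelist: Whitelist,
    cb_len: int = CB_LEN,
    umi_len: int = UMI_LEN,
    stats: TaggingStats | None = None,
) -> Iterator[TaggedRead]:
    """Fuse record-synchronized paired FASTQs into tagged reads.

    Only whitelisted barcodes are emitted. Read-1 records shorter than
    ``cb_len + umi_len`` are skipped and tallied. Desynchronized files
    (unequal record counts) raise ``ValueError`` with the record index.
    """
    if stats is None:
        stats = TaggingStats()
    with open(fastq1) as fh1, open(fastq2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        index = 0
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                break
            if (r1 is None) != (r2 is None):
                raise ValueError(
                    f"paired FASTQ files desynchronized at record {index}"
                )
            index += 1
            _t1, seq1, _q1 = r1
            _t2, seq2, qual2 = r2
            if len(seq1) < cb_len + umi_len:
                stats.skipped_short += 1
                continue
            barcode = seq1[:cb_len]
            if barcode not in whitelist:
                stats.filtered += 1
                continue
            stats.kept += 1
            yield TaggedRead(barcode, seq1[cb_len : cb_len + umi_len], seq2, qual2)


def trim_polya(sequence: str, min_run: int = 6) -> str:
    """Remove a maximal 3'-terminal run of >= ``min_run`` A's.

    The 5' end is never touched; shorter terminal runs are kept. Idempotent.
    """
    n = len(sequence)
    i = n
    while i > 0 and sequence[i - 1] == "A":
        i -= 1
    if n - i >= min_run:
        return sequence[:i]
    return sequence


def write_tagged_fastq(reads: Iterable[TaggedRead], path) -> int:
    """Write tagged reads with barcode/UMI in the name: ``@cb_umi_serial``."""
    n = 0
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            qual = r.qualities if r.qualities is not None else "I" * len(r.sequence)
            fh.write(f"@{r.cell_barcode}_{r.umi}_{i}\n{r.sequence}\n+\n{qual}\n")
            n += 1
    return n
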