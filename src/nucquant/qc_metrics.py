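"""Cell and gene quality filters plus per-cell/library summary statistics.

Filters follow the convention for droplet data: cells (nuclei) with fewer
than 400 (300) detected genes are removed first, then genes detected in
fewer than 10 of the surviving cells. A gene counts as detected in a cell
at >= 1 UMI. Detection gain quantifies how much intron-inclusive counting
raises per-cell gene detection over exon-only counting — the motivation
for counting introns in single-nucleus libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .umi_quant import CountMatrix, REGIONS

logger = logging.getLogger(__name__)

__all__ = [
    "QCConfig",
    "CellSummary",
    "per_cell_summary",
    "filter_matrix",
    "detection_gain",
    "region_fractions",
    "top_gene_fractions",
    "select_top_cells",
]


@dataclass
class QCConfig:
    min_genes_cellmode: int = 400
    min_genes_nucleusmode: int = 300
    min_cells_per_gene: int = 10
    detection_min_umi: int = 1

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")

    def min_genes(self, mode: str) -> int:
        if mode == "cell":
            return self.min_genes_cellmode
        if mode == "nucleus":
            return self.min_genes_nucleusmode
        raise ValueError(f"mode must be 'cell' or 'nucleus', got {mode!r}")


@dataclass
class CellSummary:
    barcode: str
    genes_detected: int
    total_umi: int
    intronic_fraction: float | None = None
    top_gene_fractions: list[tuple[str, float]] = field(default_factory=list)


def _detected(matrix: CountMatrix, min_umi: int = 1) -> np.ndarray:
    """Per-cell number of genes with count >= min_umi."""
    return np.asarray((matrix.counts >= min_umi).sum(axis=0)).ravel()


def per_cell_summary(
    matrix: CountMatrix,
    assignments: pd.DataFrame | None = None,
    config: QCConfig | None = None,
    n_top: int = 15,
) -> list[CellSummary]:
    """Summarize each cell: detected genes, total UMIs, optionally the
    intronic read fraction from an assignment table and top-gene shares."""
    config = config or QCConfig()
    detected = _detected(matrix, config.detection_min_umi)
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel()
    intronic: dict[str, float] = {}
    if assignments is not None:
        assigned = assignments[assignments["region"].isin(["exonic", "intronic"])]
        grp = assigned.groupby("cell")["region"]
        intronic = (grp.apply(lambda r: (r == "intronic").mean())).to_dict()
    out = []
    dense = None
    for j, bc in enumerate(matrix.cell_barcodes):
        top: list[tuple[str, float]] = []
        if totals[j] > 0 and n_top:
            col = matrix.counts.getcol(j).toarray().ravel()
            order = np.lexsort((matrix.gene_ids, -col))[:n_top]
            top = [
                (matrix.gene_ids[i], col[i] / totals[j]) for i in order if col[i] > 0
            ]
        out.append(
            CellSummary(
                barcode=bc,
                genes_detected=int(detected[j]),
                total_umi=int(totals[j]),
                intronic_fraction=intronic.get(bc),
                top_gene_fractions=top,
            )
        )
    return out


def filter_matrix(
    matrix: CountMatrix, config: QCConfig | None = None, mode: str = "nucleus"
) -> CountMatrix:
    """Remove low-quality cells, then low-quality genes.

    Order is fixed: cells below the mode's minimum detected genes go first,
    then genes detected in fewer than ``min_cells_per_gene`` of the
    *surviving* cells. Thresholds are strict 'less than' cut-offs, so a
    cell at exactly the minimum is kept.
    """
    config = config or QCConfig()
    min_genes = config.min_genes(mode)
    detected = _detected(matrix, config.detection_min_umi)
    keep_cells = np.flatnonzero(detected >= min_genes)
    sub = matrix.counts[:, keep_cells]
    cells_per_gene = np.asarray((sub >= config.detection_min_umi).sum(axis=1)).ravel()
    keep_genes = np.flatnonzero(cells_per_gene >= config.min_cells_per_gene)
    result = CountMatrix(
        [matrix.gene_ids[i] for i in keep_genes],
        [matrix.cell_barcodes[j] for j in keep_cells],
        sub[keep_genes, :],
        matrix.mode,
    )
    if result.shape[0] == 0 or result.shape[1] == 0:
        logger.warning("QC filtering removed all %s", "genes" if result.shape[0] == 0 else "cells")
    return result


def detection_gain(
    exon_matrix: CountMatrix, both_matrix: CountMatrix, min_umi: int = 1
) -> tuple[pd.Series, float, int]:
    """Per-cell ratio of genes detected with exon+intron over exon-only.

    Returns (ratios indexed by barcode, mean of the finite ratios, number
    of cells with zero exon-only detection, which are excluded from the
    mean).
    """
    if exon_matrix.cell_barcodes != both_matrix.cell_barcodes:
        raise ValueError("matrices must cover the same barcodes in the same order")
    d_exon = _detected(exon_matrix, min_umi).astype(float)
    d_both = _detected(both_matrix, min_umi).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = d_both / d_exon
    s = pd.Series(ratios, index=exon_matrix.cell_barcodes, name="detection_gain")
    finite = s[np.isfinite(s)]
    n_infinite = int((~np.isfinite(s)).sum())
    return s, float(finite.mean()) if len(finite) else float("nan"), n_infinite


def region_fractions(assignments: pd.DataFrame) -> dict[str, float]:
    """Proportion of reads per region class; proportions sum to 1."""
    if len(assignments) == 0:
        raise ValueError("empty assignment stream")
    frac = assignments["region"].value_counts(normalize=True)
    return {r: float(frac.get(r, 0.0)) for r in REGIONS}


def top_gene_fractions(matrix: CountMatrix, n: int = 15) -> list[tuple[str, float]]:
    """Top ``n`` genes by share of total library counts, descending, ties
    broken by gene_id."""
    total = matrix.counts.sum()
    if total == 0:
        raise ValueError("matrix has no counts")
    per_gene = np.asarray(matrix.counts.sum(axis=1)).ravel() / total
    order = np.lexsort((matrix.gene_ids, -per_gene))[:n]
    return [(matrix.gene_ids[i], float(per_gene[i])) for i in order]


def select_top_cells(matrix: CountMatrix, fraction: float = 0.30) -> CountMatrix:
    """Keep the ceil(fraction x n_cells) cells with most detected genes.

    Ties break by total UMI, then barcode (deterministic).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_keep = int(np.ceil(fraction * len(matrix.cell_barcodes)))
    detected = _detected(matrix)
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel()
    order = sorted(
        range(len(matrix.cell_barcodes)),
        key=lambda j: (-detected[j], -totals[j], matrix.cell_barcodes[j]),
    )[:n_keep]
    order = sorted(order)  # preserve original column order among the kept
    return CountMatrix(
        matrix.gene_ids,
        [matrix.cell_barcodes[j] for j in order],
        matrix.counts[:, order],
        matrix.mode,
    )
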