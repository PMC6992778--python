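"""Normalization, variable-gene selection, pseudo-bulk profiles, and
Pearson correlation structure with hierarchical bi-clustering.

The normalization ladder is the standard single-cell one: per-cell counts
scaled to 10,000 total (TP10k), natural-log transformed with a pseudo-count
of 1, then per-gene standardized to zero mean and unit variance. Highly
variable genes are picked by a binned dispersion statistic (variance/mean
on the linear scale, z-scored within equal-frequency mean bins). Pseudo-bulk
profiles sum raw counts over a group of cells before log-TP10k, making
droplet libraries comparable to bulk RNA-seq samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

from .umi_quant import CountMatrix

__all__ = [
    "NormalizedMatrix",
    "HVGConfig",
    "CorrelationProfile",
    "normalize",
    "tp10k",
    "log1p_tp10k",
    "standardize",
    "select_hvg",
    "pseudobulk",
    "correlate",
    "bicluster",
]

SCALE = 1e4
LADDERS = ("tp10k", "log1p_tp10k", "standardized")


@dataclass
class NormalizedMatrix:
    """Dense genes x cells values on one rung of the normalization ladder."""

    values: pd.DataFrame  # genes x cells
    ladder: str
    constant_genes: list[str] | None = None  # flagged when standardizing

    def __post_init__(self) -> None:
        if self.ladder not in LADDERS:
            raise ValueError(f"unknown ladder {self.ladder!r}")


def _to_frame(matrix: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(matrix, CountMatrix):
        return matrix.to_frame().astype(float)
    return matrix.astype(float)


def tp10k(matrix: CountMatrix | pd.DataFrame) -> NormalizedMatrix:
    """Scale each cell to 10,000 total counts (transcripts per 10k)."""
    df = _to_frame(matrix)
    totals = df.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])[:5]
        raise ValueError(
            f"all-zero cells present (e.g. {bad}); apply filter_matrix first"
        )
    return NormalizedMatrix(df / totals * SCALE, "tp10k")


def log1p_tp10k(norm: NormalizedMatrix | CountMatrix | pd.DataFrame) -> NormalizedMatrix:
    """Natural log of (TP10k + 1); applied on counts it scales first."""
    if not isinstance(norm, NormalizedMatrix):
        norm = tp10k(norm)
    if norm.ladder != "tp10k":
        raise ValueError("log1p step expects the tp10k rung")
    return NormalizedMatrix(np.log1p(norm.values), "log1p_tp10k")


def standardize(norm: NormalizedMatrix) -> NormalizedMatrix:
    """Per-gene zero mean, unit variance. Constant genes become all-zero
    rows and are reported in ``constant_genes``."""
    if norm.ladder != "log1p_tp10k":
        raise ValueError("standardize expects the log1p_tp10k rung")
    vals = norm.values
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=0)
    constant = list(vals.index[sd == 0])
    safe_sd = sd.replace(0, 1.0)
    z = vals.sub(mu, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = 0.0
    return NormalizedMatrix(z, "standardized", constant_genes=constant)


def normalize(matrix: CountMatrix | pd.DataFrame) -> NormalizedMatrix:
    """Full ladder: counts -> TP10k -> log1p -> standardized."""
    return standardize(log1p_tp10k(tp10k(matrix)))


@dataclass
class HVGConfig:
    dispersion_min: float = 1.5
    mean_min: float = 0.15  # on the log scale
    n_bins: int = 20


def select_hvg(log_matrix: NormalizedMatrix, config: HVGConfig | None = None) -> list[str]:
    """Highly variable genes from a log1p-TP10k matrix.

    Dispersion is variance/mean per gene on the exponentiated (linear)
    scale, z-standardized within ``n_bins`` equal-frequency bins of the
    linear mean; a gene is selected when its standardized dispersion is at
    least ``dispersion_min`` and its log-scale mean at least ``mean_min``.
    Constant genes (zero dispersion denominator) are never selected.
    """
    config = config or HVGConfig()
    if log_matrix.ladder != "log1p_tp10k":
        raise ValueError("HVG selection expects the log1p_tp10k rung")
    lin = np.expm1(log_matrix.values)
    mean = lin.mean(axis=1)
    var = lin.var(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = var / mean
    disp = disp.replace([np.inf, -np.inf], np.nan)
    log_mean = log_matrix.values.mean(axis=1)

    n_bins = min(config.n_bins, max(1, mean.nunique()))
    bins = pd.qcut(mean.rank(method="first"), n_bins, labels=False, duplicates="drop")
    df = pd.DataFrame({"disp": disp, "bin": bins})
    grp = df.groupby("bin")["disp"]
    mu_b = grp.transform("mean")
    sd_b = grp.transform("std").fillna(0.0)
    disp_z = (df["disp"] - mu_b) / sd_b.replace(0, 1.0)
    selected = (disp_z >= config.dispersion_min) & (log_mean >= config.mean_min)
    selected &= disp.notna() & (var > 0)  # constant genes never selected
    return list(log_matrix.values.index[selected.fillna(False)])


def pseudobulk(matrix: CountMatrix | pd.DataFrame, groups: dict[str, str]) -> pd.DataFrame:
    """Sum raw counts per group label, then log1p-TP10k each group profile.

    ``groups`` maps every barcode to a label; missing barcodes or empty
    groups are an error.
    """
    df = _to_frame(matrix)
    missing = [c for c in df.columns if c not in groups]
    if missing:
        raise ValueError(f"unlabeled barcodes: {missing[:5]}")
    labels = sorted(set(groups[c] for c in df.columns))
    out = {}
    for label in labels:
        cols = [c for c in df.columns if groups[c] == label]
        if not cols:
            raise ValueError(f"empty group {label!r}")
        sums = df[cols].sum(axis=1)
        total = sums.sum()
        if total == 0:
            raise ValueError(f"group {label!r} has no counts")
        out[label] = np.log1p(sums / total * SCALE)
    return pd.DataFrame(out)


@dataclass
class CorrelationProfile:
    """Pearson r between query profiles (rows) and references (columns)."""

    values: pd.DataFrame
    gene_set: list[str]


def correlate(
    queries: pd.DataFrame, references: pd.DataFrame, gene_set: list[str] | None = None
) -> CorrelationProfile:
    """Pearson correlation of each query column against each reference
    column over ``gene_set`` (default: shared genes). Zero-variance
    profiles yield missing values."""
    if gene_set is None:
        gene_set = sorted(set(queries.index) & set(references.index))
    if len(gene_set) < 3:
        raise ValueError("need at least 3 genes to correlate")
    missing_q = set(gene_set) - set(queries.index)
    missing_r = set(gene_set) - set(references.index)
    if missing_q or missing_r:
        raise ValueError("gene_set not contained in both profile sets")
    q = queries.loc[gene_set].to_numpy(float)
    r = references.loc[gene_set].to_numpy(float)
    qc = q - q.mean(axis=0)
    rc = r - r.mean(axis=0)
    qs = np.sqrt((qc**2).sum(axis=0))
    rs = np.sqrt((rc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (qc.T @ rc) / np.outer(qs, rs)
    corr[:, rs == 0] = np.nan
    corr[qs == 0, :] = np.nan
    values = pd.DataFrame(corr, index=queries.columns, columns=references.columns)
    return CorrelationProfile(values, list(gene_set))


def bicluster(
    corr: CorrelationProfile | pd.DataFrame,
    method: str = "complete",
    metric: str = "euclidean",
):
    """Hierarchical bi-clustering of a correlation matrix.

    Rows and columns are clustered independently (default: complete linkage
    on Euclidean distance, the convention of correlation heatmaps; use
    ``metric='correlation'`` with ``method='average'`` for 1-r distances).
    Missing values are imputed by row mean and flagged. Returns
    ``(row_order, col_order, row_linkage, col_linkage)``; a single row or
    column yields the identity order with a ``None`` linkage.
    """
    df = corr.values if isinstance(corr, CorrelationProfile) else corr
    if df.isna().any().any():
        df = df.apply(lambda row: row.fillna(row.mean()), axis=1)

    def _one_axis(mat: np.ndarray):
        if mat.shape[0] < 2:
            return list(range(mat.shape[0])), None
        link = sch.linkage(pdist(mat, metric=metric), method=method)
        return list(sch.leaves_list(link)), link

    row_order, row_link = _one_axis(df.to_numpy(float))
    col_order, col_link = _one_axis(df.to_numpy(float).T)
    return row_order, col_order, row_link, col_link
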