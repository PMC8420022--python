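"""Single-cell count-matrix preprocessing.

QC filtering on UMI totals and mitochondrial fraction, pruning of small
multi-marker (doublet-like) clusters, marker-based cluster annotation,
gene-set scoring (e.g. a glycolysis gene panel), and per-cluster
differential expression.  Clustering itself is consumed, not computed:
cluster labels arrive with the matrix.

Counts are genes x cells sparse matrices; normalization for scoring and DE
is counts-per-10k followed by log1p (configurable scale), which preserves
within-gene cell ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from scipy.io import mmread, mmwrite

from .exceptions import DataError, DegenerateInputError

__all__ = [
    "CellCountMatrix",
    "QCReport",
    "normalize_counts",
    "qc_filter",
    "prune_clusters",
    "annotate_clusters",
    "gene_set_score",
    "cluster_de",
    "read_count_matrix",
    "write_count_matrix",
]

UMI_MIN_DEFAULT = 50
UMI_MAX_DEFAULT = 50_000
MITO_MAX_DEFAULT = 0.30
MIN_CLUSTER_CELLS_DEFAULT = 250
#: a marker counts as "positive" in a cluster when its mean normalized
#: expression exceeds this fraction of the max cluster mean for that marker
POSITIVE_EXPRESSION_FRAC = 0.25


@dataclass
class CellCountMatrix:
    """Sparse genes x cells UMI counts with gene/cell annotations."""

    counts: sp.csr_matrix
    gene_names: np.ndarray
    mito_mask: np.ndarray  # bool per gene
    barcodes: np.ndarray
    sample_of_origin: np.ndarray | None = None
    cluster_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        n_genes, n_cells = self.counts.shape
        if self.gene_names.size != n_genes or self.mito_mask.size != n_genes:
            raise DataError("gene annotations do not match matrix rows")
        if self.barcodes.size != n_cells:
            raise DataError("barcodes do not match matrix columns")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise DataError("negative counts")
        for attr in ("sample_of_origin", "cluster_labels"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=object)
                if v.size != n_cells:
                    raise DataError(f"{attr} does not match matrix columns")
                setattr(self, attr, v)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def select_cells(self, mask: np.ndarray) -> "CellCountMatrix":
        """Column subset (pure; the input matrix is unmodified)."""
        return replace(
            self,
            counts=self.counts[:, mask],
            barcodes=self.barcodes[mask],
            sample_of_origin=None if self.sample_of_origin is None
            else self.sample_of_origin[mask],
            cluster_labels=None if self.cluster_labels is None
            else self.cluster_labels[mask],
        )


@dataclass
class QCReport:
    """Per-cell QC metrics plus per-cluster pruning evidence."""

    per_cell: pd.DataFrame
    per_cluster: pd.DataFrame | None = None


def _umi_totals(matrix: CellCountMatrix) -> np.ndarray:
    return np.asarray(matrix.counts.sum(axis=0)).ravel()


def normalize_counts(matrix: CellCountMatrix, scale: float = 1e4,
                     log: bool = True) -> sp.csr_matrix:
    """Counts-per-``scale`` per cell, then log1p (``log=False`` skips the log).

    Returns a new sparse matrix; preserves within-gene cell ranking.
    """
    totals = _umi_totals(matrix)
    if np.any(totals <= 0):
        raise DegenerateInputError("cells with zero total counts; QC-filter first")
    x = matrix.counts.tocsc(copy=True).astype(float)
    x = x @ sp.diags(scale / totals)
    if log:
        x.data = np.log1p(x.data)
    return sp.csr_matrix(x)


def qc_filter(matrix: CellCountMatrix,
              umi_min: int = UMI_MIN_DEFAULT,
              umi_max: int = UMI_MAX_DEFAULT,
              mito_max: float = MITO_MAX_DEFAULT,
              ) -> tuple[CellCountMatrix, QCReport]:
    """Remove cells failing the UMI and mitochondrial-fraction rules.

    A cell is discarded when its total UMIs are *less than* ``umi_min``,
    *greater than* ``umi_max``, or its mitochondrial read fraction is *more
    than* ``mito_max`` — boundary values are retained.  Idempotent: filtering
    a filtered matrix removes nothing.
    """
    if umi_min <= 0 or umi_max <= 0 or umi_min >= umi_max:
        raise DataError("require 0 < umi_min < umi_max")
    if mito_max < 1.0 and not matrix.mito_mask.any():
        raise DataError("no mitochondrial gene flags; cannot apply the "
                        "mito-fraction rule")
    totals = _umi_totals(matrix)
    mito_counts = np.asarray(matrix.counts[matrix.mito_mask].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    reason = np.full(matrix.n_cells, "", dtype=object)
    reason[mito_frac > mito_max] = "high_mito"
    reason[totals > umi_max] = "high_umi"
    reason[totals < umi_min] = "low_umi"  # lowest-precedence rules last win
    keep = reason == ""
    report = QCReport(per_cell=pd.DataFrame({
        "barcode": matrix.barcodes,
        "total_umis": totals.astype(int),
        "mito_fraction": mito_frac,
        "passed": keep,
        "reason": reason,
    }))
    return matrix.select_cells(keep), report


def _cluster_mean_expression(norm: sp.csr_matrix, labels: np.ndarray) -> pd.DataFrame:
    clusters = pd.unique(labels)
    cols = {}
    for c in clusters:
        mask = labels == c
        cols[c] = np.asarray(norm[:, mask].mean(axis=1)).ravel()
    return pd.DataFrame(cols)  # genes x clusters


def prune_clusters(matrix: CellCountMatrix, labels: np.ndarray | None = None,
                   min_cells: int = MIN_CLUSTER_CELLS_DEFAULT,
                   marker_sets: dict | None = None,
                   positive_frac: float = POSITIVE_EXPRESSION_FRAC,
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Flag small clusters positive for multiple cell types' markers.

    A cluster is removed when it has fewer than ``min_cells`` cells AND shows
    positive expression of at least two cell types' marker sets (a marker is
    positive when the cluster's mean normalized expression exceeds
    ``positive_frac`` x the maximum cluster mean for that marker; a type is
    positive when a majority of its detected markers are).  Returns the
    pruned label vector (removed clusters set to None) and an evidence table.
    """
    if labels is None:
        labels = matrix.cluster_labels
    if labels is None:
        raise DataError("no cluster labels provided")
    labels = np.asarray(labels, dtype=object)
    if labels.size != matrix.n_cells:
        raise DataError("labels do not cover all cells")
    if pd.isna(labels).any():
        raise DataError("unlabeled cells present")
    if not marker_sets:
        raise DataError("marker_sets required")
    # positivity evidence uses linear counts-per-10k: log1p compresses the
    # marker/off-marker contrast and would defeat a relative threshold
    norm = normalize_counts(matrix, log=False)
    cluster_means = _cluster_mean_expression(norm, labels)
    gene_index = {g: i for i, g in enumerate(matrix.gene_names)}
    rows = []
    removed = []
    for c in cluster_means.columns:
        size = int((labels == c).sum())
        positive_types = []
        for cell_type, markers in marker_sets.items():
            detected = [gene_index[g] for g in markers if g in gene_index]
            if not detected:
                continue
            pos = 0
            for gi in detected:
                peak = cluster_means.iloc[gi].max()
                if peak > 0 and cluster_means.at[gi, c] > positive_frac * peak:
                    pos += 1
            if pos * 2 > len(detected):
                positive_types.append(cell_type)
        multimarker = len(positive_types) >= 2
        remove = size < min_cells and multimarker
        if remove:
            removed.append(c)
        rows.append({"cluster": c, "n_cells": size,
                     "positive_types": positive_types,
                     "multimarker": multimarker, "removed": remove})
    pruned = labels.copy()
    for c in removed:
        pruned[labels == c] = None
    return pruned, pd.DataFrame(rows)


def annotate_clusters(matrix: CellCountMatrix, labels: np.ndarray,
                      marker_map: dict) -> dict:
    """Assign each cluster the cell type with maximal normalized marker signal.

    For each marker gene the cluster means are scaled by the max across
    clusters (so highly expressed markers do not dominate); a type's score in
    a cluster is the mean over its detected markers.  Ties or all-zero
    clusters give ``None`` with a warning.  Absent marker genes are skipped
    with a warning.
    """
    if not marker_map:
        raise DataError("marker_map must be nonempty")
    labels = np.asarray(labels, dtype=object)
    norm = normalize_counts(matrix, log=False)
    cluster_means = _cluster_mean_expression(norm, labels)
    gene_index = {g: i for i, g in enumerate(matrix.gene_names)}
    scaled = {}
    for cell_type, markers in marker_map.items():
        rows = []
        for g in markers:
            if g not in gene_index:
                warnings.warn(f"marker gene {g!r} absent; skipped", stacklevel=2)
                continue
            vals = cluster_means.iloc[gene_index[g]]
            peak = vals.max()
            rows.append(vals / peak if peak > 0 else vals * 0.0)
        scaled[cell_type] = (pd.concat(rows, axis=1).mean(axis=1)
                             if rows else pd.Series(0.0, index=cluster_means.columns))
    scores = pd.DataFrame(scaled)  # clusters x types
    out = {}
    for c in scores.index:
        row = scores.loc[c]
        best = row.max()
        if best <= 0 or (row == best).sum() > 1:
            warnings.warn(f"cluster {c!r} unassigned (tie or no signal)",
                          stacklevel=2)
            out[c] = None
        else:
            out[c] = row.idxmax()
    return out


def gene_set_score(matrix: CellCountMatrix, gene_list,
                   per: str = "cell", labels: np.ndarray | None = None,
                   ) -> tuple[np.ndarray | pd.Series, int]:
    """Sum of normalized expression over the detected genes of a panel.

    Returns ``(scores, n_detected)``: per-cell scores (``per="cell"``) or
    per-cluster means of the cell scores (``per="cluster"``, needs labels).
    Genes absent from the matrix are silently dropped from the panel but
    counted in the report; no detected gene at all is an error.
    """
    gene_index = {g: i for i, g in enumerate(matrix.gene_names)}
    detected = [gene_index[g] for g in gene_list if g in gene_index]
    if not detected:
        raise DataError("no gene of the panel detected in the matrix")
    norm = normalize_counts(matrix)
    scores = np.asarray(norm[detected].sum(axis=0)).ravel()
    if per == "cell":
        return scores, len(detected)
    if per == "cluster":
        if labels is None:
            labels = matrix.cluster_labels
        if labels is None:
            raise DataError("cluster scores need labels")
        s = pd.Series(scores).groupby(np.asarray(labels, dtype=object)).mean()
        return s, len(detected)
    raise ValueError(f"unknown per={per!r}")


def cluster_de(matrix: CellCountMatrix, cell_type_labels: np.ndarray,
               sample_groups: np.ndarray, cell_type, group_a, group_b,
               *, min_cells: int = 3, alpha: float = 0.05) -> pd.DataFrame:
    """Rank-sum differential expression between two groups within a cell type.

    Wilcoxon rank-sum (Mann-Whitney U) per gene on normalized expression,
    BH-FDR across genes.  Returns a table with the log2 fold change of mean
    normalized expression, U, p, q and a ``significant`` flag.
    """
    cell_type_labels = np.asarray(cell_type_labels, dtype=object)
    sample_groups = np.asarray(sample_groups, dtype=object)
    in_type = cell_type_labels == cell_type
    mask_a = in_type & (sample_groups == group_a)
    mask_b = in_type & (sample_groups == group_b)
    if mask_a.sum() < min_cells or mask_b.sum() < min_cells:
        raise DegenerateInputError(
            f"need >={min_cells} cells per side; got {int(mask_a.sum())} vs "
            f"{int(mask_b.sum())}")
    norm = normalize_counts(matrix)
    xa = np.asarray(norm[:, mask_a].todense())
    xb = np.asarray(norm[:, mask_b].todense())
    u, p = scipy.stats.mannwhitneyu(xa, xb, axis=1, alternative="two-sided")
    p = np.where(np.isnan(p), 1.0, p)
    from statsmodels.stats.multitest import multipletests
    q = multipletests(p, method="fdr_bh")[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        l2fc = np.log2(xb.mean(axis=1) / xa.mean(axis=1))
    return pd.DataFrame({
        "gene": matrix.gene_names,
        "log2_fold_change": l2fc,
        "u": u, "p": p, "q": q,
        "significant": q < alpha,
    }).set_index("gene").sort_values("q")


# ---------------------------------------------------------------------------
# Matrix-market I/O
# ---------------------------------------------------------------------------

def read_count_matrix(mtx_path, genes_path, barcodes_path) -> CellCountMatrix:
    """Read a matrix-market triplet plus genes.tsv (name, is_mito) and
    barcodes.tsv (barcode[, sample, cluster])."""
    counts = sp.csr_matrix(mmread(mtx_path))
    genes = pd.read_csv(genes_path, sep="\t")
    cells = pd.read_csv(barcodes_path, sep="\t")
    return CellCountMatrix(
        counts=counts,
        gene_names=genes["gene"].to_numpy(dtype=object),
        mito_mask=genes["is_mito"].astype(bool).to_numpy(),
        barcodes=cells["barcode"].to_numpy(dtype=object),
        sample_of_origin=cells["sample"].to_numpy(dtype=object)
        if "sample" in cells.columns else None,
        cluster_labels=cells["cluster"].to_numpy(dtype=object)
        if "cluster" in cells.columns else None,
    )


def write_count_matrix(matrix: CellCountMatrix, mtx_path, genes_path,
                       barcodes_path) -> None:
    """Write the matrix-market triplet + gene/cell annotation TSVs."""
    mmwrite(str(mtx_path), matrix.counts.tocoo())
    pd.DataFrame({"gene": matrix.gene_names,
                  "is_mito": matrix.mito_mask.astype(int)}
                 ).to_csv(genes_path, sep="\t", index=False)
    cells = pd.DataFrame({"barcode": matrix.barcodes})
    if matrix.sample_of_origin is not None:
        cells["sample"] = matrix.sample_of_origin
    if matrix.cluster_labels is not None:
        cells["cluster"] = matrix.cluster_labels
    cells.to_csv(barcodes_path, sep="\t", index=False)
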