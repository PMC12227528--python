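"""Sparse gene x cell dataset container, 10x-style triplet I/O, QC and normalization.

The :class:`Dataset` is the carrier between every pipeline stage: an integer
UMI count matrix (genes as rows, cells as columns, scipy CSR), a per-cell
metadata table, a per-gene table, and an optional log-normalized layer of the
same shape.  Per-cell QC fields (``n_umi``, ``n_genes_detected``, ``pct_mito``,
``pct_ribo`` and the z-scored detection rate used as the ``cngeneson``
covariate in the hurdle design) are always recomputed from the counts so that
they can never drift out of sync with the matrix.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "Dataset",
    "QCThresholds",
    "QC_PRESETS",
    "read_dataset",
    "write_dataset",
    "qc_filter",
    "normalize_log",
]


class DatasetFormatError(ValueError):
    """Raised when an on-disk bundle is structurally inconsistent."""


@dataclass
class QCThresholds:
    """Cell-level QC cutoffs.

    ``min_genes`` is a lower bound on the number of detected genes (inclusive);
    the mitochondrial/ribosomal bounds are strict upper bounds on UMI fractions.
    """

    min_genes: int
    max_pct_mito: float
    max_pct_ribo: float

    def __post_init__(self) -> None:
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")
        for name in ("max_pct_mito", "max_pct_ribo"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


#: Presets for nuclei (postmortem tissue) and whole-cell (organoid) captures.
QC_PRESETS: dict[str, QCThresholds] = {
    "nuclei": QCThresholds(min_genes=500, max_pct_mito=0.05, max_pct_ribo=0.05),
    "organoid": QCThresholds(min_genes=1000, max_pct_mito=0.10, max_pct_ribo=0.25),
}

_QC_COLUMNS = ("n_umi", "n_genes_detected", "pct_mito", "pct_ribo", "detection_rate")


@dataclass
class Dataset:
    """Sparse UMI counts plus cell/gene metadata and an optional normalized layer.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes x cells (CSR).
    cells
        Indexed by unique ``cell_id``; expected columns include ``donor_id``,
        ``diagnosis`` (two levels, by convention ``control``/``case``),
        ``cell_type`` and any nuisance covariates (age, sex, batches, ...).
    genes
        Indexed by unique ``gene_id``; boolean ``pct_mito_flag`` /
        ``pct_ribo_flag`` columns mark genes counted toward the QC fractions.
    norm
        Optional real matrix, same shape as ``counts`` (log-normalized layer).
    """

    counts: sp.csr_matrix
    cells: pd.DataFrame
    genes: pd.DataFrame
    norm: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and (self.counts.data < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise DatasetFormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        for axis, frame in (("cell", self.cells), ("gene", self.genes)):
            dup = frame.index[frame.index.duplicated()]
            if len(dup):
                raise DatasetFormatError(f"duplicate {axis} id: {dup[0]!r}")
        if self.norm is not None:
            self.norm = sp.csr_matrix(self.norm)
            if self.norm.shape != self.counts.shape:
                raise DatasetFormatError("norm layer shape differs from counts")
        self._recompute_qc_fields()

    # ------------------------------------------------------------------ QC
    def _recompute_qc_fields(self) -> None:
        counts = self.counts
        n_umi = np.asarray(counts.sum(axis=0)).ravel()
        n_det = counts.getnnz(axis=0).astype(np.int64)
        cells = self.cells
        cells["n_umi"] = n_umi.astype(np.int64)
        cells["n_genes_detected"] = n_det
        for flag, col in (("pct_mito_flag", "pct_mito"), ("pct_ribo_flag", "pct_ribo")):
            if flag in self.genes.columns:
                mask = np.asarray(self.genes[flag], dtype=bool)
            else:
                mask = np.zeros(counts.shape[0], dtype=bool)
            sub = np.asarray(counts[mask].sum(axis=0)).ravel() if mask.any() else np.zeros_like(n_umi, dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.where(n_umi > 0, sub / np.maximum(n_umi, 1), 0.0)
            cells[col] = frac
        cells["detection_rate"] = _zscore(n_det.astype(float))

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask_or_ids) -> "Dataset":
        """Return a new Dataset restricted to the given cells (genes are kept)."""
        if isinstance(mask_or_ids, (pd.Index, list, np.ndarray)) and not (
            isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool
        ):
            idx = self.cells.index.get_indexer(pd.Index(mask_or_ids))
            if (idx < 0).any():
                raise KeyError("unknown cell id in subset")
        else:
            idx = np.flatnonzero(np.asarray(mask_or_ids, dtype=bool))
        return Dataset(
            counts=self.counts[:, idx],
            cells=self.cells.iloc[idx].copy(),
            genes=self.genes.copy(),
            norm=None if self.norm is None else self.norm[:, idx],
        )

    def copy(self) -> "Dataset":
        return Dataset(
            counts=self.counts.copy(),
            cells=self.cells.copy(),
            genes=self.genes.copy(),
            norm=None if self.norm is None else self.norm.copy(),
        )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = float(np.std(x))
    if sd == 0.0 or len(x) < 2:
        return np.zeros_like(x, dtype=float)
    return (x - float(np.mean(x))) / sd


# --------------------------------------------------------------------- I/O

def read_dataset(path: str | os.PathLike) -> Dataset:
    """Read an MTX + cells.tsv + genes.tsv bundle written by :func:`write_dataset`.

    The matrix is MatrixMarket coordinate format with genes as rows.  QC fields
    are recomputed from the counts, never trusted from disk.
    """
    path = os.fspath(path)
    counts = sp.csr_matrix(scipy.io.mmread(os.path.join(path, "matrix.mtx")))
    cells = pd.read_csv(os.path.join(path, "cells.tsv"), sep="\t", index_col=0)
    genes = pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t", index_col=0)
    for flag in ("pct_mito_flag", "pct_ribo_flag"):
        if flag in genes.columns:
            genes[flag] = genes[flag].astype(bool)
    if counts.shape[1] != len(cells):
        raise DatasetFormatError(
            f"cell axis mismatch: matrix declares {counts.shape[1]} columns, "
            f"cells.tsv has {len(cells)} rows"
        )
    if counts.shape[0] != len(genes):
        raise DatasetFormatError(
            f"gene axis mismatch: matrix declares {counts.shape[0]} rows, "
            f"genes.tsv has {len(genes)} rows"
        )
    norm = None
    norm_path = os.path.join(path, "norm.mtx")
    if os.path.exists(norm_path):
        norm = sp.csr_matrix(scipy.io.mmread(norm_path))
    drop = [c for c in _QC_COLUMNS if c in cells.columns]
    cells = cells.drop(columns=drop)
    return Dataset(counts=counts, cells=cells, genes=genes, norm=norm)


def write_dataset(d: Dataset, path: str | os.PathLike) -> None:
    """Write the MTX + TSV bundle (text formats only)."""
    path = os.fspath(path)
    os.makedirs(path, exist_ok=True)
    counts = sp.coo_matrix(d.counts)
    counts.data = counts.data.astype(np.int64)
    scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), counts, field="integer")
    d.cells.to_csv(os.path.join(path, "cells.tsv"), sep="\t")
    d.genes.to_csv(os.path.join(path, "genes.tsv"), sep="\t")
    if d.norm is not None:
        scipy.io.mmwrite(os.path.join(path, "norm.mtx"), sp.coo_matrix(d.norm))


# ------------------------------------------------------------ QC / transform

def qc_filter(d: Dataset, t: QCThresholds) -> Dataset:
    """Retain cells with n_genes_detected >= min_genes, pct_mito < max, pct_ribo < max.

    Genes are never dropped; the detection-rate covariate is re-standardized
    over the surviving cells.  Raises if no cell survives.
    """
    keep = (
        (d.cells["n_genes_detected"].to_numpy() >= t.min_genes)
        & (d.cells["pct_mito"].to_numpy() < t.max_pct_mito)
        & (d.cells["pct_ribo"].to_numpy() < t.max_pct_ribo)
    )
    if not keep.any():
        raise ValueError("QC filter removed every cell; relax the thresholds")
    return d.subset_cells(keep)


def normalize_log(d: Dataset, scale: float = 10_000.0) -> Dataset:
    """Depth-normalize and log-transform: norm[g, c] = ln(1 + scale * counts[g, c] / n_umi[c]).

    Natural log, zeros stay zero, sparsity pattern preserved.  Cells with zero
    total UMIs are rejected (run :func:`qc_filter` with ``min_genes >= 1`` first).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    n_umi = d.cells["n_umi"].to_numpy(dtype=float)
    if (n_umi == 0).any():
        bad = d.cells.index[n_umi == 0][0]
        raise ValueError(f"cell {bad!r} has zero total UMIs; cannot normalize")
    coo = sp.coo_matrix(d.counts)
    data = np.log1p(scale * coo.data / n_umi[coo.col])
    norm = sp.csr_matrix((data, (coo.row, coo.col)), shape=d.counts.shape)
    out = d.copy()
    out.norm = norm
    return out
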