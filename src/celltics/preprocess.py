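"""Expression-matrix I/O, normalization, quality control, splitting and scoring.

Matrices are pandas DataFrames oriented genes x cells (index = gene ids,
columns = cell ids), the common scRNA-seq CSV convention. Annotations are
DataFrames indexed by cell id with columns ``cell_type`` and (optionally)
``sub_cell_type``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from sklearn.metrics import accuracy_score, f1_score

logger = logging.getLogger(__name__)

__all__ = [
    "QCConfig",
    "QCReport",
    "read_expression_csv",
    "read_expression_mtx",
    "read_annotation_csv",
    "normalize_counts",
    "qc_filter",
    "split_train_test",
    "compute_metrics",
]


@dataclass
class QCConfig:
    """Thresholds for the basic quality-control filter.

    min_genes_per_cell
        Keep a cell only if it expresses (value > 0) at least this many genes.
    min_cells_per_gene
        Keep a gene only if it is expressed in at least this many of the
        cells that survived the cell filter.
    """

    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0 or self.min_cells_per_gene < 0:
            raise ValueError("QC thresholds must be non-negative")


@dataclass
class QCReport:
    removed_cells: list = field(default_factory=list)
    removed_genes: list = field(default_factory=list)


def read_expression_csv(path, transpose: bool = False) -> pd.DataFrame:
    """Read a genes x cells CSV (first column gene id, header row cell ids).

    Set ``transpose=True`` for cells x genes files.
    """
    df = pd.read_csv(path, index_col=0)
    if transpose:
        df = df.T
    _check_ids(df)
    return df


def read_expression_mtx(matrix_path, gene_path, cell_path) -> pd.DataFrame:
    """Read a MatrixMarket triplet file plus plain-text gene/cell id lists."""
    mat = mmread(matrix_path)
    mat = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    genes = [line.strip() for line in open(gene_path) if line.strip()]
    cells = [line.strip() for line in open(cell_path) if line.strip()]
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match {len(genes)} genes x {len(cells)} cells"
        )
    df = pd.DataFrame(mat, index=genes, columns=cells)
    _check_ids(df)
    return df


def read_annotation_csv(path) -> pd.DataFrame:
    """Read a cell annotation CSV with columns cell_id, cell_type[, sub_cell_type]."""
    df = pd.read_csv(path, dtype=str)
    required = {"cell_id", "cell_type"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation must contain columns {sorted(required)}")
    df = df.set_index("cell_id")
    if df.index.duplicated().any():
        raise ValueError("duplicate cell ids in annotation")
    if "sub_cell_type" in df.columns:
        # every sub-type must belong to exactly one parent type
        owners = df.dropna(subset=["sub_cell_type"]).groupby("sub_cell_type")["cell_type"].nunique()
        bad = owners[owners > 1]
        if len(bad):
            raise ValueError(f"sub_cell_type(s) mapped to multiple cell types: {list(bad.index)}")
    return df


def _check_ids(df: pd.DataFrame) -> None:
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    if df.columns.duplicated().any():
        raise ValueError("duplicate cell ids")


def normalize_counts(raw: pd.DataFrame) -> pd.DataFrame:
    """Library-size normalize raw counts to counts-per-10k, then log2(x + 1).

    expr[c, g] = log2(10000 * m[c, g] / sum_g' m[c, g'] + 1)

    Raises if any entry is negative or any cell has zero total count.
    """
    values = raw.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("raw counts must be non-negative")
    totals = values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell(s) with zero total count: {list(raw.columns[zero])}")
    norm = np.log2(10000.0 * values / totals + 1.0)
    return pd.DataFrame(norm, index=raw.index, columns=raw.columns)


def qc_filter(matrix: pd.DataFrame, cfg: QCConfig | None = None) -> tuple[pd.DataFrame, QCReport]:
    """Drop low-quality cells, then sparsely detected genes.

    Cells expressing fewer than ``min_genes_per_cell`` genes are removed
    first; genes expressed in fewer than ``min_cells_per_gene`` of the
    remaining cells are removed second. Raises if either step empties
    the matrix.
    """
    cfg = cfg or QCConfig()
    report = QCReport()
    detected = matrix.to_numpy() > 0

    genes_per_cell = detected.sum(axis=0)
    keep_cells = genes_per_cell >= cfg.min_genes_per_cell
    report.removed_cells = list(matrix.columns[~keep_cells])
    for cell, n in zip(matrix.columns[~keep_cells], genes_per_cell[~keep_cells]):
        logger.info("qc: removing cell %s (%d detected genes < %d)", cell, n, cfg.min_genes_per_cell)
    if not keep_cells.any():
        raise ValueError("QC removed all cells")

    cells_per_gene = detected[:, keep_cells].sum(axis=1)
    keep_genes = cells_per_gene >= cfg.min_cells_per_gene
    report.removed_genes = list(matrix.index[~keep_genes])
    for gene, n in zip(matrix.index[~keep_genes], cells_per_gene[~keep_genes]):
        logger.info("qc: removing gene %s (detected in %d cells < %d)", gene, n, cfg.min_cells_per_gene)
    if not keep_genes.any():
        raise ValueError("QC removed all genes")

    return matrix.loc[keep_genes, keep_cells], report


def split_train_test(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    train_fraction: float = 0.75,
    seed: int = 0,
):
    """Stratified (by cell type) train/test split of cells.

    Each type contributes ``floor(train_fraction * n_t)`` cells to the
    training set, keeping at least one test cell per type. Deterministic
    under ``seed``. Returns ``(train_matrix, train_annot, test_matrix,
    test_annot)``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    annotation = annotation.loc[matrix.columns]
    counts = annotation["cell_type"].value_counts()
    singles = list(counts[counts < 2].index)
    if singles:
        raise ValueError(f"cell type(s) with a single cell cannot be split: {singles}")

    rng = np.random.default_rng(seed)
    train_cells: list = []
    for ctype in sorted(counts.index):
        cells = np.asarray(annotation.index[annotation["cell_type"] == ctype])
        n_train = min(int(np.floor(train_fraction * len(cells))), len(cells) - 1)
        perm = rng.permutation(len(cells))
        train_cells.extend(cells[perm[:n_train]])
    train_set = set(train_cells)
    train_cols = [c for c in matrix.columns if c in train_set]
    test_cols = [c for c in matrix.columns if c not in train_set]
    return (
        matrix[train_cols],
        annotation.loc[train_cols],
        matrix[test_cols],
        annotation.loc[test_cols],
    )


def compute_metrics(true_labels, predicted_labels) -> dict:
    """Accuracy and macro-averaged F1 over the union label universe.

    Classes with zero precision + recall contribute F1 = 0, so a
    degenerate predictor is penalized rather than ignored.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.size == 0:
        raise ValueError("empty label vectors")
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors differ in length")
    universe = sorted(set(true_labels) | set(predicted_labels))
    return {
        "acc": float(accuracy_score(true_labels, predicted_labels)),
        "macro_f1": float(
            f1_score(true_labels, predicted_labels, labels=universe, average="macro", zero_division=0)
        ),
    }


def write_expression_mtx(df: pd.DataFrame, matrix_path, gene_path, cell_path) -> None:
    """Export a matrix as MatrixMarket plus id lists (inspection helper)."""
    from scipy.sparse import csr_matrix

    mmwrite(matrix_path, csr_matrix(df.to_numpy()))
    with open(gene_path, "w") as fh:
        fh.write("\n".join(map(str, df.index)) + "\n")
    with open(cell_path, "w") as fh:
        fh.write("\n".join(map(str, df.columns)) + "\n")
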