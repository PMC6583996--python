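"""Single-cell QC, log-normalization and p73/p63 co-expression calls.

Implements the cell-level portion of a marker co-expression analysis on
plate-based (Smart-Seq2 style) single-cell data with ERCC spike-ins:

* QC: a cell is excluded when it has fewer than ``min_genes`` detected
  (non-spike-in) genes, fewer than ``min_counts`` total counts, or more than
  ``max_spikein_pct`` percent spike-in reads.  Boundaries are strict: a cell
  at exactly 900 genes, exactly 75,000 counts or exactly 12% spike-in is
  retained.
* Normalization: value(g, c) = ln(1 + scale_factor * count(g, c) / total(c))
  with per-cell totals over non-spike-in genes.
* Expression status: a cell expresses a gene when its log-normalized value
  (count mode, default threshold 0.5) or its TPM (tpm mode, default
  threshold 1) is >= the threshold.
* Co-expression: per-cluster cross-tab of the four joint statuses
  (A-/B-, A+/B-, A-/B+, A+/B+) as percentages of cluster size.

Clustering itself is not performed here; cluster labels arrive with the
matrix metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ModeError, UsageError, ValidationError

__all__ = [
    "CellMatrix",
    "QCThresholds",
    "read_cell_matrix",
    "write_cell_matrix",
    "qc_filter",
    "log_normalize",
    "classify_expression",
    "coexpression_table",
    "positive_fraction_by_group",
    "STATUS_COLUMNS",
]

#: Joint-status column order used in co-expression tables.
STATUS_COLUMNS = ("a-b-", "a+b-", "a-b+", "a+b+")


@dataclass
class QCThresholds:
    """Cell-exclusion thresholds (defaults match plate-based skin scRNA-seq QC)."""

    min_genes: int = 900
    min_counts: int = 75_000
    max_spikein_pct: float = 12.0

    def __post_init__(self) -> None:
        if self.min_genes < 0 or self.min_counts < 0 or self.max_spikein_pct < 0:
            raise UsageError("QC thresholds must be non-negative")


@dataclass
class CellMatrix:
    """Gene x cell matrix with spike-in flags and per-cell metadata.

    ``counts`` is genes (rows) x cells (columns); ``spikein`` is a boolean
    Series over the gene index; ``cell_meta`` is indexed by cell id with at
    least a ``cluster`` column (``stage`` optional).  ``mode`` is ``counts``
    (non-negative integers) or ``tpm`` (non-negative reals).
    """

    counts: pd.DataFrame
    spikein: pd.Series
    cell_meta: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in {"counts", "tpm"}:
            raise UsageError(f"mode must be 'counts' or 'tpm', got {self.mode!r}")
        if not self.spikein.index.equals(self.counts.index):
            raise ValidationError("spikein flags must be indexed by the gene index")
        missing = self.counts.columns.difference(self.cell_meta.index)
        if len(missing) > 0:
            raise ValidationError(f"cells without metadata: {list(missing[:5])}")
        if "cluster" not in self.cell_meta.columns:
            raise ValidationError("cell_meta requires a 'cluster' column")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def cells(self) -> pd.Index:
        return self.counts.columns

    def clusters(self) -> pd.Series:
        return self.cell_meta.loc[self.cells, "cluster"]

    def subset_cells(self, cells: pd.Index) -> "CellMatrix":
        return CellMatrix(
            counts=self.counts.loc[:, cells],
            spikein=self.spikein,
            cell_meta=self.cell_meta.loc[cells],
            mode=self.mode,
        )


def read_cell_matrix(matrix_path, genes_path, meta_path, mode: str = "counts") -> CellMatrix:
    """Assemble a :class:`CellMatrix` from on-disk pieces.

    ``matrix_path`` is either a genes x cells TSV (gene ids in the first
    column, cell ids in the header) or a MatrixMarket ``.mtx`` file in the
    same orientation.  ``genes_path`` is a TSV with columns gene_id and
    spikein (0/1), in matrix row order; ``meta_path`` a TSV with cell_id,
    cluster and optional stage, in matrix column order for MTX input.
    """
    from .errors import FormatError

    genes = pd.read_csv(genes_path, sep="\t")
    if "gene_id" not in genes.columns or "spikein" not in genes.columns:
        raise FormatError(f"{genes_path}: needs gene_id and spikein columns")
    genes = genes.set_index("gene_id")
    meta = pd.read_csv(meta_path, sep="\t")
    if "cell_id" not in meta.columns or "cluster" not in meta.columns:
        raise FormatError(f"{meta_path}: needs cell_id and cluster columns")
    meta = meta.set_index("cell_id")
    if str(matrix_path).endswith(".mtx"):
        from scipy.io import mmread

        X = np.asarray(mmread(matrix_path).todense())
        counts = pd.DataFrame(X, index=genes.index, columns=meta.index)
    else:
        counts = pd.read_csv(matrix_path, sep="\t", index_col=0)
        counts.index.name = "gene_id"
        counts = counts.loc[genes.index]
    if mode == "counts":
        counts = counts.astype(np.int64)
    return CellMatrix(
        counts=counts,
        spikein=genes["spikein"].astype(bool),
        cell_meta=meta,
        mode=mode,
    )


def write_cell_matrix(m: CellMatrix, matrix_path, genes_path, meta_path) -> None:
    """Write the TSV triple read back by :func:`read_cell_matrix`."""
    m.counts.to_csv(matrix_path, sep="\t")
    pd.DataFrame(
        {"gene_id": m.genes, "spikein": m.spikein.astype(int).to_numpy()}
    ).to_csv(genes_path, sep="\t", index=False)
    m.cell_meta.rename_axis("cell_id").reset_index().to_csv(meta_path, sep="\t", index=False)


def cell_qc_metrics(m: CellMatrix) -> pd.DataFrame:
    """Per-cell QC metrics: genes_detected, total_counts, spikein_pct."""
    X = m.counts.to_numpy()
    spike = m.spikein.to_numpy(dtype=bool)
    genes_detected = (X[~spike] > 0).sum(axis=0)
    total = X.sum(axis=0)
    spike_counts = X[spike].sum(axis=0) if spike.any() else np.zeros(X.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        spike_pct = np.where(total > 0, 100.0 * spike_counts / total, 0.0)
    return pd.DataFrame(
        {
            "genes_detected": genes_detected.astype(int),
            "total_counts": total,
            "spikein_pct": spike_pct,
        },
        index=m.cells,
    )


def qc_filter(m: CellMatrix, t: QCThresholds | None = None) -> tuple[CellMatrix, pd.DataFrame]:
    """Remove failing cells; return the filtered matrix and a removal report.

    The report has one row per removed cell with its metrics and a
    comma-joined ``reasons`` string drawn from {genes, counts, spikein}.
    """
    if m.mode != "counts":
        raise ModeError("qc_filter requires a count-mode matrix")
    t = t or QCThresholds()
    metrics = cell_qc_metrics(m)
    reasons: list[str] = []
    removed_cells: list[str] = []
    for cell, row in metrics.iterrows():
        why = []
        if row["genes_detected"] < t.min_genes:
            why.append("genes")
        if row["total_counts"] < t.min_counts:
            why.append("counts")
        if row["spikein_pct"] > t.max_spikein_pct:
            why.append("spikein")
        if why:
            removed_cells.append(cell)
            reasons.append(",".join(why))
    report = metrics.loc[removed_cells].copy()
    report["reasons"] = reasons
    kept = m.cells.difference(pd.Index(removed_cells), sort=False)
    return m.subset_cells(kept), report


def log_normalize(m: CellMatrix, scale_factor: float = 1e4) -> pd.DataFrame:
    """ln(1 + scale_factor * count / per-cell total), totals over non-spike-in genes."""
    if m.mode != "counts":
        raise ModeError("log_normalize requires a count-mode matrix")
    nonspike = m.counts.loc[~m.spikein.to_numpy(dtype=bool)]
    totals = nonspike.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise ValidationError(
            f"cells with zero non-spike-in counts cannot be normalized: {list(zero.index[:5])}"
        )
    return np.log1p(m.counts * (scale_factor / totals))


def classify_expression(values: pd.Series, mode: str, threshold: float) -> pd.Series:
    """Per-cell boolean expression status: value >= threshold.

    ``mode`` documents the value scale ('lognorm' or 'tpm'); the rule is the
    same inclusive threshold in both.
    """
    if mode not in {"lognorm", "tpm"}:
        raise UsageError(f"mode must be 'lognorm' or 'tpm', got {mode!r}")
    if threshold < 0:
        raise UsageError("threshold must be >= 0")
    return values >= threshold


def coexpression_table(
    status_a: pd.Series, status_b: pd.Series, clusters: pd.Series
) -> pd.DataFrame:
    """Per-cluster percentages of the four joint expression statuses.

    Rows are clusters; columns ``n_cells`` plus :data:`STATUS_COLUMNS`
    (a-b-, a+b-, a-b+, a+b+), each percentage of cluster size.  Clusters with
    no cells simply do not appear.
    """
    if not status_a.index.equals(status_b.index) or not status_a.index.equals(clusters.index):
        raise ValidationError("status and cluster series must share one cell index")
    joint = pd.Series(
        np.select(
            [
                ~status_a & ~status_b,
                status_a & ~status_b,
                ~status_a & status_b,
                status_a & status_b,
            ],
            STATUS_COLUMNS,
            default="",
        ),
        index=status_a.index,
    )
    if isinstance(clusters.dtype, pd.CategoricalDtype):
        unused = set(clusters.cat.categories) - set(clusters.unique())
        if unused:
            warnings.warn(f"empty clusters omitted from co-expression table: {sorted(unused)}")
    rows = {}
    for cluster, idx in joint.groupby(clusters, observed=True).groups.items():
        n = len(idx)
        vc = joint.loc[idx].value_counts()
        rows[cluster] = {"n_cells": n, **{c: 100.0 * vc.get(c, 0) / n for c in STATUS_COLUMNS}}
    if not rows:
        warnings.warn("no non-empty clusters; co-expression table is empty")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "cluster"
    if not df.empty:
        df["n_cells"] = df["n_cells"].astype(int)
    return df


def positive_fraction_by_group(status: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Percentage of positive cells per group (e.g. cell type x stage), with n."""
    if not status.index.equals(groups.index):
        raise ValidationError("status and group series must share one cell index")
    out = status.groupby(groups, observed=True).agg(n="size", positive="sum")
    out["pct_positive"] = 100.0 * out["positive"] / out["n"]
    out.index.name = "group"
    return out[["n", "pct_positive"]]
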