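"""Principal reprogramming axis of a sample x gene expression matrix.

Fibroblast-to-keratinocyte reprogramming experiments place samples along a
single dominant transcriptional axis; with a handful of samples and
thousands of genes that axis is captured by the first principal component of
the (gene-centered) expression matrix.  This module computes the PC1
variance fraction, ranks genes by the absolute value of their PC1 loading,
keeps the top ``n_top`` (default 250) as the reprogramming signature, and
partitions them by loading sign into an "up" set (genes increasing along the
axis) and a "down" set.

PCA sign is arbitrary; orientation is fixed deterministically by requiring
the largest-|loading| gene to have a positive loading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import UsageError, ValidationError

__all__ = [
    "SignatureResult",
    "transform_expression",
    "pca_signature",
    "partition_by_sign",
]


@dataclass
class SignatureResult:
    """PC1 summary: variance fractions, ranked signed loadings, top-N sets."""

    pc1_variance_fraction: float
    variance_fractions: np.ndarray  # over all components, sums to 1
    loadings: pd.Series  # gene -> signed PC1 loading, ranked by |loading| desc
    top_n: int
    up_set: list[str]
    down_set: list[str]

    def top_genes(self) -> list[str]:
        return list(self.loadings.index[: self.top_n])


def transform_expression(raw: pd.DataFrame, method: str = "log2p1") -> pd.DataFrame:
    """Transform a non-negative abundance matrix; ``log2p1`` or ``none``."""
    if method not in {"log2p1", "none"}:
        raise UsageError(f"unknown transform {method!r}")
    if (raw.to_numpy() < 0).any():
        raise ValidationError("expression values must be non-negative")
    if method == "none":
        return raw.copy()
    return np.log2(raw + 1.0)


def pca_signature(
    m: pd.DataFrame,
    n_top: int = 250,
    center: bool = True,
    unit_scale: bool = False,
) -> SignatureResult:
    """PCA of a sample (rows) x gene (columns) matrix; PC1 gene signature.

    Genes are mean-centered by default; ``unit_scale`` additionally divides
    each gene by its standard deviation, dropping zero-variance genes with a
    warning.  ``center=False`` decomposes the raw (uncentered) matrix, in
    which case "variance" fractions are squared-singular-value fractions.
    """
    if m.shape[0] < 3:
        raise UsageError(f"PCA needs at least 3 samples, got {m.shape[0]}")
    X = m.astype(float)
    if unit_scale:
        sd = X.std(axis=0, ddof=1)
        constant = sd.index[sd == 0]
        if len(constant) > 0:
            warnings.warn(f"dropping {len(constant)} zero-variance genes before scaling")
            X = X.drop(columns=constant)
            sd = sd.drop(index=constant)
        X = (X - X.mean(axis=0)) / sd
    if n_top > X.shape[1]:
        raise UsageError(f"n_top={n_top} exceeds gene count {X.shape[1]}")
    if center:
        pca = PCA(n_components=None, svd_solver="full")
        pca.fit(X.to_numpy())
        fractions = pca.explained_variance_ratio_
        pc1 = pca.components_[0]
    else:
        _, sv, vt = np.linalg.svd(X.to_numpy(), full_matrices=False)
        fractions = sv**2 / np.sum(sv**2)
        pc1 = vt[0]
    loadings = pd.Series(pc1, index=X.columns, name="pc1_loading")
    ranked = loadings.reindex(loadings.abs().sort_values(ascending=False, kind="stable").index)
    if ranked.iloc[0] < 0:  # deterministic orientation: top gene positive
        ranked = -ranked
    result = SignatureResult(
        pc1_variance_fraction=float(fractions[0]),
        variance_fractions=fractions,
        loadings=ranked,
        top_n=n_top,
        up_set=[],
        down_set=[],
    )
    result.up_set, result.down_set = partition_by_sign(result)
    return result


def partition_by_sign(s: SignatureResult) -> tuple[list[str], list[str]]:
    """Split the top-N genes into positive-loading and negative-loading sets.

    Exact-zero loadings belong to neither set and trigger a warning.
    """
    top = s.loadings.iloc[: s.top_n]
    zero = top.index[top == 0]
    if len(zero) > 0:
        warnings.warn(f"{len(zero)} top genes have exactly zero PC1 loading; excluded")
    up = list(top.index[top > 0])
    down = list(top.index[top < 0])
    return up, down


def signature_frame(s: SignatureResult) -> pd.DataFrame:
    """Ranked loadings with rank, top-N membership, and up/down direction."""
    df = pd.DataFrame({"pc1_loading": s.loadings})
    df.index.name = "gene_id"
    df["rank"] = np.arange(1, len(df) + 1)
    df["in_top"] = df["rank"] <= s.top_n
    df["direction"] = np.where(df["pc1_loading"] > 0, "up", np.where(df["pc1_loading"] < 0, "down", "zero"))
    return df
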