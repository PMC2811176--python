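"""Normalization and global QC for ratio matrices.

Quantile normalization forces every sample's empirical distribution onto
the across-sample mean of order statistics while preserving each sample's
internal ranking; tied input values receive the mean of the target values
they jointly span.  QC surfaces are the all-pairs Pearson correlation
table and a Ward minimum-variance dendrogram over samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_model import MethylationMatrix

__all__ = [
    "quantile_normalize",
    "center_arrays",
    "pairwise_pearson",
    "ward_cluster",
    "tree_to_newick",
    "qc_report",
]

log = logging.getLogger(__name__)


def quantile_normalize(matrix: MethylationMatrix) -> MethylationMatrix:
    """Quantile-normalize sample columns to the mean of order statistics.

    Loci with missing values must be removed beforehand (see
    ``MethylationMatrix.drop_incomplete_loci``).  A single-sample matrix
    is returned unchanged with a warning: there is nothing to normalize
    against.
    """
    if matrix.n_samples < 2:
        log.warning("quantile_normalize: single-sample matrix returned unchanged")
        return MethylationMatrix(matrix.values.copy(), dict(matrix.intervals))
    vals = matrix.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError(
            "quantile_normalize requires complete loci; drop missing values first"
        )
    order = np.argsort(vals, axis=0, kind="stable")
    target = np.sort(vals, axis=0).mean(axis=1)  # mean of order statistics
    out = np.empty_like(vals)
    rows = np.arange(vals.shape[0])
    for j in range(vals.shape[1]):
        col = np.empty(vals.shape[0])
        col[order[:, j]] = target
        # ties: every member of a tied group gets the mean of the target
        # values the group occupies
        s = pd.Series(col).groupby(pd.Series(vals[:, j])).transform("mean")
        out[:, j] = s.to_numpy()
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return MethylationMatrix(df, dict(matrix.intervals))


def center_arrays(matrix: MethylationMatrix, how: str = "median") -> MethylationMatrix:
    """Subtract each sample column's median (or mean) from that column."""
    if how not in ("median", "mean"):
        raise ValueError("how must be 'median' or 'mean'")
    vals = matrix.values
    center = vals.median(axis=0) if how == "median" else vals.mean(axis=0)
    return MethylationMatrix(vals - center, dict(matrix.intervals))


def pairwise_pearson(matrix: MethylationMatrix) -> pd.DataFrame:
    """Sample x sample Pearson correlation table.

    Each pairwise correlation uses loci with no missing value in either
    sample; a zero-variance column yields NaN for its pairs (diagonal is
    forced to 1 for samples with at least one observation).
    """
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 samples")
    if matrix.n_loci < 3:
        raise ValueError("need >= 3 loci")
    corr = matrix.values.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def ward_cluster(matrix: MethylationMatrix) -> np.ndarray:
    """Agglomerative clustering of samples, Ward's criterion on Euclidean distance.

    Returns the scipy linkage matrix (merge list + heights).  Loci with
    any missing value are excluded from the distance computation.
    Deterministic: equal-height merges resolve to the lowest-index pair
    (scipy's ordering).
    """
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 samples")
    complete, _ = matrix.drop_incomplete_loci()
    X = complete.values.to_numpy(dtype=float).T  # samples x loci
    return hierarchy.linkage(pdist(X, metric="euclidean"), method="ward")


def tree_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    def rec_root(node) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:0"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right})"

    return rec_root(tree) + ";"


def qc_report(matrix: MethylationMatrix) -> dict:
    """Missingness, per-sample distribution summary, and correlation table."""
    vals = matrix.values
    summary = pd.DataFrame(
        {
            "n_missing": vals.isna().sum(),
            "mean": vals.mean(),
            "sd": vals.std(ddof=1),
            "median": vals.median(),
        }
    )
    return {
        "n_loci": matrix.n_loci,
        "n_samples": matrix.n_samples,
        "n_loci_with_missing": int(vals.isna().any(axis=1).sum()),
        "sample_summary": summary,
        "pearson": pairwise_pearson(matrix) if matrix.n_samples >= 2 and matrix.n_loci >= 3 else None,
    }
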