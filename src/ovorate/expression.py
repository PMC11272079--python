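"""Expression specificity (tau) and clustering of expression profiles.

tau summarizes how narrowly a gene is expressed over n conditions
(tissues, stages or cell types):

    tau = sum_i (1 - x_i / max(x)) / (n - 1)

on the raw expression values.  tau = 1 means expression confined to a
single condition, tau = 0 means uniform expression; genes expressed
in k of n conditions at equal level have tau = (n - k) / (n - 1).
Genes with tau above 0.90 (strictly) are classed as highly specific.

Expression matrices are plain pandas DataFrames, genes as rows and
condition labels as columns, nonnegative values (RPKM or similar).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger("ovorate")

__all__ = [
    "compute_tau",
    "tau_table",
    "classify_specific",
    "standardize_expression",
    "hierarchical_cluster",
    "read_expression_matrix",
]

TAU_THRESHOLD = 0.90


class UndefinedTauError(ValueError):
    pass


def read_expression_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any():
        raise ValueError("duplicate condition labels")
    return df


def compute_tau(x, log_transform: bool = False) -> float:
    """tau of one gene's expression vector over >= 2 conditions.

    Raw values are used by default; ``log_transform`` applies log2(x + 1)
    first (off by default).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("tau needs a 1-d vector of length >= 2")
    if (x < 0).any():
        raise ValueError("negative expression value")
    if log_transform:
        x = np.log2(x + 1.0)
    mx = x.max()
    if mx == 0:
        raise UndefinedTauError("tau undefined for an all-zero expression vector")
    xhat = x / mx
    return float((1.0 - xhat).sum() / (len(x) - 1))


def tau_table(expr: pd.DataFrame, log_transform: bool = False) -> pd.Series:
    """Per-gene tau; genes with zero maximum expression are excluded
    (count logged)."""
    nonzero = expr.max(axis=1) > 0
    dropped = int((~nonzero).sum())
    if dropped:
        logger.info("tau: excluded %d genes with zero expression everywhere", dropped)
    sub = expr[nonzero]
    return pd.Series(
        [compute_tau(row.to_numpy(), log_transform) for _, row in sub.iterrows()],
        index=sub.index,
        name="tau",
    )


def classify_specific(tau: float, threshold: float = TAU_THRESHOLD) -> str:
    """'highly_specific' iff tau strictly exceeds the threshold."""
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau out of [0, 1]: {tau}")
    return "highly_specific" if tau > threshold else "broad"


def standardize_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across conditions; zero-variance genes dropped."""
    sd = expr.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("standardize: dropped %d zero-variance genes", dropped)
    sub = expr[keep]
    return sub.sub(sub.mean(axis=1), axis=0).div(sd[keep], axis=0)


def hierarchical_cluster(
    expr: pd.DataFrame, metric: str = "euclidean"
) -> str:
    """Average-linkage dendrogram over *conditions* as a newick string.

    Conditions (columns) are clustered on their per-gene profiles with
    average (UPGMA-style) linkage; Euclidean distance by default, with a
    correlation-distance option.  Columns are processed in lexicographic
    label order, fixing tie-breaks.
    """
    if expr.shape[1] < 3:
        raise ValueError("clustering needs at least 3 conditions")
    labels = sorted(expr.columns)
    profiles = expr[labels].to_numpy().T  # conditions x genes
    if metric == "correlation":
        dist = pdist(profiles, metric="correlation")
    elif metric == "euclidean":
        dist = pdist(profiles, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    linkage = hierarchy.linkage(dist, method="average")
    root = hierarchy.to_tree(linkage)

    def newick(node, parent_height) -> str:
        length = max(parent_height - node.dist, 0.0) / 2.0
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = newick(node.left, node.dist)
        right = newick(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    inner = newick(root, root.dist)
    # strip the root's zero-length suffix
    return inner.rsplit(":", 1)[0] + ";"
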