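"""Genus-composition pipeline: coverage filter, relative abundance,
per-host averaging, top-N collapse and Euclidean hierarchical clustering.

The stage order mirrors the analysis it implements: samples with fewer
than 1,000 aligned counts are dropped, counts become per-sample fractions,
fractions are averaged per host category, the 10 most abundant genera keep
their columns with everything else pooled into ``others``, and profiles are
clustered on pairwise Euclidean distances.  The same clustering operation
is reused on KO paralog matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "Dendrogram",
    "filter_low_coverage",
    "relative_abundance",
    "host_mean_composition",
    "top_n_collapse",
    "hclust_euclidean",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_TOTAL = 1000
DEFAULT_TOP_N = 10
OTHERS_LABEL = "others"
_LINKAGES = ("average", "single", "complete", "ward")


@dataclass
class Dendrogram:
    """Binary merge tree over row labels, as a SciPy linkage matrix."""

    labels: list[str]
    linkage: np.ndarray

    def cut(self, k: int) -> dict[str, int]:
        """Assign each label a cluster id (1..k) by cutting into k clusters."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_newick(self) -> str:
        """Serialize as Newick; branch lengths derive from merge heights."""
        root = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                label = self.labels[node.id]
                if any(ch in label for ch in "(),:;'\t \n"):
                    label = "'" + label.replace("'", "''") + "'"
                return f"{label}:{parent_height:.10g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = fmt(root.left, root.dist)
        right = fmt(root.right, root.dist)
        return f"({left},{right});"


def filter_low_coverage(
    counts: pd.DataFrame, min_total: int = DEFAULT_MIN_TOTAL
) -> pd.DataFrame:
    """Drop samples whose total count is below ``min_total`` (strict).

    Survivor order is preserved; removing every sample is an error.
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=1)
    keep = totals >= min_total
    for sample in counts.index[~keep]:
        logger.info(
            "sample %s dropped: total count %d < %d",
            sample,
            int(totals[sample]),
            min_total,
        )
    if not keep.any():
        raise ValueError(f"all samples fall below the coverage threshold {min_total}")
    return counts.loc[keep]


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Convert counts to per-sample fractions (each row sums to 1)."""
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = list(counts.index[totals <= 0])
        raise ValueError(f"zero-total samples (filter first): {bad}")
    return counts.div(totals, axis=0)


def host_mean_composition(
    fractions: pd.DataFrame, sample_to_host: Mapping[str, str]
) -> pd.DataFrame:
    """Unweighted mean of per-sample fractions within each host category."""
    missing = [s for s in fractions.index if s not in sample_to_host]
    if missing:
        raise ValueError(f"samples without host label: {missing}")
    hosts = pd.Series({s: sample_to_host[s] for s in fractions.index})
    means = fractions.groupby(hosts).mean()
    means.index.name = None
    return means


def top_n_collapse(host_matrix: pd.DataFrame, n: int = DEFAULT_TOP_N) -> pd.DataFrame:
    """Keep the ``n`` genera with the largest mean abundance across hosts;
    sum all remaining genera into an ``others`` column.  Row sums are
    preserved; with ``n`` >= the genus count the matrix is returned as is.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if host_matrix.shape[1] <= n:
        return host_matrix.copy()
    ranking = host_matrix.mean(axis=0).sort_values(ascending=False, kind="stable")
    top = list(ranking.index[:n])
    rest = [g for g in host_matrix.columns if g not in top]
    collapsed = host_matrix[top].copy()
    collapsed[OTHERS_LABEL] = host_matrix[rest].sum(axis=1)
    return collapsed


def hclust_euclidean(matrix: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of rows on pairwise Euclidean distances.

    ``linkage`` is one of average (UPGMA, the default), single, complete or
    ward.  Requires >= 2 rows and no missing values.
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs >= 2 rows")
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values")
    dists = pdist(matrix.values.astype(float), metric="euclidean")
    z = hierarchy.linkage(dists, method=linkage)
    return Dendrogram(labels=[str(lb) for lb in matrix.index], linkage=z)
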