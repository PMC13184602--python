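"""Pattern discovery: variable-feature PCA, clustering, and set overlaps.

The working object is a methylation matrix: rows are features (genes or
exon-level aggregates), columns are samples, entries are methylation levels
in percent. Features with a level missing in any sample (gene not covered
there) are dropped before variance ranking — complete-case analysis, no
imputation. PCA runs on centred, unscaled levels (all features share the
percent unit); scaling is available as a flag.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .io import MethkitError

logger = logging.getLogger(__name__)

__all__ = [
    "build_matrix",
    "top_k_variable",
    "pca",
    "PCAResult",
    "cluster_common_hyper",
    "ClusterResult",
    "overlap_counts",
    "OverlapReport",
]


def build_matrix(
    gene_tables: Mapping[str, pd.DataFrame], value_col: str = "level_pct"
) -> pd.DataFrame:
    """Feature x sample level matrix from per-sample gene tables (complete cases)."""
    cols = {}
    for sample_id in sorted(gene_tables):
        t = gene_tables[sample_id]
        cols[sample_id] = t.set_index("gene_id")[value_col]
    mat = pd.DataFrame(cols)
    return mat.dropna(axis=0)


def top_k_variable(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    """The k features with the largest across-sample variance (n-1 denominator).

    Ties are broken by feature identifier order; k larger than the number of
    features is clipped with a warning.
    """
    if k > len(matrix):
        logger.warning("k=%d exceeds %d features; clipping", k, len(matrix))
        k = len(matrix)
    variances = matrix.var(axis=1, ddof=1)
    ranked = variances.sort_index().sort_values(ascending=False, kind="stable")
    return matrix.loc[ranked.index[:k]]


@dataclass
class PCAResult:
    scores: pd.DataFrame = field(repr=False)  # samples x components
    loadings: pd.DataFrame = field(repr=False)  # features x components
    explained_variance_ratio: np.ndarray = field(default=None)


def pca(matrix: pd.DataFrame, scale: bool = False, n_components: int | None = None) -> PCAResult:
    """PCA of samples in feature space (samples are observations).

    Components are ordered by non-increasing explained variance; with all
    components retained the scores reproduce the centred data exactly.
    Raises :class:`MethkitError` on a constant matrix (zero total variance).
    """
    X = matrix.to_numpy(dtype=float).T  # samples x features
    if X.shape[0] < 2:
        raise MethkitError("PCA requires at least two samples")
    if np.allclose(X.var(axis=0), 0):
        raise MethkitError("PCA skipped: matrix has zero variance")
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp_names),
        loadings=pd.DataFrame(model.components_.T, index=matrix.index, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


@dataclass
class ClusterResult:
    linkage: np.ndarray = field(repr=False)
    labels: list[str] = field(default_factory=list)
    newick: str = ""
    n_features: int = 0


def cluster_common_hyper(
    gene_tables: Mapping[str, pd.DataFrame],
    hyper_min_pct: float = 70.0,
    metric: str = "euclidean",
    method: str = "average",
    axis: str = "samples",
) -> ClusterResult | None:
    """Hierarchical clustering over genes hypermethylated in *every* sample.

    The common set is genes whose gene-level exonic methylation is at or
    above ``hyper_min_pct`` in all samples of the comparison. Returns None
    (with a log message) when the common set is empty. ``axis`` selects
    whether samples (default) or genes are clustered.
    """
    mat = build_matrix(gene_tables)
    common = mat[(mat >= hyper_min_pct).all(axis=1)]
    if common.empty:
        logger.info("no genes hypermethylated in every sample; clustering skipped")
        return None
    data = common.T if axis == "samples" else common
    labels = list(data.index)
    if len(labels) < 2:
        logger.info("fewer than two observations to cluster; skipped")
        return None
    Z = hierarchy.linkage(data.to_numpy(dtype=float), method=method, metric=metric)
    return ClusterResult(
        linkage=Z, labels=labels, newick=_linkage_to_newick(Z, labels), n_features=len(common)
    )


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    # ultrametric convention: a node sits at half its merge height, so the
    # path between two leaves equals their cophenetic (linkage) distance
    tree = hierarchy.to_tree(Z)

    def fmt(node, parent_height):
        height = node.dist / 2.0
        length = parent_height - height
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = fmt(node.left, height)
        right = fmt(node.right, height)
        return f"({left},{right}):{length:.10g}"

    root_height = tree.dist / 2.0
    return f"({fmt(tree.left, root_height)},{fmt(tree.right, root_height)});"


@dataclass
class OverlapReport:
    """Inclusion-exclusion decomposition of 2-3 labelled sets.

    ``regions`` maps a tuple of member labels (e.g. ``('control','drought')``
    for the exclusive pairwise region) to the number of elements found in
    exactly those sets; the disjoint region counts sum to the union size.
    """

    labels: tuple[str, ...]
    regions: dict[tuple[str, ...], int]

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    @property
    def common_to_all(self) -> int:
        return self.regions.get(self.labels, 0)

    def unique_to(self, label: str) -> int:
        return self.regions.get((label,), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [("+".join(k), v) for k, v in sorted(self.regions.items())]
        return pd.DataFrame(rows, columns=["region", "count"])


def overlap_counts(sets: Mapping[str, set]) -> OverlapReport | list[OverlapReport]:
    """Exclusive-region counts for 2 or 3 labelled sets.

    With more than three sets, every pair and triple gets its own report
    (returned as a list).
    """
    labels = tuple(sorted(sets))
    if len(labels) < 2:
        raise MethkitError("overlap requires at least two sets")
    if len(labels) > 3:
        reports = []
        for r in (2, 3):
            for combo in itertools.combinations(labels, r):
                reports.append(overlap_counts({l: sets[l] for l in combo}))
        return reports
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(set(sets[l]) for l in combo))
            outside = set.union(
                *(set(sets[l]) for l in labels if l not in combo), set()
            ) if len(combo) < len(labels) else set()
            regions[combo] = len(inside - outside)
    return OverlapReport(labels=labels, regions=regions)
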