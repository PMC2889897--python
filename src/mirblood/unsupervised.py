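"""Unsupervised sample structure: variance screening, complete-linkage
hierarchical clustering with a two-cluster Fisher exact test, and PCA.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA


def select_top_variance(m: pd.DataFrame, k: int) -> pd.DataFrame:
    """Submatrix of the ``k`` features with the largest across-sample variance.

    Ties are broken by feature id in lexicographic order so the selection is
    deterministic.
    """
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    if k > m.shape[0]:
        raise ValueError(f"k={k} exceeds feature count {m.shape[0]}")
    variances = m.var(axis=1, ddof=1)
    order = sorted(m.index, key=lambda fid: (-variances[fid], fid))
    selected = m.loc[order[:k]]
    selected.attrs = dict(m.attrs)
    return selected


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative merge history over samples (scipy linkage encoding)."""

    linkage: np.ndarray  # (n-1, 4) merge matrix
    leaf_ids: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def cut(self, n_clusters: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(labels, index=list(self.leaf_ids), name="cluster")

    def to_newick(self) -> str:
        """Newick string with merge heights converted to branch lengths."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, list(self.leaf_ids))
        return str(tree).strip()


def hierarchical_cluster(
    m: pd.DataFrame, scale_features: bool = False
) -> ClusterTree:
    """Bottom-up complete-linkage clustering of samples, Euclidean distance.

    Samples are the columns of the expression matrix; distances are computed
    on the feature vectors as given (optionally z-scored per feature with
    ``scale_features``, off by default).
    """
    if m.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    X = m.to_numpy(dtype=float).T
    if np.isnan(X).any():
        raise ValueError("expression matrix contains NaN")
    if scale_features:
        sd = X.std(axis=0, ddof=1)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="complete")
    return ClusterTree(linkage=Z, leaf_ids=tuple(m.columns))


@dataclass(frozen=True)
class TwoCutResult:
    """Two-cluster cut of the dendrogram crossed against disease status."""

    labels: pd.Series  # cluster 1/2 per sample
    table: np.ndarray  # 2x2, rows = clusters, cols = (control, diseased)
    fisher_p: float


def two_cut_fisher(
    tree: ClusterTree, ann: pd.DataFrame, diseased_groups=("M", "N")
) -> TwoCutResult:
    """Cut the tree into two clusters and Fisher-test them against disease status.

    The melanoma test and validation arms are pooled as "diseased" by
    default. The two-tailed Fisher exact p-value sums hypergeometric point
    probabilities no larger than the observed table's.
    """
    labels = tree.cut(2)
    groups = ann.set_index("sample_id").loc[list(tree.leaf_ids), "group"]
    diseased = groups.isin(tuple(diseased_groups))
    if diseased.all() or (~diseased).all():
        raise ValueError("both disease states must be present")
    table = np.array(
        [
            [int(((labels == c) & ~diseased).sum()), int(((labels == c) & diseased).sum())]
            for c in (1, 2)
        ]
    )
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return TwoCutResult(labels=labels, table=table, fisher_p=p)


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame  # samples x components
    explained_fraction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return self.scores


def pca(m: pd.DataFrame, n_components: int = 2) -> PcaResult:
    """Mean-centered PCA of samples in feature space (no feature scaling).

    The sign of each component is fixed by forcing its largest-magnitude
    loading positive, so scores are reproducible across library versions.
    Requests beyond the available rank are truncated with a warning.
    """
    if m.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    X = m.to_numpy(dtype=float).T
    max_rank = min(X.shape[0], X.shape[1])
    if n_components > max_rank:
        import warnings

        warnings.warn(
            f"truncating n_components from {n_components} to rank {max_rank}",
            stacklevel=2,
        )
        n_components = max_rank
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    for i in range(n_components):
        loading = model.components_[i]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, i] *= -1.0
    frame = pd.DataFrame(
        scores,
        index=list(m.columns),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return PcaResult(scores=frame, explained_fraction=model.explained_variance_ratio_.copy())
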