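"""Hierarchical clustering, dendrogram groups, group ORA, and PCA.

Standardized site profiles are clustered with Euclidean average linkage,
the dendrogram is cut into a fixed number of groups, and each group is
tested for gene-ontology over-representation against all other groups with
Fisher's exact test.  PCA runs on tissue-sex samples as observations with
sites as features, with a deterministic loading sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .config import PipelineConfig
from .enrichment import fisher_exact_2x2


@dataclass
class Dendrogram:
    """Agglomerative clustering result over matrix rows."""

    linkage: np.ndarray         # scipy linkage matrix, (n-1) x 4
    leaves: list[str]           # row keys, leaf index order

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def leaf_order(self) -> list[str]:
        return [self.leaves[i] for i in hierarchy.leaves_list(self.linkage)]


@dataclass
class PCAResult:
    scores: pd.DataFrame               # samples x components
    loadings: pd.DataFrame             # features x components
    explained_variance_ratio: np.ndarray


def cluster_rows(
    matrix: pd.DataFrame, cfg: PipelineConfig | None = None
) -> Dendrogram:
    """Average-linkage dendrogram on Euclidean row distances."""
    cfg = cfg or PipelineConfig()
    if len(matrix) < 2:
        raise ValueError("clustering requires at least 2 rows")
    if matrix.isna().any().any():
        raise ValueError("clustering input must have no missing values")
    dists = pdist(matrix.to_numpy(dtype=float), metric=cfg.cluster_metric)
    Z = hierarchy.linkage(dists, method=cfg.cluster_linkage)
    return Dendrogram(Z, list(matrix.index))


def cut_groups(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Cut the dendrogram into exactly k groups (labels 0..k-1 per leaf)."""
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    labels = hierarchy.cut_tree(dendrogram.linkage, n_clusters=k).ravel()
    return pd.Series(labels, index=dendrogram.leaves, name="group")


def group_ora(
    groups: pd.Series,
    leaf_proteins: dict[str, str],
    annotations: dict[str, set[str]],
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-group GO over-representation versus all other groups.

    For each (group, term): a 2x2 table of in-group vs rest leaves,
    annotated vs not (a leaf is annotated when its protein's closed term
    set contains the term), tested one-sided by default.  Returns a long
    table with counts, p-value, and a significance flag at ``ora_alpha``.
    """
    cfg = cfg or PipelineConfig()
    leaves = list(groups.index)
    n = len(leaves)
    terms = sorted(set().union(*(
        annotations.get(leaf_proteins[leaf], set()) for leaf in leaves
    )) if leaves else set())
    term_leaves = {
        t: {leaf for leaf in leaves if t in annotations.get(leaf_proteins[leaf], set())}
        for t in terms
    }
    rows = []
    for g in sorted(groups.unique()):
        members = set(groups.index[groups == g])
        m = len(members)
        for t in terms:
            a = len(term_leaves[t] & members)          # in-group, annotated
            b = m - a                                  # in-group, not
            c = len(term_leaves[t]) - a                # rest, annotated
            d = (n - m) - c
            p = fisher_exact_2x2(
                [[a, b], [c, d]], alternative=cfg.ora_alternative
            )
            rows.append((g, t, a, b, c, d, p, p < cfg.ora_alpha))
    return pd.DataFrame(
        rows,
        columns=[
            "group", "term", "in_annot", "in_not",
            "out_annot", "out_not", "pvalue", "significant",
        ],
    )


def pca(
    matrix: pd.DataFrame, cfg: PipelineConfig | None = None, n_components: int | None = None
) -> PCAResult:
    """PCA with samples (columns) as observations and sites (rows) as features.

    Loadings keep a deterministic sign: within each component the
    largest-magnitude loading entry is made positive.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    X = matrix.to_numpy(dtype=float).T            # samples x features
    k = n_components or min(X.shape)
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T                # features x components
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.index, columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def top_loading_features(
    result: PCAResult, component: str = "PC1", k: int = 10
) -> pd.Series:
    """Features ranked by |loading| on one component, largest first."""
    col = result.loadings[component]
    return col.reindex(col.abs().sort_values(ascending=False).index).head(k)


def top_features_both(result: PCAResult, k: int = 10) -> list[str]:
    """Features in the top-k by |loading| on both PC1 and PC2."""
    top1 = set(top_loading_features(result, "PC1", k).index)
    top2 = set(top_loading_features(result, "PC2", k).index)
    both = top1 & top2
    order = (
        result.loadings.loc[list(both), ["PC1", "PC2"]].abs().min(axis=1)
        if both else pd.Series(dtype=float)
    )
    return list(order.sort_values(ascending=False).index)
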