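"""Sample-structure analyses: PCA of cells, Ward hierarchical clustering,
and hypergeometric over-representation of gene sets.

Cells (samples) are embedded on log10(value + 1) profiles with genes
centered but not scaled; principal components are ordered by explained
variance with the sign fixed so the largest-magnitude gene loading is
positive. Clustering uses Ward linkage on Euclidean distances of the same
transformed profiles; samples are processed in sorted-id order, which makes
the tree invariant to input column order and gives deterministic
tie-breaking. Over-representation of a selected gene list against named
gene sets uses the upper-tail hypergeometric test with BH adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .iohub import ExpressionMatrix


def _transform(matrix: ExpressionMatrix, pseudo_count: float = 1.0) -> pd.DataFrame:
    """log10(value + pseudo) with per-gene centering; samples in rows."""
    logged = np.log10(matrix.values.to_numpy(dtype=float) + pseudo_count)
    centered = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered.T, index=matrix.values.columns, columns=matrix.values.index)


def pca_embed(
    matrix: ExpressionMatrix,
    n_components: int = 3,
    pseudo_count: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of samples on transformed expression profiles.

    Returns (sample scores, gene loadings, explained-variance fractions).
    Components are orthonormal in gene space, ordered by decreasing
    explained variance; the variance fractions sum to <= 1 (= 1 over the
    full rank).
    """
    n_samples = matrix.shape[1]
    n_genes = matrix.shape[0]
    if n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    max_rank = min(n_genes, n_samples - 1)
    if n_components > max_rank:
        raise ValueError(f"n_components {n_components} exceeds max rank {max_rank}")
    X = _transform(matrix, pseudo_count)
    if np.ptp(X.to_numpy()) == 0:
        raise ValueError("constant matrix has no variance to decompose")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X.to_numpy())
    loadings = pca.components_.T  # genes x components
    # sign convention: largest-|loading| gene positive per component
    for k in range(n_components):
        idx = np.argmax(np.abs(loadings[:, k]))
        if loadings[idx, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return (
        pd.DataFrame(scores, index=X.index, columns=comp_names),
        pd.DataFrame(loadings, index=matrix.values.index, columns=comp_names),
        pca.explained_variance_ratio_,
    )


def ward_cluster(matrix: ExpressionMatrix, pseudo_count: float = 1.0) -> str:
    """Ward-linkage dendrogram of samples, serialized as Newick with branch
    lengths.

    Samples are sorted by id before clustering, so permuting the input
    columns yields the identical tree.
    """
    if matrix.shape[1] < 2:
        raise ValueError("clustering needs >= 2 samples")
    sample_ids = sorted(matrix.values.columns)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    X = _transform(matrix.subset_samples(sample_ids), pseudo_count).to_numpy()
    linkage = hierarchy.linkage(X, method="ward")
    tree = hierarchy.to_tree(linkage)

    def newick(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{sample_ids[node.id]}:{length:.10g}"
        left = newick(node.left, node.dist)
        right = newick(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    body = newick(tree, tree.dist)
    # root has no branch above it; strip its length
    body = body.rsplit(":", 1)[0]
    return body + ";"


def cut_two_clusters(matrix: ExpressionMatrix, pseudo_count: float = 1.0) -> dict[str, int]:
    """Partition samples into two flat clusters from the Ward tree."""
    sample_ids = sorted(matrix.values.columns)
    X = _transform(matrix.subset_samples(sample_ids), pseudo_count).to_numpy()
    linkage = hierarchy.linkage(X, method="ward")
    labels = hierarchy.fcluster(linkage, t=2, criterion="maxclust")
    return dict(zip(sample_ids, (int(v) for v in labels)))


@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    universe_size: int
    set_size: int
    selected_size: int
    overlap: int
    p_hyper: float
    q_bh: float


def ora_hypergeom(
    selected: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
) -> list[EnrichmentRecord]:
    """Upper-tail hypergeometric over-representation of ``selected`` in each
    gene set, BH-adjusted across the collection.

    Gene sets are intersected with the universe before testing; ``selected``
    must be a subset of the universe. p = P(X >= k) for overlap k under
    hypergeometric(N, K, n).
    """
    if not universe:
        raise ValueError("empty universe")
    if not selected <= universe:
        extra = sorted(selected - universe)[:5]
        raise ValueError(f"selected genes outside universe: {extra}")
    N = len(universe)
    n = len(selected)
    names, pvals, rows = [], [], []
    for name, members in gene_sets.items():
        in_universe = members & universe
        K = len(in_universe)
        k = len(in_universe & selected)
        # P(X >= k); sf(k-1) is the inclusive upper tail
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        names.append(name)
        pvals.append(min(p, 1.0))
        rows.append((name, N, K, n, k))
    if not rows:
        return []
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return [
        EnrichmentRecord(name, N, K, n, k, p, float(q))
        for (name, N, K, n, k), p, q in zip(rows, pvals, qvals)
    ]


def top_loading_genes(loadings: pd.DataFrame, component: str, m: int = 500) -> set[str]:
    """The m genes with largest absolute loading on a component — the
    default selection feeding per-component over-representation analysis."""
    if component not in loadings.columns:
        raise KeyError(f"no component {component!r}")
    ranked = loadings[component].abs().sort_values(ascending=False)
    return set(ranked.index[:m])
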