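"""Clustering of the fused embedding and the evaluation metric suite.

Leiden runs on a KNN graph of the embedding, with a bisection over the
resolution parameter when a target number of domains is requested.
External metrics (ARI, NMI, pairwise F1) compare against ground-truth
labels; internal metrics (silhouette, Davies-Bouldin) score geometry
when no truth exists. A Wilcoxon rank-sum marker table and a
domain-level pathway-activity summary support downstream biology.
"""
from __future__ import annotations

import warnings

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn import metrics as skm
from sklearn.neighbors import kneighbors_graph
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    ActivityMatrix,
    DomainLabels,
    ExpressionMatrix,
    FusedEmbedding,
    check_aligned,
)


def _leiden_once(graph: igraph.Graph, resolution: float, seed: int) -> np.ndarray:
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def leiden_cluster(
    H: FusedEmbedding | np.ndarray,
    n_domains: int | None = None,
    resolution: float | None = None,
    seed: int = 0,
    knn: int = 15,
) -> DomainLabels:
    """Leiden clustering of the embedding.

    Exactly one of ``n_domains`` / ``resolution`` must be given. With
    ``n_domains``, the resolution is found by bisection over
    [0.01, 3.0] (max 40 iterations); if no resolution yields the exact
    count, the nearest-count labeling is returned with a warning.
    """
    if (n_domains is None) == (resolution is None):
        raise ValueError("give exactly one of n_domains or resolution")
    X = H.H if isinstance(H, FusedEmbedding) else np.asarray(H, float)
    cell_ids = (
        list(H.cell_ids)
        if isinstance(H, FusedEmbedding)
        else [str(i) for i in range(len(X))]
    )
    n = len(X)
    if n_domains is not None and n_domains > n:
        raise ValueError("more domains requested than cells")

    k = min(knn, n - 1)
    adj = kneighbors_graph(X, n_neighbors=k, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    graph = igraph.Graph(n=n, edges=edges)
    graph.es["weight"] = [1.0] * len(edges)

    if resolution is not None:
        return DomainLabels(cell_ids, _leiden_once(graph, resolution, seed))

    lo, hi = 0.01, 3.0
    best_labels, best_gap = None, None
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        labels = _leiden_once(graph, mid, seed)
        k_found = len(np.unique(labels))
        gap = abs(k_found - n_domains)
        if best_gap is None or gap < best_gap:
            best_labels, best_gap = labels, gap
        if k_found == n_domains:
            break
        if k_found < n_domains:
            lo = mid
        else:
            hi = mid
    if best_gap:
        warnings.warn(
            f"bisection did not reach {n_domains} clusters; returning the "
            f"nearest result ({len(np.unique(best_labels))})"
        )
    return DomainLabels(cell_ids, best_labels)


def _aligned_labels(truth: DomainLabels, pred: DomainLabels):
    if len(truth.labels) != len(pred.labels):
        raise ValueError("partitions have different lengths")
    check_aligned(truth, pred)
    return truth.labels, pred.labels


def contingency(truth: DomainLabels, pred: DomainLabels) -> np.ndarray:
    t, p = _aligned_labels(truth, pred)
    return skm.cluster.contingency_matrix(t, p)


def ari(truth: DomainLabels, pred: DomainLabels) -> float:
    """Hubert-Arabie adjusted Rand index, in [-1, 1]."""
    t, p = _aligned_labels(truth, pred)
    return float(skm.adjusted_rand_score(t, p))


def nmi(truth: DomainLabels, pred: DomainLabels, average: str = "geometric") -> float:
    """Normalized mutual information, geometric-mean normalization by
    default (arithmetic available via ``average``)."""
    t, p = _aligned_labels(truth, pred)
    return float(
        skm.normalized_mutual_info_score(t, p, average_method=average)
    )


def pairwise_f1(truth: DomainLabels, pred: DomainLabels) -> float:
    """F1 over co-clustered cell pairs.

    Precision = co-clustered pairs of ``pred`` that are co-clustered in
    ``truth``; recall the converse; F1 their harmonic mean. Returns 0
    with a warning when ``pred`` co-clusters no pair.
    """
    t, p = _aligned_labels(truth, pred)
    c = skm.cluster.contingency_matrix(t, p).astype(float)

    def pairs(x):
        return (x * (x - 1) / 2).sum()

    tp = pairs(c)
    pred_pairs = pairs(c.sum(axis=0))
    true_pairs = pairs(c.sum(axis=1))
    if pred_pairs == 0:
        warnings.warn("prediction co-clusters no pair; F1 defined as 0")
        return 0.0
    if true_pairs == 0:
        return 0.0
    precision = tp / pred_pairs
    recall = tp / true_pairs
    if precision + recall == 0:
        return 0.0
    return float(2 * precision * recall / (precision + recall))


def silhouette_db(
    H: FusedEmbedding | np.ndarray, labels: DomainLabels
) -> tuple[float, float]:
    """Silhouette coefficient and Davies-Bouldin index (Euclidean)."""
    X = H.H if isinstance(H, FusedEmbedding) else np.asarray(H, float)
    lab = labels.labels
    if len(np.unique(lab)) < 2:
        raise ValueError("internal indices require at least two clusters")
    sc = float(skm.silhouette_score(X, lab, metric="euclidean"))
    db = float(skm.davies_bouldin_score(X, lab))
    return sc, db


def wilcoxon_markers(
    expr: ExpressionMatrix, labels: DomainLabels
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker table per domain.

    Normal approximation with tie correction, two-sided p, and
    Benjamini-Hochberg q within each domain; positive statistic means
    higher expression inside the domain. Sorted by domain then by
    decreasing statistic.
    """
    check_aligned(expr, labels)
    X = np.asarray(expr.counts, dtype=float)
    lab = labels.labels
    ranks = np.apply_along_axis(rankdata, 0, X)
    tie_term = np.zeros(X.shape[1])  # tie correction per gene
    for gi in range(X.shape[1]):
        _, counts = np.unique(X[:, gi], return_counts=True)
        tie_term[gi] = (counts**3 - counts).sum()
    rows = []
    for dom in np.unique(lab):
        inside = lab == dom
        n1, n2 = int(inside.sum()), int((~inside).sum())
        if n1 < 2 or n2 < 2:
            warnings.warn(f"domain {dom} too small for rank-sum testing")
            continue
        r1 = ranks[inside].sum(axis=0)
        n = n1 + n2
        mu = n1 * (n + 1) / 2.0
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (r1 - mu) / np.sqrt(sigma2)
        from scipy.stats import norm

        pvals = 2 * norm.sf(np.abs(z))
        pvals = np.where(np.isfinite(z), pvals, np.nan)
        finite = np.isfinite(pvals)
        qvals = np.full_like(pvals, np.nan)
        if finite.any():
            qvals[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
        mean_in = X[inside].mean(axis=0)
        mean_out = X[~inside].mean(axis=0)
        lfc = np.log2((mean_in + 1e-9) / (mean_out + 1e-9))
        for gi, gene in enumerate(expr.gene_ids):
            rows.append(
                (int(dom), gene, float(z[gi]) if np.isfinite(z[gi]) else np.nan,
                 pvals[gi], qvals[gi], lfc[gi])
            )
    df = pd.DataFrame(
        rows, columns=["domain", "gene", "statistic", "pval", "qval", "log2fc"]
    )
    return df.sort_values(
        ["domain", "statistic"], ascending=[True, False], na_position="last"
    ).reset_index(drop=True)


def domain_activity_summary(
    activity: ActivityMatrix, labels: DomainLabels
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Domain-level pathway activity profile.

    Returns (median activity domains x pathways, Pearson correlation
    domains x domains of the median vectors, fraction of cells with
    positive activity per domain x pathway). A domain whose median
    vector is constant yields NaN correlations with a warning.
    """
    check_aligned(activity, labels)
    doms = np.unique(labels.labels)
    med = np.stack(
        [np.median(activity.scores[labels.labels == d], axis=0) for d in doms]
    )
    frac = np.stack(
        [(activity.scores[labels.labels == d] > 0).mean(axis=0) for d in doms]
    )
    sd = med.std(axis=1)
    if np.any(sd == 0):
        warnings.warn("constant median-activity vector; correlations are NaN")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(med)
    idx = [f"domain_{d}" for d in doms]
    cols = list(activity.pathway_names)
    return (
        pd.DataFrame(med, index=idx, columns=cols),
        pd.DataFrame(corr, index=idx, columns=idx),
        pd.DataFrame(frac, index=idx, columns=cols),
    )


def umap_project(
    H: FusedEmbedding | np.ndarray, seed: int = 0
) -> np.ndarray:
    """Deterministic 2-D UMAP of the embedding (PCA fallback for n < 10)."""
    X = H.H if isinstance(H, FusedEmbedding) else np.asarray(H, float)
    if len(X) < 10:
        warnings.warn("fewer than 10 cells; using the top two principal axes")
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        return Xc @ vt[:2].T
    import umap

    reducer = umap.UMAP(n_components=2, random_state=seed)
    return np.asarray(reducer.fit_transform(X), dtype=float)
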