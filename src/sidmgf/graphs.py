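"""Spatial and signal graph construction with symmetric normalization.

The spatial graph links cells whose Euclidean distance in platform
coordinates is strictly below a radius r (unweighted). The signal graph
takes a K-nearest-neighbor backbone in pathway-activity space
(Euclidean, union-symmetrized) and weights each retained edge by the
cosine similarity of the two activity profiles. Both feed GCN encoders
through the symmetric normalization D^{-1/2} (A + I) D^{-1/2}.
"""
from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree
from sklearn.neighbors import NearestNeighbors

from .datatypes import ActivityMatrix, CellGraph


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two activity vectors, in [-1, 1].

    A zero-norm vector has no direction; the similarity is defined as 0
    with a warning.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        warnings.warn("cosine similarity of a zero-norm vector defined as 0")
        return 0.0
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def default_radius(coords: np.ndarray, factor: float = 1.2) -> float:
    """Radius heuristic: ``factor`` times the median nearest-neighbor
    distance, so grid platforms give ~4 and hexagonal platforms ~6
    spatial neighbors without platform-specific constants."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least two cells to pick a radius")
    tree = cKDTree(coords)
    d, _ = tree.query(coords, k=2)
    nn = np.median(d[:, 1])
    if nn == 0:
        raise ValueError("median nearest-neighbor distance is zero")
    return float(factor * nn)


def build_spatial_graph(coords: np.ndarray, r: float | None = None) -> CellGraph:
    """Unweighted graph with an edge (i, j) iff dist(S_i, S_j) < r.

    ``r`` defaults to :func:`default_radius`. The inequality is strict;
    duplicate coordinates (distance 0) are linked.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if r is None:
        r = default_radius(coords)
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < r]  # query_pairs is <= r; the contract is strict
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]]) if len(pairs) else []
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]]) if len(pairs) else []
    data = np.ones(len(rows))
    adj = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    graph = CellGraph(adj, kind="spatial", weighted=False)
    return normalize_adjacency(graph)


def build_signal_graph(
    AS: ActivityMatrix | np.ndarray, K: int = 15, nonneg: bool = True
) -> CellGraph:
    """KNN backbone in activity space, cosine-weighted edges.

    Neighbors are found with the Euclidean metric on activity rows and
    the edge set is union-symmetrized (an edge survives if either
    endpoint selected it); each edge then carries the cosine similarity
    of the two rows. ``nonneg`` clips negative cosines to zero during
    normalization (signed weights would make degrees ill-defined).
    """
    X = AS.scores if isinstance(AS, ActivityMatrix) else np.asarray(AS, float)
    n = X.shape[0]
    if K < 1 or K >= n:
        raise ValueError(f"K must satisfy 1 <= K < n cells, got K={K}, n={n}")
    nn = NearestNeighbors(n_neighbors=K + 1, metric="euclidean").fit(X)
    _, idx = nn.kneighbors(X)
    src = np.repeat(np.arange(n), K + 1)
    dst = idx.ravel()
    keep = src != dst
    src, dst = src[keep], dst[keep]
    # drop any surplus neighbor kept because self was not in the K+1 list
    order = np.argsort(src, kind="stable")
    src, dst = src[order], dst[order]
    counts = np.bincount(src, minlength=n)
    mask = np.ones(len(src), dtype=bool)
    pos = 0
    for i in range(n):
        c = counts[i]
        if c > K:
            mask[pos + K : pos + c] = False
        pos += c
    src, dst = src[mask], dst[mask]

    lo, hi = np.minimum(src, dst), np.maximum(src, dst)
    uniq = np.unique(np.stack([lo, hi], axis=1), axis=0)

    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    if np.any(norms == 0):
        warnings.warn("zero-norm activity rows; their cosine weights set to 0")
    num = np.einsum("ij,ij->i", X[uniq[:, 0]], X[uniq[:, 1]])
    w = num / (safe[uniq[:, 0]] * safe[uniq[:, 1]])
    w = np.clip(w, -1.0, 1.0)
    w[(norms[uniq[:, 0]] == 0) | (norms[uniq[:, 1]] == 0)] = 0.0

    rows = np.concatenate([uniq[:, 0], uniq[:, 1]])
    cols = np.concatenate([uniq[:, 1], uniq[:, 0]])
    data = np.concatenate([w, w])
    adj = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    graph = CellGraph(adj, kind="signal", weighted=True)
    return normalize_adjacency(graph, nonneg=nonneg)


def normalize_adjacency(graph: CellGraph, nonneg: bool = True) -> CellGraph:
    """Fill ``norm_propagation`` = D^{-1/2} (A + I) D^{-1/2}.

    With ``nonneg`` (default) negative edge weights are clipped to zero
    before adding self-loops, keeping degrees positive. With signed
    weights a non-positive degree is a hard error suggesting the
    transform.
    """
    A = graph.adjacency.tocoo(copy=True)
    if nonneg:
        A.data = np.maximum(A.data, 0.0)
        A.eliminate_zeros()
    n = A.shape[0]
    deg = np.asarray(A.sum(axis=1)).ravel() + 1.0  # + self-loop
    if np.any(deg <= 0):
        raise ValueError(
            "non-positive degree after adding self-loops; negative edge "
            "weights present — enable the non-negative weight transform"
        )
    dinv = 1.0 / np.sqrt(deg)
    # scale each off-diagonal entry by the symmetric product d_i * d_j,
    # computed once per entry so the result is exactly symmetric
    data = A.data * (dinv[A.row] * dinv[A.col])
    rows = np.concatenate([A.row, np.arange(n)])
    cols = np.concatenate([A.col, np.arange(n)])
    vals = np.concatenate([data, dinv * dinv])
    graph.norm_propagation = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return graph
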