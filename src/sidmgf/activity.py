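"""Pathway activity scoring: expression -> cells x pathways matrix.

The activity-strength matrix ``AS`` is computed with a per-sample,
rank-based enrichment score in the GSVA family: a Poisson kernel CDF
smooths each gene's counts across cells, genes are ranked per cell, and
a weighted random walk down the ranked list yields one score per
(cell, pathway) bounded in [-1, 1].

Preprocessing (quality filtering, highly variable gene selection,
library-size normalization, log1p, scaling) is delegated to scanpy; raw
counts of the retained genes are preserved for the count-likelihood
decoder.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import pdtr

from .datatypes import ActivityMatrix, ExpressionMatrix, PathwayCollection


@dataclass
class KcdfMatrix:
    """Genes x cells kernel-CDF statistics, each entry in [0, 1]."""

    values: np.ndarray
    gene_ids: list[str] | None = None
    cell_ids: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min(initial=0.0) < 0 or self.values.max(initial=0.0) > 1:
            raise ValueError("KCDF statistics must lie in [0, 1]")


def preprocess(
    expr: ExpressionMatrix,
    n_hvg: int = 3000,
    min_counts: int | None = None,
    min_genes: int | None = None,
    target_sum: float = 1e4,
    scale: bool = True,
) -> ExpressionMatrix:
    """Filter, select highly variable genes, normalize, log1p and scale.

    Parameters
    ----------
    expr
        Raw integer counts.
    n_hvg
        Number of highly variable genes retained (dispersion criterion,
        seurat flavor). Clamped with a warning when larger than the gene
        count.
    min_counts, min_genes
        Optional per-cell quality thresholds; ``None`` keeps every cell
        (all-zero cells included) so filtering stays an explicit choice.
    target_sum
        Library-size normalization target per cell before log1p.

    Returns a processed :class:`ExpressionMatrix` whose ``counts`` hold
    the scaled log-expression of the retained genes, with ``raw_counts``
    (raw counts of those genes) and ``size_factors`` (library size over
    median library size) attached for the ZINB reconstruction loss.
    """
    import anndata as ad
    import scanpy as sc

    expr.validate_integer_counts()
    adata = ad.AnnData(X=np.asarray(expr.counts, dtype=np.float64).copy())
    adata.obs_names = expr.cell_ids
    adata.var_names = expr.gene_ids
    adata.obsm["spatial"] = expr.coords.copy()

    if min_counts is not None:
        sc.pp.filter_cells(adata, min_counts=min_counts)
    if min_genes is not None:
        sc.pp.filter_cells(adata, min_genes=min_genes)
    if adata.n_obs == 0:
        raise ValueError("no cells left after quality filtering")

    raw = np.asarray(adata.X, dtype=float).copy()
    libsize = raw.sum(axis=1)
    size_factors = libsize / max(np.median(libsize), 1.0)
    size_factors = np.maximum(size_factors, 1e-8)

    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)

    if n_hvg > adata.n_vars:
        warnings.warn(
            f"n_hvg={n_hvg} exceeds the {adata.n_vars} available genes; "
            "keeping all genes"
        )
        n_hvg = adata.n_vars
    if n_hvg < adata.n_vars:
        # mean-binned dispersion normalization needs a dense mean axis;
        # with few genes fall back to ranking raw dispersions directly
        n_bins = 20 if adata.n_vars >= 100 else 1
        sc.pp.highly_variable_genes(
            adata, n_top_genes=n_hvg, flavor="seurat", n_bins=n_bins
        )
        keep = adata.var["highly_variable"].to_numpy()
    else:
        keep = np.ones(adata.n_vars, dtype=bool)

    raw_kept = raw[:, keep]
    adata = adata[:, keep].copy()
    if scale:
        sc.pp.scale(adata)

    return ExpressionMatrix(
        counts=np.asarray(adata.X, dtype=float),
        cell_ids=[str(i) for i in adata.obs_names],
        gene_ids=[str(i) for i in adata.var_names],
        coords=np.asarray(adata.obsm["spatial"], dtype=float),
        raw_counts=raw_kept,
        size_factors=size_factors,
        processed=True,
    )


def poisson_kcdf(raw_counts: np.ndarray, c: float = 0.5) -> KcdfMatrix:
    """Poisson kernel CDF statistic per gene across cells.

    For gene g and cell j with counts ``x``,

        z[g, j] = (1/n) * sum_m F_Pois(x[g, j]; x[g, m] + c)

    where ``F_Pois(.; lam)`` is the Poisson CDF with rate ``lam`` and
    ``c`` regularizes zero counts. Input is genes x cells, raw counts.
    """
    raw = np.asarray(raw_counts, dtype=float)
    if raw.ndim != 2:
        raise ValueError("expected a genes x cells matrix")
    if np.any(raw < 0):
        raise ValueError("negative counts passed to the Poisson kernel")
    if not np.allclose(raw, np.round(raw)):
        raise ValueError("Poisson kernel requires integer counts")
    n_genes, n_cells = raw.shape
    z = np.empty((n_genes, n_cells))
    for g in range(n_genes):
        # counts repeat heavily, so evaluate the CDF on unique values only
        uniq, inverse, mult = np.unique(
            raw[g], return_inverse=True, return_counts=True
        )
        cdf = pdtr(uniq[:, None], uniq[None, :] + c)
        z[g] = ((cdf * mult[None, :]).sum(axis=1) / n_cells)[inverse]
    return KcdfMatrix(z)


def enrichment_scores(
    kcdf: KcdfMatrix,
    sets: PathwayCollection,
    gene_ids: list[str],
    tau: float = 1.0,
    mode: str = "max_diff",
    chunk: int = 256,
) -> ActivityMatrix:
    """Rank-walk enrichment score per cell and pathway.

    Per cell: genes are ranked by decreasing KCDF statistic (ties broken
    by gene order, stable), the symmetric rank statistic
    ``s = |G/2 - rank|`` is formed, and a walk down the ranked list adds
    ``s**tau`` (normalized by the in-set total) at in-set genes and
    subtracts ``1/(G - |set|)`` at out-of-set genes. With the maximum
    positive deviation ``ES+`` and minimum negative deviation ``ES-``,
    the score is ``ES+ + ES-`` (``max_diff``) or the deviation of larger
    magnitude (``max_abs``); both lie in [-1, 1].
    """
    if mode not in ("max_diff", "max_abs"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    z = kcdf.values
    n_genes, n_cells = z.shape
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length does not match KCDF rows")

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    sets, _missing = sets.restrict_to(gene_ids)
    if len(sets) == 0:
        raise ValueError("no pathway overlaps the gene universe")
    names = sets.names
    k = len(names)
    member = np.zeros((k, n_genes), dtype=bool)
    for si, name in enumerate(names):
        for g in sets.sets[name]:
            member[si, gene_index[g]] = True
    sizes = member.sum(axis=1)
    if np.any(sizes >= n_genes):
        raise ValueError("a gene set covers the whole gene universe")
    out_step = 1.0 / (n_genes - sizes)  # (k,)

    # decreasing-z order with stable tie-break on gene index
    order = np.argsort(-z, axis=0, kind="stable")  # (G, n)
    ranks = np.arange(1, n_genes + 1, dtype=float)
    s_by_position = np.abs(n_genes / 2.0 - ranks) ** tau  # (G,)

    scores = np.empty((n_cells, k))
    for start in range(0, n_cells, chunk):
        sl = slice(start, min(start + chunk, n_cells))
        ord_c = order[:, sl]  # (G, m)
        in_sorted = member[:, ord_c]  # (k, G, m)
        inc = s_by_position[None, :, None] * in_sorted
        denom = inc.sum(axis=1, keepdims=True)
        denom = np.where(denom > 0, denom, 1.0)
        steps = np.where(
            in_sorted, inc / denom, -out_step[:, None, None]
        )
        walk = np.cumsum(steps, axis=1)
        es_pos = np.maximum(walk.max(axis=1), 0.0)
        es_neg = np.minimum(walk.min(axis=1), 0.0)
        if mode == "max_diff":
            sc = es_pos + es_neg
        else:
            sc = np.where(es_pos >= -es_neg, es_pos, es_neg)
        scores[sl] = sc.T
    scores = np.clip(scores, -1.0, 1.0)
    return ActivityMatrix(scores, list(kcdf.cell_ids or range(n_cells)), names)


def compute_activity(
    expr: ExpressionMatrix,
    sets: PathwayCollection,
    tau: float = 1.0,
    mode: str = "max_diff",
) -> ActivityMatrix:
    """Full activity pipeline: Poisson KCDF then rank-walk enrichment.

    Uses the raw counts of the retained genes when preprocessing has
    attached them, otherwise the matrix itself (assumed raw counts).
    Pathways with no gene in the expression universe are dropped with a
    warning.
    """
    raw = expr.raw_counts if expr.raw_counts is not None else expr.counts
    restricted, missing = sets.restrict_to(expr.gene_ids)
    dropped = [n for n in sets.sets if n not in restricted.sets]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} pathway(s) with no gene in the "
            f"expression universe: {dropped[:5]}"
        )
    kcdf = poisson_kcdf(np.asarray(raw, dtype=float).T)
    kcdf.gene_ids = list(expr.gene_ids)
    kcdf.cell_ids = list(expr.cell_ids)
    return enrichment_scores(kcdf, restricted, expr.gene_ids, tau=tau, mode=mode)
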