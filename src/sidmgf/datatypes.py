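"""Core in-memory containers shared across the pipeline.

Every container carries explicit cell identifiers so that misalignment
between stages (expression -> activity -> graphs -> embedding -> labels)
is detectable rather than silent.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Cells x genes count matrix with per-cell 2-D spatial coordinates.

    ``counts`` holds raw (or preprocessed) expression, rows aligned with
    ``cell_ids`` and ``coords`` (platform units, no rescaling applied).
    ``raw_counts`` optionally preserves the untransformed counts of the
    retained genes after preprocessing, for the count-likelihood decoder.
    """

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    coords: np.ndarray
    raw_counts: np.ndarray | None = None
    size_factors: np.ndarray | None = None
    processed: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_ids = list(self.cell_ids)
        self.gene_ids = list(self.gene_ids)
        n, g = self.counts.shape
        if len(self.cell_ids) != n:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n} matrix rows"
            )
        if len(self.gene_ids) != g:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {g} matrix columns"
            )
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape}, expected ({n}, 2)"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if not self.processed and np.any(self.counts < 0):
            raise ValueError("negative entries in count matrix")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def validate_integer_counts(self) -> None:
        """Raise if counts are not whole numbers (floats tolerated)."""
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("count matrix is not integer-valued")


@dataclass
class PathwayCollection:
    """Ordered mapping pathway name -> member gene identifiers."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"empty gene set: {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def restrict_to(self, universe) -> tuple["PathwayCollection", dict]:
        """Intersect each set with a gene universe.

        Returns the restricted collection (empty sets dropped) and a report
        mapping pathway name -> genes that were not found. Matching is
        exact-string and case-sensitive.
        """
        universe = set(universe)
        kept, missing = {}, {}
        for name, genes in self.sets.items():
            inside = [g for g in genes if g in universe]
            outside = [g for g in genes if g not in universe]
            if outside:
                missing[name] = outside
            if inside:
                kept[name] = inside
        return (
            PathwayCollection(
                kept, {k: self.descriptions.get(k, "") for k in kept}
            ),
            missing,
        )


@dataclass
class ActivityMatrix:
    """Cells x pathways activity-strength scores, each entry in [-1, 1]."""

    scores: np.ndarray
    cell_ids: list[str]
    pathway_names: list[str]

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.cell_ids), len(self.pathway_names)):
            raise ValueError("scores shape does not match ids")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite activity scores")
        if np.max(np.abs(self.scores), initial=0.0) > 1.0 + 1e-9:
            raise ValueError("activity scores outside [-1, 1]")


@dataclass
class CellGraph:
    """Sparse symmetric adjacency over cells plus its propagation matrix.

    ``kind`` is "spatial" (unweighted, entries in {0,1}) or "signal"
    (weighted by cosine similarity of activity profiles). The propagation
    matrix is the symmetric normalization D^{-1/2} (A + I) D^{-1/2}; an
    isolated node keeps only its self-loop (identity row).
    """

    adjacency: sp.csr_matrix
    kind: str
    weighted: bool
    norm_propagation: sp.csr_matrix | None = None

    def __post_init__(self):
        a = sp.csr_matrix(self.adjacency)
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if abs(a - a.T).max() > 0:
            raise ValueError("adjacency must be exactly symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency must have a zero diagonal")
        self.adjacency = a

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2


@dataclass
class FusedEmbedding:
    """Fused cells x d representation with per-cell attention weights."""

    H: np.ndarray
    cell_ids: list[str]
    attention: np.ndarray | None = None
    branch_spatial: np.ndarray | None = None
    branch_signal: np.ndarray | None = None

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=float)
        if self.H.ndim != 2 or self.H.shape[1] == 0:
            raise ValueError("embedding must be n x d with d > 0")
        if self.H.shape[0] != len(self.cell_ids):
            raise ValueError("embedding rows do not match cell ids")

    @property
    def n_cells(self) -> int:
        return self.H.shape[0]

    @property
    def dim(self) -> int:
        return self.H.shape[1]


@dataclass
class DomainLabels:
    """Per-cell integer cluster assignments (predicted or ground truth)."""

    cell_ids: list[str]
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(int)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("labels must be integers")
            self.labels = as_int
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        if len(self.cell_ids) != len(self.labels):
            raise ValueError("one label per cell required")

    def relabeled(self) -> "DomainLabels":
        """Map labels onto 0..k-1 preserving first-appearance order."""
        mapping: dict[int, int] = {}
        out = np.empty_like(self.labels)
        for i, lab in enumerate(self.labels):
            out[i] = mapping.setdefault(int(lab), len(mapping))
        return DomainLabels(list(self.cell_ids), out)

    @property
    def n_domains(self) -> int:
        return len(np.unique(self.labels))


def check_aligned(*objs) -> list[str]:
    """Assert all objects share one cell ordering; return the ids."""
    ids = None
    for o in objs:
        oid = list(o.cell_ids)
        if ids is None:
            ids = oid
        elif oid != ids:
            raise ValueError("cell orderings differ between objects")
    return ids or []
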