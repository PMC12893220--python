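"""Readers and writers for every external artifact the pipeline touches.

Supported formats: dense CSV/TSV expression with a sibling coordinate
table, MatrixMarket triplet with ``.rows``/``.cols`` sidecars, AnnData
``.h5ad`` containers, GMT gene sets, TSV label tables, and the result
bundle (embedding TSV, labels TSV, graphs as MatrixMarket, JSON manifest).

Graphs are serialized as *general* MatrixMarket with both symmetric
triangle entries stored, for maximal reader compatibility.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .datatypes import (
    ActivityMatrix,
    CellGraph,
    DomainLabels,
    ExpressionMatrix,
    FusedEmbedding,
    PathwayCollection,
    check_aligned,
)

EXPRESSION_FORMATS = ("csv", "mtx_triplet", "h5_container")


def _read_coords(coords_path, cell_ids: list[str]) -> np.ndarray:
    df = pd.read_csv(coords_path, sep="\t", dtype={"cell_id": str})
    for col in ("cell_id", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"coordinate table missing column {col!r}")
    lookup = dict(zip(df["cell_id"], zip(df["x"], df["y"])))
    coords = np.empty((len(cell_ids), 2), dtype=float)
    for i, cid in enumerate(cell_ids):
        if cid not in lookup:
            raise ValueError(f"missing coordinate for cell {cid!r}")
        coords[i] = lookup[cid]
    return coords


def load_expression(
    path, fmt: str, coords_path=None
) -> ExpressionMatrix:
    """Load a cells x genes count matrix plus spatial coordinates.

    Parameters
    ----------
    path
        The matrix file. For ``mtx_triplet``, sibling ``<path>.rows``
        (cell ids) and ``<path>.cols`` (gene ids) files must exist.
    fmt
        One of ``csv`` (dense, first column = cell id, header = gene ids),
        ``mtx_triplet`` (cells x genes sparse triplet), or
        ``h5_container`` (AnnData on disk; coordinates read from
        ``obsm["spatial"]`` or ``obs[["x", "y"]]``).
    coords_path
        Sibling TSV with columns ``cell_id``, ``x``, ``y``. Required for
        ``csv`` and ``mtx_triplet``; ignored for ``h5_container`` unless
        the container has no embedded coordinates.

    All-zero cells are retained; filtering is an explicit later step.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt not in EXPRESSION_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {EXPRESSION_FORMATS}")

    if fmt == "csv":
        df = pd.read_csv(path, index_col=0)
        counts = df.to_numpy(dtype=float)
        cell_ids = [str(i) for i in df.index]
        gene_ids = [str(c) for c in df.columns]
        if coords_path is None:
            raise ValueError("csv format requires a coords_path TSV")
        coords = _read_coords(coords_path, cell_ids)
    elif fmt == "mtx_triplet":
        rows_file = path.with_name(path.name + ".rows")
        cols_file = path.with_name(path.name + ".cols")
        for f in (rows_file, cols_file):
            if not f.exists():
                raise FileNotFoundError(f"missing sidecar file {f}")
        cell_ids = rows_file.read_text().split()
        gene_ids = cols_file.read_text().split()
        counts = np.asarray(sio.mmread(path).todense(), dtype=float)
        if coords_path is None:
            raise ValueError("mtx_triplet format requires a coords_path TSV")
        coords = _read_coords(coords_path, cell_ids)
    else:  # h5_container
        import anndata as ad

        adata = ad.read_h5ad(path)
        counts = adata.X
        if sp.issparse(counts):
            counts = np.asarray(counts.todense())
        counts = np.asarray(counts, dtype=float)
        cell_ids = [str(i) for i in adata.obs_names]
        gene_ids = [str(i) for i in adata.var_names]
        if "spatial" in adata.obsm:
            coords = np.asarray(adata.obsm["spatial"], dtype=float)[:, :2]
        elif {"x", "y"} <= set(adata.obs.columns):
            coords = adata.obs[["x", "y"]].to_numpy(dtype=float)
        elif coords_path is not None:
            coords = _read_coords(coords_path, cell_ids)
        else:
            raise ValueError(
                "h5 container has no obsm['spatial'] or obs x/y coordinates"
            )

    expr = ExpressionMatrix(counts, cell_ids, gene_ids, coords)
    expr.validate_integer_counts()
    return expr


def save_expression(dir_path, expr: ExpressionMatrix, fmt: str = "mtx_triplet"):
    """Write an expression matrix + coordinates; returns the matrix path."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    coords_df = pd.DataFrame(
        {"cell_id": expr.cell_ids, "x": expr.coords[:, 0], "y": expr.coords[:, 1]}
    )
    coords_path = dir_path / "coords.tsv"
    coords_df.to_csv(coords_path, sep="\t", index=False)
    if fmt == "csv":
        mat_path = dir_path / "expr.csv"
        pd.DataFrame(
            expr.counts, index=expr.cell_ids, columns=expr.gene_ids
        ).to_csv(mat_path)
    elif fmt == "mtx_triplet":
        mat_path = dir_path / "expr.mtx"
        sio.mmwrite(str(mat_path), sp.coo_matrix(expr.counts))
        mat_path.with_name("expr.mtx.rows").write_text(
            "\n".join(expr.cell_ids) + "\n"
        )
        mat_path.with_name("expr.mtx.cols").write_text(
            "\n".join(expr.gene_ids) + "\n"
        )
    else:
        raise ValueError(f"unsupported save format {fmt!r}")
    return mat_path, coords_path


def load_gene_sets(path) -> PathwayCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Genes are de-duplicated within a set, order preserved. Sets that are
    empty after de-duplication are dropped with a warning. A line with
    fewer than three tab-separated fields is a hard error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected name, description and at least one gene"
                )
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate pathway {name!r}")
            genes, seen = [], set()
            for g in fields[2:]:
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            if not genes:
                warnings.warn(f"dropping empty gene set {name!r}")
                continue
            sets[name] = genes
            descriptions[name] = desc
    return PathwayCollection(sets, descriptions)


def save_gene_sets(path, sets: PathwayCollection) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.sets.items():
            desc = sets.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def load_labels(path) -> DomainLabels:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    return DomainLabels(list(df["cell_id"]), df["label"].to_numpy(dtype=int))


def save_labels(path, labels: DomainLabels) -> None:
    pd.DataFrame({"cell_id": labels.cell_ids, "label": labels.labels}).to_csv(
        path, sep="\t", index=False
    )


def load_embedding(path) -> FusedEmbedding:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    H = df.drop(columns="cell_id").to_numpy(dtype=float)
    return FusedEmbedding(H, list(df["cell_id"]))


def save_embedding(path, emb: FusedEmbedding) -> None:
    cols = {f"dim_{j}": emb.H[:, j] for j in range(emb.dim)}
    pd.DataFrame({"cell_id": emb.cell_ids, **cols}).to_csv(
        path, sep="\t", index=False
    )


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_results(
    dir_path,
    embedding: FusedEmbedding,
    labels: DomainLabels,
    graphs: dict[str, CellGraph] | None = None,
    seed: int | None = None,
    config: dict | None = None,
    extra: dict | None = None,
) -> dict:
    """Write the result bundle and return its manifest.

    Embedding and labels go out as TSV; each graph as general
    MatrixMarket (both triangles stored). The manifest JSON records
    shapes, the seed, and a hash of the run configuration.
    """
    check_aligned(embedding, labels)
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)

    save_embedding(dir_path / "embedding.tsv", embedding)
    save_labels(dir_path / "labels.tsv", labels)
    manifest: dict = {
        "n_cells": embedding.n_cells,
        "embedding_dim": embedding.dim,
        "n_domains": labels.n_domains,
        "seed": seed,
        "config_hash": config_hash(config or {}),
        "config": config or {},
        "graphs": {},
    }
    for name, graph in (graphs or {}).items():
        if graph.n_cells != embedding.n_cells:
            raise ValueError(f"graph {name!r} cell count mismatch")
        gpath = dir_path / f"graph_{name}.mtx"
        sio.mmwrite(str(gpath), sp.coo_matrix(graph.adjacency), symmetry="general")
        manifest["graphs"][name] = {
            "path": gpath.name,
            "n_edges": graph.n_edges,
            "kind": graph.kind,
        }
    if extra:
        manifest.update(extra)
    with open(dir_path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def load_graph(path, kind: str = "spatial", weighted: bool = False) -> CellGraph:
    adj = sp.csr_matrix(sio.mmread(path))
    return CellGraph(adj, kind=kind, weighted=weighted)


def save_activity(path, activity: ActivityMatrix) -> None:
    pd.DataFrame(
        activity.scores, index=activity.cell_ids, columns=activity.pathway_names
    ).to_csv(path, sep="\t", index_label="cell_id")


def load_activity(path) -> ActivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col="cell_id")
    return ActivityMatrix(
        df.to_numpy(dtype=float), [str(i) for i in df.index], list(df.columns)
    )
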