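"""Self-contained synthetic SRT datasets with planted spatial domains.

The generator emulates the data regime the method assumes: a 2-D field
of cells partitioned into contiguous domains, each domain activating a
disjoint set of pathway programs, with counts drawn from a negative
binomial (mean/dispersion parameterization shared with the model's
likelihood) and technical dropout applied as an independent Bernoulli
mask — exactly the ZINB mixture the omics decoder fits. A matching GMT
file records the planted pathway memberships, so the entire pipeline
runs with zero downloads.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datatypes import DomainLabels, ExpressionMatrix, PathwayCollection
from . import io as io_formats


@dataclass
class SynthConfig:
    """Parameters of the synthetic SRT generator.

    ``program_effect`` is the natural-log fold activation a domain's
    pathways receive on their member genes; ``nb_dispersion`` is the
    NB theta (smaller = noisier); ``dropout`` is the technical-zero
    probability pi; library sizes are drawn log-uniform in
    ``library_range`` and scale every gene mean of a cell.

    ``ectopic_rate`` is the fraction of cells whose expressed program is
    swapped for a random other domain's program (salt-and-pepper noise:
    the cell still *belongs* to its spatial domain but transcriptionally
    resembles another). This emulates the noisy, dropout-ridden regime
    in which expression-only clustering scatters isolated cells across
    domains and spatial context is required to recover contiguous
    regions.
    """

    n_cells: int = 900
    grid: tuple[int, int] | None = (30, 30)
    n_domains: int = 4
    layout: str = "stripes"
    n_genes: int = 300
    n_pathways: int = 12
    genes_per_pathway: int = 15
    program_effect: float = 1.0
    base_mean: float = 0.3
    nb_dispersion: float = 2.0
    dropout: float = 0.3
    ectopic_rate: float = 0.1
    library_range: tuple[float, float] = (0.75, 1.3333333333333333)
    seed: int = 0

    def __post_init__(self):
        if self.n_domains < 2:
            raise ValueError("need at least two domains")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if not (0 <= self.ectopic_rate < 1):
            raise ValueError("ectopic_rate must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.genes_per_pathway * self.n_pathways > self.n_genes:
            raise ValueError("pathway programs exceed the gene universe")
        if self.layout not in ("stripes", "blobs", "rings"):
            raise ValueError(f"unknown layout {self.layout!r}")


def _place_cells(cfg: SynthConfig, rng) -> np.ndarray:
    if cfg.grid is not None:
        nx, ny = cfg.grid
        if nx * ny != cfg.n_cells:
            raise ValueError("grid shape does not match n_cells")
        xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        return np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
    return rng.uniform(0, np.sqrt(cfg.n_cells), size=(cfg.n_cells, 2))


def _assign_domains(coords: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    y = coords[:, 1]
    if cfg.layout == "stripes":
        # horizontal bands, mimicking cortical layers
        edges = np.quantile(y, np.linspace(0, 1, cfg.n_domains + 1))
        labels = np.clip(
            np.searchsorted(edges[1:-1], y, side="right"), 0, cfg.n_domains - 1
        )
        return labels
    center = coords.mean(axis=0)
    r = np.linalg.norm(coords - center, axis=1)
    if cfg.layout == "rings":
        edges = np.quantile(r, np.linspace(0, 1, cfg.n_domains + 1))
        return np.clip(
            np.searchsorted(edges[1:-1], r, side="right"), 0, cfg.n_domains - 1
        )
    # blobs: nearest of n_domains anchor points spread on a circle
    angles = 2 * np.pi * np.arange(cfg.n_domains) / cfg.n_domains
    span = np.ptp(coords, axis=0) / 2
    anchors = center + np.stack(
        [span[0] * np.cos(angles), span[1] * np.sin(angles)], axis=1
    ) * 0.7
    d = np.linalg.norm(coords[:, None] - anchors[None], axis=2)
    return d.argmin(axis=1)


def generate(cfg: SynthConfig):
    """Draw one synthetic dataset.

    Returns ``(expr, pathways, truth, true_means)`` where ``true_means``
    is the pre-dropout, library-scaled NB mean matrix used for
    denoising comparisons.
    """
    rng = np.random.default_rng(cfg.seed)
    coords = _place_cells(cfg, rng)
    domains = _assign_domains(coords, cfg)

    cell_ids = [f"cell_{i:05d}" for i in range(cfg.n_cells)]
    gene_ids = [f"gene_{g:04d}" for g in range(cfg.n_genes)]

    # disjoint pathway memberships over the first programmed genes
    sets = {}
    for p in range(cfg.n_pathways):
        start = p * cfg.genes_per_pathway
        sets[f"PW_{p:03d}"] = gene_ids[start : start + cfg.genes_per_pathway]
    pathways = PathwayCollection(sets, {k: "synthetic program" for k in sets})

    # each domain activates an (approximately equal) disjoint slice of pathways
    pw_domain = np.arange(cfg.n_pathways) % cfg.n_domains
    gene_domain = -np.ones(cfg.n_genes, dtype=int)
    for p in range(cfg.n_pathways):
        start = p * cfg.genes_per_pathway
        gene_domain[start : start + cfg.genes_per_pathway] = pw_domain[p]

    base = cfg.base_mean * np.exp(rng.normal(0.0, 0.25, size=cfg.n_genes))
    mean = np.tile(base, (cfg.n_cells, 1))
    programmed = gene_domain >= 0
    # transcriptional program per cell: the spatial domain's program,
    # except for ectopic cells that express a random other domain's one
    expressed = domains.copy()
    if cfg.ectopic_rate > 0:
        flip = rng.random(cfg.n_cells) < cfg.ectopic_rate
        shift = rng.integers(1, cfg.n_domains, size=cfg.n_cells)
        expressed = np.where(
            flip, (domains + shift) % cfg.n_domains, domains
        )
    boost = (gene_domain[None, :] == expressed[:, None]) & programmed[None, :]
    mean = np.where(boost, mean * np.exp(cfg.program_effect), mean)

    lib = np.exp(
        rng.uniform(
            np.log(cfg.library_range[0]), np.log(cfg.library_range[1]),
            size=cfg.n_cells,
        )
    )
    mean = mean * lib[:, None]

    theta = cfg.nb_dispersion
    # numpy's negative_binomial(n, p): n = theta, p = theta / (theta + mu)
    counts = rng.negative_binomial(theta, theta / (theta + mean)).astype(float)
    if cfg.dropout > 0:
        keep = rng.random(counts.shape) >= cfg.dropout
        counts = counts * keep

    expr = ExpressionMatrix(counts, cell_ids, gene_ids, coords)
    truth = DomainLabels(cell_ids, domains)
    return expr, pathways, truth, mean


def standard_benchmark(seed: int = 0):
    """The canonical synthetic fixture: 900 cells on a 30 x 30 grid,
    4 stripe domains, 300 genes, 12 pathways x 15 genes,
    program effect 1.0 (natural log), theta 2, dropout 0.3."""
    return generate(SynthConfig(seed=seed))


def write_dataset(out_dir, expr, pathways, truth, true_means) -> dict:
    """Persist a generated dataset as plain-text artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_formats.save_expression(out, expr, fmt="mtx_triplet")
    io_formats.save_gene_sets(out / "pathways.gmt", pathways)
    io_formats.save_labels(out / "truth.tsv", truth)
    import pandas as pd

    pd.DataFrame(true_means, index=expr.cell_ids, columns=expr.gene_ids).to_csv(
        out / "true_means.tsv", sep="\t", index_label="cell_id"
    )
    return {
        "expr": str(out / "expr.mtx"),
        "coords": str(out / "coords.tsv"),
        "gmt": str(out / "pathways.gmt"),
        "truth": str(out / "truth.tsv"),
        "true_means": str(out / "true_means.tsv"),
    }
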