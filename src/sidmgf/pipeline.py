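"""End-to-end orchestration: preprocess -> activity -> graphs -> train
-> embed -> cluster.

The central objects follow the model/results convention of statistical
modelling packages: :class:`SiDMGF` holds the data and configuration,
``fit()`` trains the graph autoencoder and returns
:class:`SiDMGFResults`, which carries the fused embedding, attention
weights and loss curves and exposes clustering, denoising, evaluation
and a text summary. :func:`run` is a thin file-to-file wrapper over the
two objects (it also backs the command-line interface).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import evaluate as ev
from . import io as io_formats
from .activity import compute_activity, preprocess
from .datatypes import (
    ActivityMatrix,
    CellGraph,
    DomainLabels,
    ExpressionMatrix,
    FusedEmbedding,
    PathwayCollection,
)
from .graphs import build_signal_graph, build_spatial_graph
from .network import ABLATIONS, MultigraphAutoencoder
from ._autodiff import Adam

logger = logging.getLogger("sidmgf")


@dataclass
class RunConfig:
    """Flat run configuration mirroring the CLI flags."""

    expr_path: str | None = None
    expr_format: str = "mtx_triplet"
    coords_path: str | None = None
    gmt_path: str | None = None
    out_dir: str | None = None
    truth_path: str | None = None

    n_hvg: int = 3000
    min_counts: int | None = None
    min_genes: int | None = None
    radius: float | None = None
    knn: int = 15
    signed_weights: bool = False
    lam: float = 1.0
    hidden_dims: tuple[int, int] = (128, 64)
    latent_dim: int = 64
    epochs: int = 150
    learning_rate: float = 1e-3
    input_noise: float = 1.0
    theta_per_gene: bool = True
    signal_input: str = "expression"  # or "activity"
    ablation: str = "full"
    target_domains: int | None = None
    resolution: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {self.ablation!r}")
        if self.signal_input not in ("expression", "activity"):
            raise ValueError("signal_input must be expression or activity")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _spawn_seeds(master: int, n: int = 4) -> list[int]:
    """Derive independent sub-seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


class SiDMGF:
    """Spatial-domain model over one SRT slice.

    Built from a raw :class:`ExpressionMatrix` and a
    :class:`PathwayCollection`; construction runs preprocessing,
    pathway-activity scoring and graph building so the intermediate
    artifacts (``activity``, ``spatial_graph``, ``signal_graph``) are
    inspectable before training. ``fit()`` trains the multigraph
    autoencoder and returns a :class:`SiDMGFResults`.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        pathways: PathwayCollection,
        config: RunConfig | None = None,
        **overrides,
    ):
        cfg = config or RunConfig()
        if overrides:
            cfg = dataclasses.replace(cfg, **overrides)
        self.config = cfg
        self.raw_expr = expr
        logger.info("preprocessing %d cells x %d genes", expr.n_cells, expr.n_genes)
        self.expr = preprocess(
            expr,
            n_hvg=cfg.n_hvg,
            min_counts=cfg.min_counts,
            min_genes=cfg.min_genes,
        )
        self.activity: ActivityMatrix = compute_activity(self.expr, pathways)
        self.pathways = pathways
        logger.info(
            "activity matrix %d x %d", *self.activity.scores.shape
        )
        self.spatial_graph: CellGraph = build_spatial_graph(
            self.expr.coords, r=cfg.radius
        )
        self.signal_graph: CellGraph = build_signal_graph(
            self.activity, K=min(cfg.knn, self.expr.n_cells - 1),
            nonneg=not cfg.signed_weights,
        )
        logger.info(
            "graphs: spatial %d edges, signal %d edges",
            self.spatial_graph.n_edges,
            self.signal_graph.n_edges,
        )

    @classmethod
    def from_files(cls, config: RunConfig) -> "SiDMGF":
        expr = io_formats.load_expression(
            config.expr_path, config.expr_format, coords_path=config.coords_path
        )
        pathways = io_formats.load_gene_sets(config.gmt_path)
        return cls(expr, pathways, config=config)

    def fit(
        self,
        epochs: int | None = None,
        learning_rate: float | None = None,
        seed: int | None = None,
        callback=None,
    ) -> "SiDMGFResults":
        cfg = self.config
        epochs = cfg.epochs if epochs is None else epochs
        lr = cfg.learning_rate if learning_rate is None else learning_rate
        master = cfg.seed if seed is None else seed
        init_seed, cluster_seed, noise_seed, _ = _spawn_seeds(master)

        signal_in = (
            self.activity.scores
            if cfg.signal_input == "activity"
            else None
        )
        net = MultigraphAutoencoder(
            n_genes=self.expr.n_genes,
            hidden_dims=cfg.hidden_dims,
            latent_dim=cfg.latent_dim,
            theta_per_gene=cfg.theta_per_gene,
            ablation=cfg.ablation,
            lam=cfg.lam,
            seed=init_seed,
            signal_in_dim=(
                self.activity.scores.shape[1]
                if cfg.signal_input == "activity"
                else None
            ),
        )
        opt = Adam(net.params, lr=lr)
        X = np.asarray(self.expr.counts, dtype=float)
        raw = np.asarray(self.expr.raw_counts, dtype=float)
        sf = np.asarray(self.expr.size_factors, dtype=float)

        history: list[dict] = []
        t0 = time.time()
        # denoising-autoencoder corruption: the encoder sees a noised
        # input each step while the likelihood targets stay the clean
        # raw counts, so cell-specific sampling noise cannot be
        # memorized into the embedding
        noise_rng = np.random.default_rng(noise_seed)
        for epoch in range(epochs):
            opt.zero_grad()
            Xc = (
                X + noise_rng.normal(0.0, cfg.input_noise, X.shape)
                if cfg.input_noise > 0
                else X
            )
            Xc_sig = signal_in
            if signal_in is not None and cfg.input_noise > 0:
                Xc_sig = signal_in + noise_rng.normal(
                    0.0, cfg.input_noise * np.std(signal_in), signal_in.shape
                )
            loss, parts, H, alpha = net.loss(
                Xc, raw, self.spatial_graph, self.signal_graph, sf,
                X_signal=Xc_sig,
            )
            loss.backward()
            opt.step()
            history.append(parts)
            if callback is not None:
                callback(epoch, parts)
            if epoch % 50 == 0 or epoch == epochs - 1:
                logger.info(
                    "epoch %d: total %.4f (zinb %.4f, spatial %.4f)",
                    epoch, parts["total"], parts.get("zinb", 0.0),
                    parts.get("spatial", 0.0),
                )
        # a final forward pass with the updated parameters
        H, alpha, _ = net.forward(
            X, self.spatial_graph, self.signal_graph, X_signal=signal_in
        )
        if not np.all(np.isfinite(H.data)):
            raise RuntimeError("non-finite embedding after training")
        embedding = FusedEmbedding(
            H.data.copy(), list(self.expr.cell_ids), attention=alpha
        )
        logger.info("trained %d epochs in %.1fs", epochs, time.time() - t0)
        return SiDMGFResults(
            model=self,
            network=net,
            embedding=embedding,
            loss_history=history,
            seed=master,
            cluster_seed=cluster_seed,
            signal_input=signal_in,
        )


class SiDMGFResults:
    """Fitted state: fused embedding, attention, losses, diagnostics."""

    def __init__(self, model, network, embedding, loss_history, seed,
                 cluster_seed, signal_input=None):
        self.model = model
        self.network = network
        self.embedding = embedding
        self.loss_history = loss_history
        self.seed = seed
        self.cluster_seed = cluster_seed
        self._signal_input = signal_input
        self.labels_: DomainLabels | None = None

    @property
    def attention(self) -> np.ndarray | None:
        return self.embedding.attention

    def cluster(
        self,
        n_domains: int | None = None,
        resolution: float | None = None,
        seed: int | None = None,
    ) -> DomainLabels:
        if n_domains is None and resolution is None:
            resolution = 1.0
        labels = ev.leiden_cluster(
            self.embedding,
            n_domains=n_domains,
            resolution=resolution,
            seed=self.cluster_seed if seed is None else seed,
        )
        self.labels_ = labels
        return labels

    def denoise(self) -> np.ndarray:
        """ZINB mean matrix as denoised expression (cells x HVGs)."""
        m = self.model
        return self.network.denoised_mean(
            np.asarray(m.expr.counts, float),
            m.spatial_graph,
            m.signal_graph,
            np.asarray(m.expr.size_factors, float),
            X_signal=self._signal_input,
        )

    def evaluate(self, truth: DomainLabels | None = None) -> dict:
        """External metrics vs truth (if given) plus internal indices."""
        if self.labels_ is None:
            raise ValueError("call cluster() before evaluate()")
        out: dict = {"n_domains": self.labels_.n_domains}
        if truth is not None:
            out["ari"] = ev.ari(truth, self.labels_)
            out["nmi"] = ev.nmi(truth, self.labels_)
            out["pairwise_f1"] = ev.pairwise_f1(truth, self.labels_)
        if self.labels_.n_domains >= 2:
            sc, db = ev.silhouette_db(self.embedding, self.labels_)
            out["silhouette"] = sc
            out["davies_bouldin"] = db
        return out

    def umap(self, seed: int | None = None) -> np.ndarray:
        return ev.umap_project(
            self.embedding, seed=self.cluster_seed if seed is None else seed
        )

    def summary(self, truth: DomainLabels | None = None) -> str:
        cfg = self.model.config
        last = self.loss_history[-1] if self.loss_history else {}
        lines = [
            "SiDMGF spatial-domain model",
            "=" * 44,
            f"cells: {self.embedding.n_cells}   latent dim: {self.embedding.dim}",
            f"ablation: {cfg.ablation}   lambda: {cfg.lam}",
            f"epochs: {len(self.loss_history)}   seed: {self.seed}",
            f"final loss: total {last.get('total', float('nan')):.4f}"
            f" (zinb {last.get('zinb', float('nan')):.4f},"
            f" spatial {last.get('spatial', float('nan')):.4f})",
        ]
        if self.attention is not None:
            mean_alpha = self.attention.mean(axis=0)
            lines.append(
                f"mean attention: spatial {mean_alpha[0]:.3f}, "
                f"signal {mean_alpha[1]:.3f}"
            )
        if self.labels_ is not None:
            lines.append(f"domains found: {self.labels_.n_domains}")
            metrics = self.evaluate(truth)
            for k, v in metrics.items():
                if isinstance(v, float):
                    lines.append(f"  {k}: {v:.4f}")
        return "\n".join(lines)


def denoise(results: SiDMGFResults, expr=None) -> np.ndarray:
    """Module-level denoising entry point (trained results required)."""
    if not isinstance(results, SiDMGFResults):
        raise ValueError("denoise requires a fitted SiDMGFResults object")
    return results.denoise()


def run(config: RunConfig):
    """File-to-file pipeline: load, fit, cluster, evaluate, save.

    Returns ``(embedding, labels, report)``; when ``config.out_dir`` is
    set, writes the result bundle (embedding/labels TSV, both graphs as
    MatrixMarket, manifest JSON with seed + config hash, metrics JSON).
    """
    model = SiDMGF.from_files(config)
    results = model.fit()
    labels = results.cluster(
        n_domains=config.target_domains, resolution=config.resolution
    )
    truth = None
    if config.truth_path:
        truth = io_formats.load_labels(config.truth_path)
        order = {c: i for i, c in enumerate(truth.cell_ids)}
        idx = [order[c] for c in labels.cell_ids]
        truth = DomainLabels(
            [truth.cell_ids[i] for i in idx], truth.labels[idx]
        )
    report = results.evaluate(truth)
    report["loss_final"] = results.loss_history[-1]
    if config.out_dir:
        io_formats.save_results(
            config.out_dir,
            results.embedding,
            labels,
            graphs={
                "spatial": model.spatial_graph,
                "signal": model.signal_graph,
            },
            seed=config.seed,
            config=config.to_dict(),
            extra={
                "loss_history": results.loss_history,
                "library_versions": _library_versions(),
            },
        )
        with open(Path(config.out_dir) / "metrics.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return results.embedding, labels, report


def _library_versions() -> dict:
    import scipy
    import sklearn

    import sidmgf

    return {
        "sidmgf": sidmgf.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }
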