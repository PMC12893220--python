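"""The multigraph-fusion graph autoencoder and its loss terms.

Two GCN encoders (spatial branch, signal branch) share the scaled
expression matrix as input and propagate it through their respective
normalized adjacencies. A per-cell attention head softmax-weights the
two branch embeddings, an MLP projects the fusion to the latent space,
and two decoders pull the latent code back toward the data: an
inner-product graph decoder reconstructs the spatial adjacency under a
binary cross-entropy, and a ZINB omics decoder reconstructs the raw
counts of the retained genes under a zero-inflated negative binomial
likelihood. The total objective is L = L_ZINB + lambda * L_spatial.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .datatypes import CellGraph

ABLATIONS = (
    "full",
    "no_signal",
    "no_spatial",
    "no_graph_decoder",
    "no_omics_decoder",
    "no_attention",
)


@dataclass
class ZinbParams:
    """Per-entry ZINB parameters: dropout pi, mean mu, dispersion theta.

    ``theta`` may be a single row (per-gene dispersion) broadcast over
    cells.
    """

    pi: np.ndarray
    mu: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if np.any(self.pi <= 0) or np.any(self.pi >= 1):
            raise ValueError("pi must lie strictly in (0, 1)")
        if np.any(self.mu <= 0):
            raise ValueError("mu must be positive")
        if np.any(self.theta <= 0):
            raise ValueError("theta must be positive")


def gcn_forward(H_in, graph: CellGraph, W, bias=None, activation: str = "relu"):
    """One graph-convolution layer: act(P @ H_in @ W + b).

    ``P`` is the graph's symmetric-normalized propagation matrix.
    Accepts numpy arrays or autodiff tensors; returns a Tensor.
    """
    if graph.norm_propagation is None:
        raise ValueError("graph has no norm_propagation; normalize it first")
    act = ad.ACTIVATIONS[activation]
    H_in = ad.as_tensor(H_in)
    W = ad.as_tensor(W)
    out = ad.matmul(ad.spmm(graph.norm_propagation, H_in), W)
    if bias is not None:
        out = ad.add(out, ad.as_tensor(bias))
    return act(out)


def attention_logit(H, W1, b, W2):
    """Per-cell scalar attention logit: W2 . tanh(W1 h_i + b)."""
    return ad.matmul(ad.tanh(ad.add(ad.matmul(ad.as_tensor(H), W1), b)), W2)


def attention_fuse(H_s, H_a, head: dict, mlp=None):
    """Softmax-weighted fusion of the two branch embeddings.

    ``head`` maps branch -> (W1, b, W2). Returns (H_fused, alpha) where
    ``alpha`` is the n x 2 array of (spatial, signal) attention weights,
    each row summing to one.
    """
    logit_s = attention_logit(H_s, *head["spatial"])
    logit_a = attention_logit(H_a, *head["signal"])
    alpha_s = ad.sigmoid(ad.add(logit_s, ad.mul(logit_a, -1.0)))  # n x 1
    one_minus = ad.add(ad.mul(alpha_s, -1.0), 1.0)
    fused = ad.add(ad.mul(alpha_s, ad.as_tensor(H_s)),
                   ad.mul(one_minus, ad.as_tensor(H_a)))
    alpha = np.hstack([alpha_s.data, one_minus.data])
    if mlp is not None:
        fused = mlp(fused)
    return fused, alpha


def spatial_reconstruction_loss(H, graph: CellGraph, balanced: bool = False):
    """Mean BCE between G_s and the sigmoid of the inner-product decoder.

    The reconstructed graph is G_hat = H H^T; each of the n^2 cell pairs
    contributes softplus(z) - z * G_s(i, j) (binary cross-entropy with
    logits). With ``balanced`` (the training default) edge pairs are
    re-weighted by the non-edge/edge ratio so the sparse positive class
    is not drowned out. Returns a scalar Tensor (>= 0); use ``.item()``
    for the float value.
    """
    H = ad.as_tensor(H)
    A = getattr(graph, "_dense_cache", None)
    if A is None:
        A = np.asarray(graph.adjacency.todense(), dtype=float)
        np.fill_diagonal(A, 0.0)
        A = (A != 0).astype(float)  # BCE targets are edge indicators
        graph._dense_cache = A
    pos_weight = None
    if balanced:
        n_pos = max(A.sum(), 1.0)
        pos_weight = (A.size - n_pos) / n_pos
    Z = ad.matmul(H, ad.transpose(H))
    return ad.bce_logits_mean(Z, A, pos_weight=pos_weight)


def _zinb_log_pmf(x: np.ndarray, pi_logit, log_mu, log_theta):
    """Elementwise ZINB log-pmf on tensors, numerically stable.

    log NB(x | mu, theta) = lgamma(x + theta) - lgamma(theta)
        - lgamma(x + 1) + theta * (log theta - log(theta + mu))
        + x * (log mu - log(theta + mu))

    and the zero-inflated mixture puts point mass pi at x = 0:
    pmf = pi * 1[x = 0] + (1 - pi) * NB(x).
    """
    return ad.zinb_log_pmf(np.asarray(x, dtype=float), pi_logit, log_mu, log_theta)


def zinb_nll(x, params: ZinbParams, reduction: str = "sum") -> float:
    """Negative log-likelihood of counts under the ZINB mixture.

    ``reduction`` is ``sum`` (the likelihood of the whole matrix) or
    ``mean`` (per entry, the scale used inside the training objective).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or not np.allclose(x, np.round(x)):
        raise ValueError("ZINB likelihood requires non-negative integer counts")
    lp = _zinb_log_pmf(
        x,
        Tensor(np.log(params.pi) - np.log1p(-params.pi)),
        Tensor(np.log(params.mu)),
        Tensor(np.log(np.broadcast_to(params.theta, x.shape))),
    )
    if reduction == "sum":
        return float(-lp.data.sum())
    if reduction == "mean":
        return float(-lp.data.mean())
    raise ValueError(f"unknown reduction {reduction!r}")


def total_loss(l_zinb: float, l_spatial: float, lam: float) -> float:
    """L = L_ZINB + lambda * L_spatial."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    return l_zinb + lam * l_spatial


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class MultigraphAutoencoder:
    """Dual-GCN multigraph fusion network with ZINB + graph decoders.

    Parameters
    ----------
    n_genes
        Width of the expression input (and of the ZINB output).
    hidden_dims
        GCN layer widths per branch.
    latent_dim
        Width of the fused embedding H.
    attention_dim
        Hidden width of the per-branch attention head.
    decoder_hidden
        Width of the shared ZINB decoder trunk.
    theta_per_gene
        Per-gene (row-broadcast) dispersion when True, scalar otherwise.
    ablation
        One of :data:`ABLATIONS`; single-branch ablations disable the
        attention head (undefined with one branch), ``no_attention``
        fixes alpha = (0.5, 0.5).
    """

    def __init__(
        self,
        n_genes: int,
        hidden_dims=(128, 64),
        latent_dim: int = 64,
        attention_dim: int = 32,
        decoder_hidden: int = 128,
        theta_per_gene: bool = True,
        activation: str = "relu",
        ablation: str = "full",
        lam: float = 1.0,
        seed: int = 0,
        signal_in_dim: int | None = None,
    ):
        if ablation not in ABLATIONS:
            raise ValueError(f"unknown ablation {ablation!r}")
        self.n_genes = n_genes
        self.hidden_dims = tuple(hidden_dims)
        self.latent_dim = latent_dim
        self.activation = activation
        self.ablation = ablation
        self.lam = 0.0 if ablation == "no_graph_decoder" else lam
        rng = np.random.default_rng(seed)

        def param(*shape, glorot=None):
            if glorot is not None:
                t = Tensor(_glorot(rng, *glorot), requires_grad=True)
            else:
                t = Tensor(np.zeros(shape), requires_grad=True)
            return t

        self.params: list[Tensor] = []

        def track(t):
            self.params.append(t)
            return t

        in_dims = {
            "spatial": n_genes,
            "signal": signal_in_dim if signal_in_dim is not None else n_genes,
        }
        self.gcn = {}
        for branch in ("spatial", "signal"):
            if ablation == "no_signal" and branch == "signal":
                continue
            if ablation == "no_spatial" and branch == "spatial":
                continue
            dims = [in_dims[branch], *self.hidden_dims]
            layers = []
            for fi, fo in zip(dims[:-1], dims[1:]):
                layers.append(
                    (track(param(glorot=(fi, fo))), track(param(fo)))
                )
            self.gcn[branch] = layers

        d = self.hidden_dims[-1]
        self.two_branch = len(self.gcn) == 2
        self.head = None
        if self.two_branch and ablation != "no_attention":
            self.head = {
                b: (
                    track(param(glorot=(d, attention_dim))),
                    track(param(attention_dim)),
                    track(param(glorot=(attention_dim, 1))),
                )
                for b in ("spatial", "signal")
            }
        self.W_mlp = track(param(glorot=(d, latent_dim)))
        self.b_mlp = track(param(latent_dim))

        self.W_dec = track(param(glorot=(latent_dim, decoder_hidden)))
        self.b_dec = track(param(decoder_hidden))
        self.W_pi = track(param(glorot=(decoder_hidden, n_genes)))
        self.b_pi = track(param(n_genes))
        self.W_mu = track(param(glorot=(decoder_hidden, n_genes)))
        self.b_mu = track(param(n_genes))
        theta_shape = n_genes if theta_per_gene else 1
        self.theta_raw = track(param(theta_shape))
        self.theta_raw.data[:] = 1.0  # softplus(1) ~ 1.31, a mild start

    # -- forward pieces ------------------------------------------------
    def _branch(self, X, graph: CellGraph, branch: str):
        H = X
        for li, (W, b) in enumerate(self.gcn[branch]):
            last = li == len(self.gcn[branch]) - 1
            act = "identity" if last else self.activation
            H = gcn_forward(H, graph, W, bias=b, activation=act)
        return H

    def _mlp(self, fused):
        # linear projection: a non-negative output range would force the
        # inner-product decoder toward sigmoid >= 0.5 on every pair and
        # collapse the embedding
        return ad.add(ad.matmul(fused, self.W_mlp), self.b_mlp)

    def forward(
        self,
        X,
        spatial_graph: CellGraph,
        signal_graph: CellGraph | None,
        X_signal=None,
    ):
        """Encode: returns (H_fused Tensor, alpha array or None, branches).

        ``X_signal`` optionally feeds a different input (e.g. the
        activity matrix) to the signal branch; default is ``X`` on both.
        """
        branches = {}
        if "spatial" in self.gcn:
            branches["spatial"] = self._branch(X, spatial_graph, "spatial")
        if "signal" in self.gcn:
            if signal_graph is None:
                raise ValueError("signal graph required for the signal branch")
            branches["signal"] = self._branch(
                X if X_signal is None else X_signal, signal_graph, "signal"
            )

        alpha = None
        if not self.two_branch:
            fused = next(iter(branches.values()))
        elif self.ablation == "no_attention":
            fused = ad.mul(
                ad.add(branches["spatial"], branches["signal"]), 0.5
            )
            n = X.shape[0]
            alpha = np.full((n, 2), 0.5)
        else:
            fused, alpha = attention_fuse(
                branches["spatial"], branches["signal"], self.head
            )
        H = self._mlp(fused)
        return H, alpha, branches

    def decode_zinb(self, H, log_size_factors: np.ndarray):
        """ZINB heads from the latent code; returns tensor params.

        ``mu`` is exp(linear) scaled by the per-cell library size factor;
        ``theta`` is a softplus-transformed free parameter per gene.
        """
        trunk = ad.relu(ad.add(ad.matmul(H, self.W_dec), self.b_dec))
        pi_logit = ad.add(ad.matmul(trunk, self.W_pi), self.b_pi)
        log_mu = ad.add(
            ad.add(ad.matmul(trunk, self.W_mu), self.b_mu),
            log_size_factors[:, None],
        )
        log_theta = ad.log(
            ad.add(ad.softplus(self.theta_raw), 1e-4)
        )
        return pi_logit, log_mu, log_theta

    def loss(
        self,
        X: np.ndarray,
        raw_counts: np.ndarray,
        spatial_graph: CellGraph,
        signal_graph: CellGraph | None,
        size_factors: np.ndarray,
        X_signal=None,
    ):
        """Total training objective on the current parameters.

        Per-entry mean scale is used for both terms so the lambda
        trade-off is size-independent. Returns (loss Tensor, parts dict,
        H Tensor, alpha).
        """
        H, alpha, _ = self.forward(X, spatial_graph, signal_graph, X_signal)
        parts = {}
        terms = []
        if self.ablation != "no_omics_decoder":
            pi_logit, log_mu, log_theta = self.decode_zinb(
                H, np.log(size_factors)
            )
            lp = _zinb_log_pmf(raw_counts, pi_logit, log_mu, log_theta)
            l_zinb = ad.mul(ad.tmean(lp), -1.0)
            parts["zinb"] = float(l_zinb.data)
            terms.append(l_zinb)
        if self.lam > 0 or self.ablation == "no_omics_decoder":
            l_sp = spatial_reconstruction_loss(H, spatial_graph, balanced=True)
            parts["spatial"] = float(l_sp.data)
            lam = 1.0 if self.ablation == "no_omics_decoder" else self.lam
            terms.append(ad.mul(l_sp, lam))
        else:
            parts["spatial"] = 0.0
        total = terms[0]
        for t in terms[1:]:
            total = ad.add(total, t)
        parts["total"] = float(total.data)
        return total, parts, H, alpha

    def denoised_mean(self, X, spatial_graph, signal_graph, size_factors,
                      X_signal=None):
        """The ZINB mean mu as the denoised expression matrix."""
        H, _, _ = self.forward(X, spatial_graph, signal_graph, X_signal)
        _, log_mu, _ = self.decode_zinb(H, np.log(size_factors))
        return np.exp(log_mu.data)
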