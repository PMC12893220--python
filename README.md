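# sidmgf

Spatial domain identification for spatially resolved transcriptomics
(SRT) by **multigraph fusion**: a spatial-proximity graph and a
pathway-activity ("signal") graph are encoded by two graph
convolutional networks, fused per cell by attention, and trained
against a zero-inflated negative binomial (ZINB) reconstruction of the
raw counts plus a reconstruction of the spatial graph. Leiden
clustering of the fused embedding yields spatial domains — contiguous
tissue regions of spatially adjacent cells with similar expression.

The package is aimed at computational biologists analysing
Visium / STARmap / osmFISH / Stereo-seq-style slices who want domain
calls that use three complementary sources of information at once:
gene expression, physical location, and pathway-level biological
context.

## The model

Given raw counts $X \in \mathbb{N}^{n \times g}$ with coordinates
$S \in \mathbb{R}^{n \times 2}$ and gene sets (GMT; e.g. KEGG):

1. **Activity.** A GSVA-style per-cell enrichment score with a Poisson
   kernel CDF turns expression into an activity matrix
   $AS \in [-1, 1]^{n \times k}$ over $k$ pathways.
2. **Graphs.** The spatial graph $G_s$ links cells with
   $\lVert S_i - S_j \rVert < r$ (unweighted; $r$ defaults to 1.2x the
   median nearest-neighbour distance). The signal graph $G_a$ is a
   union-symmetrised KNN backbone in activity space, each edge weighted
   by $\cos(AS_{i\cdot}, AS_{j\cdot})$.
3. **Encoders + fusion.** Each graph drives a two-layer GCN,
   $H^{(l+1)} = \sigma(\tilde D^{-1/2} (G + I) \tilde D^{-1/2} H^{(l)} W^{(l)})$,
   over the scaled expression. Per-cell attention
   $\alpha_i = \mathrm{softmax}(W_2 \tanh(W_1 h_i + b))$ weights the two
   branch embeddings and a linear projection gives the fused $H$.
4. **Decoders.** An inner-product decoder reconstructs $G_s$ through a
   binary cross-entropy $\mathcal{L}_{spatial}$ on
   $\phi(H H^\top)$; a ZINB decoder with heads $(\pi, \mu, \theta)$
   reconstructs the raw counts through
   $\mathcal{L}_{ZINB} = -\sum \ln \mathrm{ZINB}(x \mid \pi, \mu, \theta)$.
   The objective is
   $\mathcal{L} = \mathcal{L}_{ZINB} + \lambda\, \mathcal{L}_{spatial}$.
5. **Domains.** Leiden on a KNN graph of $H$, with a resolution
   bisection when a target number of domains is requested. Metrics:
   ARI / NMI / pairwise F1 against annotations, silhouette and
   Davies–Bouldin without them, a Wilcoxon rank-sum marker table and a
   domain-level pathway-activity summary for interpretation.

The network is trained with a compact reverse-mode autodiff core over
numpy (`sidmgf._autodiff`) — no deep-learning framework is required —
with denoising-style input corruption so the embedding cannot memorise
per-cell sampling noise (see `docs/methods.md`).

## Worked example

The built-in generator plants four stripe domains (think cortical
layers) on a 30 x 30 grid with domain-specific pathway programs, shallow
ZINB counts and heavy dropout:

```python
from sidmgf import SiDMGF, standard_benchmark

expr, pathways, truth, _ = standard_benchmark(seed=1)
model = SiDMGF(expr, pathways)         # preprocess, activity, graphs
results = model.fit(seed=1)            # train the autoencoder
labels = results.cluster(n_domains=4)  # Leiden with resolution search
print(results.summary(truth))
```

```
SiDMGF spatial-domain model
============================================
cells: 900   latent dim: 64
ablation: full   lambda: 1.0
epochs: 150   seed: 1
final loss: total 1.0311 (zinb 0.6109, spatial 0.4202)
mean attention: spatial 0.667, signal 0.333
domains found: 4
  ari: 0.9418
  nmi: 0.9221
  pairwise_f1: 0.9563
  silhouette: 0.1104
  davies_bouldin: 2.5614
```

ARI 0.94 means the four planted stripes are recovered almost exactly;
the attention column shows the model leaning on the spatial branch
(0.67 vs 0.33), which is what planted contiguous domains reward.
`results.denoise()` returns the ZINB mean $\mu$ as a denoised
expression matrix for marker visualisation.

The same pipeline runs from the shell:

```bash
sidmgf synth --out data/ --seed 3            # write a synthetic slice
sidmgf run --expr data/expr.mtx --coords data/coords.tsv \
           --gmt data/pathways.gmt --truth data/truth.tsv \
           --out out/ --n-domains 4 --seed 1
sidmgf eval --pred out/labels.tsv --truth data/truth.tsv
```

Real slices load from dense CSV, MatrixMarket triplet
(`.mtx` + `.mtx.rows`/`.mtx.cols` sidecars + a `cell_id/x/y` TSV) or an
AnnData `.h5ad` with `obsm["spatial"]`.

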