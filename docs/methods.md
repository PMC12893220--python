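# Methods

This note documents the modelling choices behind `sidmgf`: the
procedure, its assumptions, the parameters that matter, what the
synthetic generator does and does not emulate, and the numerical
decisions taken where the design was genuinely open.

## Pipeline overview

Input is a cells x genes raw count matrix with 2-D coordinates in
platform units, plus gene sets in GMT. The stages are:

1. preprocessing (scanpy): optional per-cell quality filters
   (`min_counts`, `min_genes`; off by default so filtering is always an
   explicit user decision), library-size normalisation to
   `target_sum = 1e4`, log1p, selection of `n_hvg = 3000` highly
   variable genes by the binned-dispersion criterion, unit-variance
   scaling. Raw counts of the retained genes and per-cell size factors
   (library / median library) are kept for the count likelihood.
   With fewer than 100 genes the dispersion normalisation falls back to
   a single bin (ranking raw dispersions): mean-binning needs a dense
   mean axis and degenerates on tiny universes.
2. pathway activity: a per-sample rank-based enrichment score of the
   GSVA family, computed on the **raw counts** of the retained genes
   (the Poisson kernel presumes counts). Per gene, the kernel CDF
   statistic is `z_gj = (1/n) sum_m F_Pois(x_gj; x_gm + 0.5)`; per
   cell, genes are ranked by decreasing `z` (ties broken by gene order,
   so results are deterministic), the symmetric rank statistic
   `s = |G/2 - rank|` is accumulated down the ranked list
   (`s^tau / total` inside the set, `-1/(G - |set|)` outside,
   `tau = 1`), and the score is the sum of the maximum positive and
   minimum negative deviations ("max_diff"). Scores are bounded in
   [-1, 1] by construction. By default the activity is computed on the
   retained highly variable genes; pass the full matrix to
   `compute_activity` to use every gene.
3. graphs: spatial radius graph (strict `< r`, unweighted; default
   `r = 1.2 x` median nearest-neighbour distance, giving ~4 neighbours
   on square grids and ~6 on hexagonal ones) and the signal graph
   (`K = 15` nearest neighbours in activity space under the Euclidean
   metric, union-symmetrised, cosine-weighted). Both are normalised as
   `D^{-1/2}(A + I)D^{-1/2}`; negative cosine weights are clipped to
   zero before normalisation by default, because signed weights can
   produce non-positive degrees (a flag keeps signed weights and errors
   in that case).
4. encoding: two 2-layer GCNs (300 -> 128 -> 64 by default, ReLU
   between layers, linear final layer) share the scaled expression as
   input; per-cell attention (`tanh` head, hidden width 32, softmax
   over the two branch logits) mixes the branches; a **linear**
   projection gives the 64-dimensional fused embedding.
5. decoding and training: inner-product graph decoder with
   class-balanced binary cross-entropy against the spatial adjacency,
   and a ZINB decoder (shared ReLU trunk of width 128; `pi` via
   sigmoid, `mu = exp(linear) x` size factor, `theta` a free per-gene
   softplus parameter) against the raw counts. Objective
   `L = L_ZINB + lambda * L_spatial` with both terms on a per-entry
   mean scale and `lambda = 1`.
6. clustering: Leiden (igraph + leidenalg, RB-configuration) on a
   15-NN graph of the embedding; when a domain count is requested the
   resolution is bisected over [0.01, 3.0] (max 40 iterations, nearest
   count returned with a warning on failure).

## Numerical and design decisions

**Autodiff core.** The network is trained through a small reverse-mode
engine over numpy (`_autodiff.py`) providing exactly the primitives the
model needs, including fused nodes for the ZINB log-pmf (gradients via
digamma) and the BCE-with-logits. Every gradient is verified against
central finite differences in the test suite.

**ZINB zero mass.** The mixture is
`pmf = pi * 1[x = 0] + (1 - pi) * NB(x | mu, theta)`; without the point
mass the density does not normalise. Likelihoods are evaluated in log
space with `logaddexp` at the zeros, so extreme `pi` or `mu` do not
underflow.

**Linear fusion output.** The final projection to the embedding is
linear, not ReLU. A non-negative embedding forces
`sigmoid(H H^T) >= 0.5` on every cell pair, so the overwhelmingly
negative pair targets of the graph decoder shrink the embedding toward
zero — a collapse mode we observed directly. A linear output lets
non-adjacent pairs take negative inner products without destroying the
representation.

**Balanced graph BCE.** Spatial graphs are ~0.4% edges. Inside the
training objective the BCE is class-balanced
(`0.5 * (mean over edges + mean over non-edges)`), the standard graph
autoencoder weighting; otherwise the edge term vanishes into the
negative class. The public `spatial_reconstruction_loss` defaults to
the plain unweighted mean (its documented contract; the `balanced` flag
switches). The full `n^2` pair set is used for the problem sizes here;
negative-pair subsampling would only be needed beyond ~5000 cells.

**Denoising input corruption.** Each training step adds seeded
Gaussian noise (`sigma = 1.0`, the scale of the standardised input) to
the encoder input while the likelihood targets remain the clean raw
counts. Without this, the encoder can use its own cell's contribution
to the propagated features to memorise per-cell sampling noise, and
domain coherence of the embedding degrades as training proceeds; with
it the embedding is stable over a wide range of epoch counts. This is
the classical denoising-autoencoder mechanism used by count
autoencoders for expression data.

**Optimisation.** Adam, learning rate 1e-3, full batch, 150 epochs, no
early stopping (fixed epochs keep runs deterministic). The loss
reaches its knee well before 150 epochs on the benchmark; the
corruption above makes the exact stopping point uncritical.

**Seeds.** One master seed is split (via `SeedSequence`) into
initialisation, clustering and corruption seeds; all are below 2^31 and
recorded in the run manifest, and a rerun from the manifest reproduces
labels exactly.

**Metric conventions.** ARI is the Hubert–Arabie form computed from
the contingency table (scikit-learn), cross-checked in the tests
against an independent pair-counting enumeration. NMI uses the
geometric-mean normalisation (arithmetic available). The clustering F1
is defined over co-clustered cell pairs (precision: predicted pairs
that are true; recall: true pairs recovered); with degenerate margins
(all-singleton or single-cluster partitions on both sides) perfect
agreement scores 1. Wilcoxon markers use the normal approximation with
tie correction and Benjamini–Hochberg adjustment within each domain.

**Degenerate inputs.** Zero-norm activity vectors get cosine 0 with a
warning; isolated graph nodes keep an identity propagation row; a
constant expression matrix yields fully tied ranks, where the
enrichment walk is determined by the tie-break rule alone (scores can
be far from zero for sets concentrated at one end of the gene order —
an inherent property of the rank-walk family, covered by an oracle
test); singleton silhouette values are 0 per the usual convention.

## Ablations

`ablation` switches reproduce component-removal variants at run time:
`no_signal` / `no_spatial` drop a branch (attention is then undefined
and disabled), `no_graph_decoder` forces `lambda = 0`,
`no_omics_decoder` trains on the spatial term alone, and
`no_attention` fixes both weights at 0.5.

## The synthetic generator

`simulate.generate` emulates the regime the method assumes: contiguous
spatial domains with domain-specific pathway programs under heavy
technical noise. Cells sit on a grid (or uniformly at random); domains
are stripes (default; quantile bands mimicking cortical layers), rings
or blobs. Each of the 12 pathways (15 genes each, disjoint) belongs to
one domain; member genes of a cell's expressed program get mean
`mu * exp(program_effect)` with `program_effect = 1.0`. Counts are
NB(mean, theta = 2) — the same parameterisation as the model's
likelihood, so the generator and the loss share one tested pmf — with
independent Bernoulli dropout at `pi = 0.3` applied after sampling, and
log-uniform library sizes in [0.75, 4/3].

Two choices set the difficulty and deserve justification:

- `base_mean = 0.3`: per-gene baseline counts well below one, the
  shallow-count regime of spot-based platforms. Most of the difficulty
  is therefore *unstructured* sampling noise, which expression-only
  clustering cannot average away but spatial smoothing can.
- `ectopic_rate = 0.1`: a tenth of cells express a random *other*
  domain's program while keeping their spatial domain label —
  scattered heterotypic cells that make non-spatial clustering produce
  salt-and-pepper errors.

`standard_benchmark(seed)` is the canonical fixture: 900 cells on a
30 x 30 grid, 4 stripe domains, 300 genes, 12 x 15 pathway genes, and
the parameters above. The generator does **not** emulate histology,
platform artefacts (spot swapping, tissue detachment), batch effects,
within-domain cell-type mixtures beyond the ectopic mechanism, or
hexagonal spot geometry — so passing tests demonstrate correct
mechanics and the intended qualitative behaviour (spatial information
dominates, components contribute in the expected order), not
performance on real tissue.

## Problem sizes used in the checks

The automated checks run the full pipeline on the 900-cell benchmark:
the planted-domain recovery uses 3 seeds, the ablation ordering 5 seeds
x 3 model variants, and the denoising comparison reuses the full-model
runs; one run takes roughly half a minute on a single CPU core.
Formula-level oracles (ZINB likelihood, enrichment walk, ARI/NMI/F1,
silhouette/Davies–Bouldin) run on instances small enough to enumerate
by hand or brute force.

## Known limitations

- Full-batch training with dense `n x n` pair losses bounds practical
  slice sizes to a few thousand cells on one core.
- The Poisson-kernel activity step assumes counts; normalised inputs
  would need a Gaussian kernel, which is out of scope.
- The resolution bisection assumes Leiden's cluster count is monotone
  in resolution, which holds only approximately; the nearest-count
  fallback covers the exceptions.
- Gene matching between expression and GMT is exact-string and
  case-sensitive by design; unmatched genes are reported, never
  fuzzy-matched.
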