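# Methods

## Problem setting

Spatial transcriptomics assigns each capture spot (or segmented cell) an
expression vector and a 2-D coordinate. Spatial domains — cortical layers,
anatomical nuclei — are contiguous regions with coherent expression.
Clustering expression alone fragments domains wherever counts are noisy;
clustering coordinates alone ignores biology. The model here couples the
two through a fused neighbor graph inside a graph convolutional
autoencoder trained with two contrastive objectives.

## Preprocessing

Counts are library-size normalized so every spot totals the median library
size (configurable target sum), `log1p`-transformed, reduced to the top
3000 highly variable genes (Seurat-flavored normalized dispersion via
scanpy; plain variance available), and scaled per gene to zero mean and
unit variance without clipping. Panels with at most the requested number
of genes (STARmap/osmFISH/MERFISH-style) skip selection automatically.
All-zero spots are rejected with their identifiers, since library-size
scaling is undefined for them.

## Graph construction

Spatial and expression kNN graphs (k₁ = k₂ = 3, Euclidean by default) are
built from the directed top-k relation and symmetrized by OR; ties at
equal distance resolve by ascending spot index so graphs are reproducible
for duplicated points. The expression graph is computed on a 50-component
PCA of the processed matrix for robustness (raw-matrix option available).
Fusion is `A = min(A_spatial + α·A_gene, 1)`; α defaults to 0.5, giving
expression edges half the spatial weight so spatial adjacency dominates
and clipping prevents doubly-supported edges from exceeding weight 1.
GCN propagation uses `D^{-1/2}(A + I)D^{-1/2}`; the self-loop guarantees
every degree ≥ 1, so isolated spots propagate only their own signal.

## Model and losses

Encoder and decoder are each one graph convolution. The encoder activation
is ELU (smooth, no dead units in a single-layer network); the decoder is
linear because the reconstruction target is zero-mean scaled expression,
which a bounded or non-negative activation cannot reach. The adjacency
decoder is `sigmoid(Z Zᵀ)` — the n×n inner-product form, the only
dimensionally consistent reading given that the reconstruction loss
compares it against the n×n adjacency. Weights are Glorot-uniform from a
seeded generator.

The corrupted view multiplies X elementwise by Gaussian noise with mean 1
(expectation-preserving) and std 0.1; fresh noise is drawn every epoch
from a generator seeded by the noise spec, keeping runs bit-reproducible.
The space-aware loss is the mean squared difference over all n² entries
between the cross-view cosine similarity matrix and A. The cluster-level
feature loss partitions spots into k near-equal random groups (seeded; an
optional mode re-derives groups from interim Leiden communities every 100
epochs), averages each group's embedding per view, and penalizes the d×d
cross-view feature cosine matrix's deviation from the identity with split
normalization — diagonal term divided by d², off-diagonal by d²−d; a
uniform 1/d² variant is exposed as an option. Totals are weighted
(γ₁, γ₂, γ₃) = (10, 0.5, 0.8) and (α₁, α₂) = (1.0, 0.5).

Gradients of the full objective with respect to W_e and W_d are derived
analytically (including backpropagation through row/column cosine
normalization and the group-mean readout) and checked against central
finite differences to 1e-6 in the tests. Optimization is plain Adam
(β = 0.9/0.999, ε = 1e-8). Pre-training (500 epochs, lr 0.001) minimizes
γ₁·L_rec only: warm-starting reconstruction stabilizes the cosine
similarity matrices before the contrastive terms act. Full training
(1000 epochs, lr 0.005) minimizes the weighted sum. The pairing of the
two printed learning rates with the two phases follows their listing
order.

## Clustering, run selection, refinement

The clean-view embedding is reduced to 20 principal components with a
deterministic sign convention (largest-magnitude loading positive).
When the number of domains k is known, a Gaussian mixture with a single
shared full covariance (the mclust-EEE analogue; diagonal and full-per-
component variants available) assigns labels; otherwise Leiden community
detection runs on a 15-NN graph of the embedding. Training is executed
twice, with corruption std 0.1 and 0.2, and the run with the lower
Davies–Bouldin index on the PCA-20 embedding is kept. Refinement
reassigns each spot to the modal label within radius r of its coordinates
(r = 50, matching Visium pixel spacing; pass the radius in your
platform's units), in a single pass over the pre-refinement labels; ties
and empty neighborhoods keep the original label, and iteration count is
configurable.

## Denoising, gene ranking, imputation checks

Denoising averages each spot's (log-normalized) expression with its 15
nearest neighbors in the latent embedding, self included by default (a
flag excludes it); smoothing therefore follows learned domain structure,
not raw distance. Genes are ranked for interpretability by the standard
deviation of their encoder-weight rows — constant rows carry no
discriminative information and rank last; the ranking is invariant to
latent-dimension permutations, and per-gene mean expression is reported
alongside in the CLI output rather than entering the ranking. The
imputation-space check projects the decoder output to 2-D (seeded UMAP by
default; PCA and identity projectors for deterministic comparisons) and
compares upper-triangular pairwise-distance vectors against the original
expression space via Pearson, MSE, Spearman (mid-rank ties) and cosine
similarity.

## Metrics

ARI, NMI (geometric-mean denominator), homogeneity and Davies–Bouldin are
implemented directly from their contingency-table/centroid definitions and
validated exhaustively against brute-force oracles over all partitions of
six items into at most three blocks, plus spot-checks against
scikit-learn. Conventions for degenerate inputs: NMI of a single-cluster
labeling returns 0 with a warning (the normalizing entropy vanishes); ARI
of two identical trivial partitions returns 1; homogeneity with zero
class entropy returns 1; Davies–Bouldin raises on coincident centroids,
naming the cluster pair. Entropies use natural logarithms (the base
cancels).

## Synthetic tissue generator

The generator emulates layered cortical tissue: spots on a unit-spacing
jittered grid (jitter std 0.1 spacing), contiguous domains as parallel
stripes (cortical-layer analogue; Voronoi blobs and concentric rings also
available), log-normal baseline gene means (log-mean 1.0, log-sd 0.5 —
a few counts per gene, typical of spot-level depth per gene),
domain-specific marker programs multiplied by `exp(marker_log_fc)`,
gamma–Poisson (negative binomial) sampling with shape 2.0, and 5%
elementwise dropout. Presets: `easy` (800 spots, 4 stripes, 200 genes,
10 markers/domain, log-FC 1.5) is recoverable nearly perfectly and is the
main regression fixture; `ambiguous` lowers the marker log-FC to 0.3 so
expression alone is uninformative and any recovery must come from the
spatial graph; `noisy-labels` flips 5% of the returned ground-truth
labels. The generator does not emulate transcriptome-scale gene counts,
cell-type mixtures within spots, spatially varying capture efficiency, or
platform-specific artifacts — passing tests demonstrate correct mechanics
and sensible behavior under controlled signal/noise, not performance on
real tissue.

Scaled-down problem sizes are used for the shipped end-to-end checks
(100 pre-training / 200 training epochs on the 800-spot presets); the
stripe structure of the easy preset is recovered well within that
schedule, and all reported quantities are computed at those sizes.

## Known limitations

* The one-layer architecture aggregates spatial context a single hop per
  application; when expression carries almost no domain signal (the
  `ambiguous` preset), the achievable ARI is bounded by what one round of
  neighborhood smoothing exposes, and reconstruction-dominated training
  can erode even that. The ablation gap between the fused and gene-only
  graphs is then within run-to-run noise.
* Loss magnitudes follow the per-spot sum form of the reconstruction loss,
  so its gradient dominates the contrastive terms by roughly the gene
  count; this matches the printed objective and default weights but means
  γ₂ and γ₃ act as fine adjustments, not primary drivers.
* Refinement assumes roughly uniform spot density; a fixed radius in
  coordinate units over- or under-smooths where density varies.
* The h5ad reader loads matrices densely; memory scales as n_spots ×
  n_genes.
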