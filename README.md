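# stdcl

Spatial-domain identification in spatial transcriptomics by **dual graph
contrastive learning**: a single-hidden-layer graph convolutional
autoencoder fuses spatial coordinates and gene expression into one neighbor
graph, and two contrastive losses shape its latent embedding — one aligning
cross-view spot similarities with spatial adjacency, one decorrelating
latent feature dimensions at the cluster level. On top of the embedding the
package provides domain clustering with spatial label refinement,
latent-neighbor expression denoising, interpretable gene ranking, and
formula-faithful benchmark metrics. It is aimed at analysts working with
spot- or cell-resolved platforms (10x Visium, Stereo-seq, STARmap, osmFISH,
MERFISH) who have a counts matrix and 2-D coordinates and want contiguous,
biologically coherent tissue domains.

## Model

Given library-size-normalized, log-transformed, scaled expression
**X** ∈ ℝ^{n×g} and coordinates, two binary kNN graphs (k₁ spatial
neighbors, k₂ expression neighbors) are fused as

    A = min(A_spatial + α · A_gene, 1),     α ∈ (0, 1]

With the self-loop propagation matrix Ã = D^{-1/2}(A + I)D^{-1/2},
D = diag((A + I)·1), the autoencoder computes

    Z  = σ(Ã X W_e)          latent embedding (ELU, d = 64)
    H  = Ã Z W_d             reconstructed expression (linear decoder)
    Â  = sigmoid(Z Zᵀ)       reconstructed adjacency

and is trained on

    L = γ₁·L_rec + γ₂·L_con + γ₃·L_clu,     (γ₁, γ₂, γ₃) = (10, 0.5, 0.8)

where `L_rec = (1/n) Σᵢ [α₁‖Hᵢ−Xᵢ‖² + α₂‖Âᵢ−Aᵢ‖²]` with (α₁, α₂) =
(1.0, 0.5); `L_con` is the mean squared difference between the n×n
cross-view cosine similarity matrix (clean view vs a Gaussian-corrupted
view X̂ = X ⊙ N) and A; and `L_clu` pushes the d×d cross-view feature
cosine matrix of group-averaged embeddings toward the identity. Training
is two-phase Adam (reconstruction-only warm-up at lr 0.001 for 500 epochs,
full objective at lr 0.005 for 1000 epochs), run under two corruption noise
levels with the run of lower Davies–Bouldin index retained. Labels come
from a shared-covariance Gaussian mixture (or Leiden) on the PCA-20
embedding, followed by majority-vote refinement within a spatial radius.

The whole model, including its analytic gradients and the Adam optimizer,
is implemented in NumPy and validated against finite differences in the
test suite.

## Worked example

```python
import stdcl

ds = stdcl.generate_dataset(stdcl.get_preset("easy", seed=0))   # 800 spots, 4 stripe domains
cfg = stdcl.TrainConfig(pretrain_epochs=100, train_epochs=200, seed=0)
out = stdcl.run_pipeline(ds, k=4, cfg=cfg, refine_radius=1.5)   # 1.5 grid steps

ari = stdcl.adjusted_rand_index(ds.labels, out.result.labels_refined)
print(f"ARI={ari:.3f}  DBI={out.result.dbi:.3f}")
```

prints

```
ARI=0.997  DBI=0.526
```

meaning the refined domain labels agree almost perfectly with the simulated
stripe layout (adjusted Rand index 1.0 would be exact agreement), and the
selected training run produced compact, well-separated clusters in the
PCA-20 embedding (lower Davies–Bouldin is better).

The same pipeline is available from the shell:

```bash
stdcl simulate --preset easy --seed 0 --out data/
stdcl run --input data/ --k 4 --seed 0 --out results/
stdcl evaluate --labels results/labels.tsv --truth data/truth.tsv
```

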