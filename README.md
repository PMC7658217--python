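# diffproj

Adaptive diffusion-map embedding, clustering and trajectory analysis for
single-cell RNA-seq count data.

`diffproj` is for computational biologists who want a compact, tested
implementation of the diffusion-based single-cell workflow: quality-control
filtering and normalization of UMI count matrices, a density-adaptive
anisotropic diffusion-map embedding whose "structure components" replace
PCA, a UMAP layout of those components, shared-nearest-neighbor modularity
clustering, Wilcoxon marker ranking, cell-cycle scoring, and
absorbing-Markov-chain trajectory inference (pseudotime, terminal states,
branch probabilities, differentiation entropy, diffusion imputation, gene
trends). A synthetic-data module generates count matrices with known
cluster, cyclic and branching structure so the whole pipeline can be
exercised and validated without any real dataset.

## The method

Given a cell-by-feature matrix X (by default the z-scaled highly variable
genes), the embedding is built from a random walk on the cell graph:

1. **Adaptive kernel.** For each cell *i* with K nearest neighbors, the
   bandwidth σᵢ is its distance to the ⌈K/2⌉-th neighbor, and
   w<sub>ij</sub> = exp(−d²<sub>ij</sub>/σᵢ²) on graph edges, symmetrized as
   W = (w + wᵀ)/2. The kernel adapts to each cell's local density.
2. **Anisotropic normalization.** With degrees qᵢ = Σⱼ W<sub>ij</sub>, the
   kernel is renormalized W̃<sub>ij</sub> = W<sub>ij</sub>/(qᵢqⱼ)<sup>α</sup>
   with α = 1, which approximates the Laplace–Beltrami operator and
   decouples the manifold's geometry from sampling density. Row
   normalization yields the Markov operator P.
3. **Spectrum and multiscaling.** The top N eigenpairs of P are computed
   through the symmetric conjugate D<sup>1/2</sup>PD<sup>−1/2</sup>. The
   trivial pair (λ₁ = 1) is dropped and each remaining eigenvector ψᵢ is
   weighted by λᵢ/(1−λᵢ) — the closed-form sum of its contribution over
   random walks of every length. The number of **structure components**
   carrying signal is chosen at the largest eigengap (floor 2).
4. **Layout.** A UMAP layout of the structure components, with M
   (`min_dist`) the effective minimum distance between embedded points and
   S (`spread`) their effective scale, initialized from the leading
   components so runs are seed-stable.

Downstream, clustering runs Louvain modularity on an SNN-Jaccard graph of
the structure components; markers are ranked by ln fold change with
one-vs-rest Wilcoxon tests; and trajectories are inferred Palantir-style:
waypoint-refined pseudotime from a start cell, terminal states at
diffusion-component extrema, absorption probabilities of a forward-biased
walk, and per-cell differentiation entropy −Σ p ln p.

## Worked example

```python
import numpy as np
from scipy import stats
import diffproj as dp

# a 3-branch differentiation lineage with known ground truth
counts, truth = dp.simulate_branching_counts(
    n_cells=3000, n_genes=1500, n_branches=3, seed=1
)
scaled, lognorm, hvg = dp.preprocess_counts(counts, n_hvg=1500)

space = dp.fit_dbmap(scaled.values, dp.DbmapParams(n_components=30, n_neighbors=15))
print(f"eigenvalues: {np.round(space.eigenvalues[:6], 4)}")
print(f"structure components selected by eigengap: {space.selected_m}")

start = int(np.argmin(truth.pseudotime_true))
model = dp.TrajectoryModel().fit(space, start_cell=start)
rho = stats.spearmanr(truth.pseudotime_true, model.pseudotime_).statistic
print(f"terminal states detected: {len(model.terminal_cells_)}")
print(f"pseudotime vs truth (Spearman): {rho:.3f}")
print(f"max entropy (multipotent cells): {model.entropy_.max():.3f}  ln(3) = {np.log(3):.3f}")
```

prints

```
eigenvalues: [1.     0.9569 0.9538 0.9164 0.7719 0.7629]
structure components selected by eigengap: 3
terminal states detected: 3
pseudotime vs truth (Spearman): 0.936
max entropy (multipotent cells): 1.098  ln(3) = 1.099
```

The spectrum shows three eigenvalues near 1 followed by a sharp gap — the
three nontrivial directions of a 3-branch tree — and the eigengap rule
selects exactly those. The trajectory model finds one terminal state per
simulated leaf, orders cells in close agreement with the true depth, and
assigns near-maximal differentiation entropy (ln 3 for three reachable
fates) to uncommitted progenitors while terminal cells have entropy 0.

The same pipeline is available from the shell:

```bash
diffproj simulate branches --out sim --seed 1
diffproj preprocess --counts sim/counts --outdir prep --n-hvg 1500
diffproj embed --input prep/scaled.tsv --outdir emb --layout
diffproj cluster --components emb/components.tsv --outdir emb --resolution 0.1
diffproj markers --lognorm-dir prep --clusters emb/clusters.tsv --outdir mark
diffproj trajectory --components emb/components.tsv --start-cell <barcode> --outdir traj
```

All outputs are TSV tables with headers.

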