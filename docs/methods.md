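# Methods

This note documents the models and procedures implemented in `diffproj`,
the assumptions behind them, the parameters that matter, and the numerical
and design choices made where the recipe was genuinely open.

## Preprocessing

Cells are filtered on three per-cell statistics: total counts (`nreads`),
detected genes (`ngenes`) and mitochondrial percentage (`mito_pc`,
computed from gene symbols with a configurable prefix, default `MT-`).
Thresholds are free parameters; as an aid, `detect_knee` suggests a lower
bound as the knee of the log₁₀ rank curve — the point of maximum
perpendicular distance to the chord joining the curve's endpoints. This
rule was chosen because it is parameter-free, deterministic, and checkable
against an exhaustive oracle; a flat or log-linear curve has no knee and
is flagged rather than silently thresholded.

Normalization follows the standard per-sample workflow: counts per cell
scaled to a fixed size factor (default 10,000) and log1p-transformed.
Highly variable genes are ranked by dispersion (variance/mean of the
expm1-scale values), z-standardized within 20 equal-frequency mean bins
(default 5,000 genes kept); zero-variance genes never outrank genes with
positive dispersion, and remaining ties break by gene index for
determinism. Selected genes are z-scaled per gene with the *population*
standard deviation and clipped at ±10 — the convention of the workflow
this package mirrors; both choices are visible parameters rather than
silent defaults.

## Diffusion embedding

The embedding operates on any numeric matrix; the intended input is the
scaled HVG matrix, for which the diffusion components act as a drop-in
replacement for PCA. Stages, with defaults in parentheses:

- **kNN** (K = 15, euclidean): exact search with ties broken by index up
  to 8,192 cells (chunked brute force), the scikit-learn neighbor backend
  above that. Exactness at fixture scale makes the whole embedding
  bit-deterministic.
- **Adaptive kernel** (bandwidth rank ⌈K/2⌉): per-cell Gaussian bandwidth
  at a fixed neighbor rank, symmetrized by averaging. The bandwidth falls
  back to the smallest positive neighbor distance for duplicated points
  (and to 1 if a cell's whole row is duplicates).
- **Anisotropic normalization** (α = 1): kernel divided by
  (qᵢqⱼ)<sup>α</sup> then row-normalized. α = 1 approximates the
  Laplace–Beltrami operator; α is exposed for users who want plain
  normalized-cut behavior (α = 0).
- **Eigendecomposition** (N = 30): via the symmetric conjugate
  D<sup>1/2</sup>PD<sup>−1/2</sup>, dense below ~200 cells, otherwise
  ARPACK with a fixed constant start vector so results do not depend on
  global random state. Eigenvector signs are fixed so the
  largest-magnitude entry is positive.
- **Multiscaling and selection**: nontrivial eigenvectors are weighted by
  λ/(1−λ), the closed form of the component's contribution summed over
  random walks of every length (λ is capped at 1−10⁻⁹ first). This is our
  reading of "random walks scaled to normalize the relative progression of
  diffusion"; it matches the multiscale-space construction used by
  diffusion-based trajectory tools. The number of structure components is
  the position of the largest consecutive eigengap in the nontrivial
  spectrum, floored at 2 so a 2-D structure space always exists; a flat
  spectrum (no gap to find) sets a flag and the floor. A manual override
  (`n_select`) is available.

Assumptions worth noting: the kNN graph must be connected (an isolated
vertex is an error, not silently dropped), and eigenvalue multiplicity at
the top of the spectrum (disconnected data) makes component orientation
solver-dependent even with sign fixing.

## Layout

The 2-D/3-D visualization optimizes the UMAP cross-entropy objective over
a fuzzy neighbor graph built on the *selected* structure components, with
`min_dist` (M, default 0.3) and `spread` (S, default 1.0) as the two
user-facing geometry parameters (S ≥ M required). The layout is
initialized from the first d structure components scaled into UMAP's
10-unit box; with a fixed seed the optimization is single-threaded and
bit-reproducible. Optimizer internals (epochs, negative sampling) follow
the umap-learn defaults and are recorded in the fitted object only through
the seed; embedding quality is measured by rank-based trustworthiness
against the input components rather than by eyeballing.

## Clustering and markers

The cluster graph is a shared-nearest-neighbor graph: k = 20 neighbor
sets (self included), Jaccard edge weights, edges below 1/15 pruned — the
defaults of the workflow this package follows. Communities are found by
Louvain modularity (igraph, seeded; Leiden available as an alternative
backend) at resolution 0.8 by default, with 0.3 as the coarse "main cell
types" setting. Singleton communities are relabeled REMOVED (−1) and
clusters are renumbered by decreasing size. Modularity granularity scales
with graph size: on the 2,000-cell synthetic mixtures used for validation,
the coarse main-type structure emerges at resolution ≈ 0.1, which is what
the validation suite and acceptance script use; with tens of thousands of
cells the conventional 0.3/0.8 settings play the same role.

Markers are one-vs-rest per cluster: genes expressed in ≥ 10% of either
group and with |ln fold change| ≥ 0.25, where the fold change uses a +1
pseudocount on the expm1 scale (the natural-log convention must be stated
because "log fold change" is ambiguous across toolkits). P-values come
from the two-sided Wilcoxon rank-sum test — exact when both groups have
≤ 25 observations and no ties (midrank enumeration when ties are present
and the subset count is ≤ 2×10⁵; full enumeration near size 25 is
combinatorially impossible, so larger tied problems use the normal
approximation with tie correction) — with Benjamini–Hochberg adjustment
within each cluster. Tables are sorted by fold change, matching the
top-2-per-cluster reporting convention.

Cell-cycle scoring is the bin-matched module score: genes binned into 24
equal-frequency average-expression bins; for each signature gene, 100
control genes drawn (seeded) from its bin; score = mean signature
expression − mean pooled control expression. Phase is G1 iff both the S
and G2/M scores are ≤ 0, otherwise the argmax. Doublet *candidates* are
clusters whose best marker fold change is below 0.5 — flagging is
advisory because doublet removal in the source workflow was curation
driven; nothing is deleted without the caller's say-so.

## Trajectory

The multiscale space for trajectory inference is the eigengap-selected
structure components; the terminal-state scan additionally covers the
first 10 multiscale components. (Using unselected noise components in the
metric space measurably degrades pseudotime on synthetic lineages.)

- **Pseudotime**: shortest-path distance from the start cell on the
  k = 15 graph (edge length = Euclidean distance in multiscale space),
  then refined: each cell's value becomes the Gaussian-weighted average
  over 500 waypoints (deterministic per-dimension farthest-point sampling
  seeded at the start cell) of waypoint pseudotime ± graph distance, the
  sign negative for cells currently earlier than the waypoint; iterated
  until the largest change falls below `tol` (10⁻³ of the range) or 25
  passes, then shifted to zero at the start cell, negatives clamped, and
  min-max scaled to [0,1]. This is a deliberately simplified,
  convergence-bounded reconstruction of waypoint refinement;
  user-precomputed pseudotime can be supplied instead.
- **Terminal states**: candidates are the argmin/argmax cells of each
  scanned component. A candidate is kept when (a) its pseudotime is
  maximal within its own k-neighborhood up to a 0.2% slack — mid-branch
  extrema have later neighbors, true endpoints do not — and (b) its
  pseudotime exceeds the population's 75th percentile; survivors are
  greedily de-duplicated so no two share a k-neighborhood, later cells
  winning. Detection is a heuristic; supplying terminal cells explicitly
  bypasses it, and an empty result is an error instructing manual
  specification rather than a guess.
- **Branch probabilities**: the kNN graph is made directed, keeping edge
  i→j iff pt(j) > pt(i) − σᵢ where σᵢ is the standard deviation of
  pseudotime differences to i's neighbors (slack multiplier s = 1);
  weights are adaptive Gaussian kernels, rows normalized, terminal cells
  absorbing, and absorption probabilities solved exactly from the
  fundamental linear system (sparse LU). Cells with no forward path to
  any terminal are assigned to the nearest terminal by undirected graph
  distance, with a warning; edges into such cells are dropped and the
  remaining rows renormalized, i.e. probabilities are conditioned on
  absorption. Differentiation potential is the natural-log entropy of
  each cell's absorption row — 0 at terminals, at most ln(#terminals).
- **Imputation**: t applications of the Markov operator to the
  expression matrix (default t = 3; the diffusion time is not dictated by
  the source workflow). Pᵗ is never materialized; row-stochasticity keeps
  every imputed value inside its gene's observed range.
- **Gene trends**: Nadaraya–Watson regression of (imputed) expression on
  pseudotime, weighted by the branch probability of the queried terminal,
  on a 500-point grid over [0,1] with Silverman's rule-of-thumb bandwidth
  (floored at 10⁻³). Trends are fit on the log-normalized layer.

## Synthetic data

The generators produce the structures each stage assumes, with ground
truth, and are bit-reproducible per seed.

- **Counts model**: gamma-Poisson (negative binomial) with gene-level
  log-normal baselines, NB shape 10 (biological CV ≈ 0.32) and log-normal
  per-cell library factors (sd 0.3) — the accepted generative caricature
  of droplet UMI data at realistic noise levels.
- **Cluster mixtures** (2,000 cells × 1,000 genes, 5 clusters): each
  cluster up-regulates a broad program of 10% of genes by 2.5-fold — the
  canonical differential-expression fraction of droplet-data simulators —
  plus 3 strong canonical markers at 4-fold from a well-expressed
  baseline. Only the canonical markers are recorded as planted markers:
  a "top-5 by fold change" recovery check is meaningful only for few,
  strong markers.
- **Branching lineages** (3,000 cells × 1,500 genes, 3 branches): every
  cell has a depth u ~ U[0,1] and a latent branch; a root program (150
  genes, 4-fold at u = 0) decays log-linearly with depth, and committed
  cells (u > 0.3) interpolate log-linearly from root to leaf program over
  the full depth range, so commitment is switch-like (lineage priming)
  and branch markers of a depth-u cell sit at fold<sup>u</sup>. Cells
  before the branch point are statistically identical across branches;
  truth labels are 0 (root) before commitment.
- **Circles and mixtures**: unit circle plus Gaussian noise with the true
  angle returned; isotropic Gaussian blobs with centers at mutual
  distance sep·√dim (exact for k ≤ dim).
- **Doublets**: appended cells formed as ⌊(parent a + parent b)/2⌋ from
  random distinct parents, flagged in truth.

What the generators do *not* emulate: batch effects and study integration
(out of scope here), ambient RNA, empty droplets, gene–gene correlation
beyond the program structure, and spliced/unspliced layers. Passing tests
on these fixtures therefore demonstrate correctness of the algorithms and
recoverability of planted structure at realistic droplet noise — not
robustness to the full messiness of real tissue atlases.

## Validation scales and reproducibility

The validation suite and `scripts/acceptance.py` run everything at desk
scale: operators up to 300 cells are checked against dense solvers
(1e-8), the cyclic fixture uses 1,000 points, clustering 2,000 cells and
trajectories 3,000 — sizes at which the exact kNN path, dense oracles and
full pipelines all run in seconds to a couple of minutes on one CPU.
Recovery statistics (circular correlation of the cyclic coordinate,
adjusted Rand index, trustworthiness, Spearman pseudotime agreement,
post-branch assignment accuracy) are reported as measured; with the
generator defaults above they sit around 0.99 / ≥ 0.99 / ≥ 0.99 / ≥ 0.90 /
≥ 0.88–0.96 across seeds. Every source of randomness — simulation,
control-gene draws, Louvain, UMAP, ARPACK start vectors — is either
seeded or fixed, so identical calls give identical results.

## Known limitations

- Diffusion components cannot be evaluated on held-out cells
  (`DiffusionMap` has `fit`/`fit_transform` but no out-of-sample
  `transform`), as is inherent to spectral embeddings.
- The eigengap rule assumes one dominant scale; hierarchical data with
  several gaps get the largest one only (use `n_select` to override).
- Terminal-state detection assumes differentiation endpoints are both
  geometric extremes and pseudotime-late; cyclic trajectories have no
  terminals and should use user-supplied ones or pseudotime only.
- The Wilcoxon exact path degrades to the tie-corrected normal
  approximation for tied samples near group size 25, where enumeration is
  infeasible.
- Orientation of a square on-disk count matrix is ambiguous; the reader
  assumes the genes×cells convention.
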