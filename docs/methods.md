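# Methods

This note documents the models, numerical choices and limitations behind
`anchorcell`, in the order the pipeline runs.

## Normalization

Counts are transformed as `x = log10(r+1) / sqrt(colsum)` where the column
sum of the log-transformed values is taken **within each batch**.  The
per-batch scaling keeps sequencing-depth differences between datasets from
leaking into the shared feature space before any cross-batch step runs.
Columns whose within-batch sum is zero map to zero (0/0 := 0): this
preserves sparsity and avoids NaNs for genes undetected in one batch.
Gene alignment across batches keeps the intersection of gene identifiers in
lexicographic order, so results do not depend on the order batches are
supplied; duplicate gene ids within one file keep the first occurrence and
emit a warning.

## Dimension reduction

Both reducers target similarity preservation: minimize
`||X X^T − X' X'^T||_F^2` over rank-`d` representations `X'`.

* **FSM (default).** A streaming two-layer Hebbian/anti-Hebbian network.
  Per cell: output `y = M_lat^{-1} W x`; `W` moves toward `E[y x^T]`
  (Hebbian), `M_lat` toward `E[y y^T]` (anti-Hebbian).  The lateral inverse
  is maintained directly by a Sherman–Morrison rank-1 update, which keeps the
  per-sample cost at `O(d·M)` — the "fast" in fast similarity matching.  At
  the fixed point the learned map `F = M_lat^{-1} W` projects onto the top-d
  principal subspace of the uncentered second-moment matrix.  Numerical
  choices: learning rate `1/(t + 20)` with the lateral rate twice the
  forward rate; 30 epochs over a seed-shuffled cell order; rows are scaled
  to ~unit mean norm during fitting only (the learned linear map is scale
  equivariant, so it applies to the original matrix unchanged).  The
  validation surface is deliberately the Gram-matrix error against the exact
  rank-d eigendecomposition, not a specific iterate path, so any correct
  similarity-matching variant would pass.
* **PCA.** Exact top-d scores of the column-centered matrix (LAPACK SVD).
  PCA centers; FSM does not, because the similarity objective is defined on
  raw inner products of the normalized data.

Default `d`: `round(M/100)` clamped to `[30, 150]` and below `min(N, M)`.

## Ghost cells

Per batch, `m_h` K-means centroids (k-means++, 10 restarts, per-batch seed
derived from the global seed) of the reduced rows.  Centroids are anchors
only; no cell keeps a cluster label from this step.  Default `m_h`:
`round(N_h/100)` clamped to `[20, 100]` (e.g. 5,000 cells → 50 ghosts).
Empty-cluster handling and restarts follow scikit-learn's K-means, chosen
for robustness and reproducibility.

## Sparse encoding (LAE)

Per cell and per batch, the `s_h = ceil(p·m_h)` most cosine-similar ghosts
are selected (`p = 0.3` by default; ties at the cutoff resolve to the lower
ghost index; `s_h` is clamped to `[1, m_h]`).  The weights on the selected
ghosts solve the simplex-constrained least-squares problem; each batch block
of a row is its own simplex, following the per-ghost-set statement of the
constraint, so a row sums to `H` overall.  Solver: FISTA with fixed step
`1/L` (`L` = top eigenvalue of the anchor Gram matrix), Euclidean simplex
projection in `O(s log s)`, adaptive restart on objective increase, stopping
when the projected-gradient residual falls below `1e-7` (max 300
iterations; non-convergence returns the best iterate with a flag).  On
random instances the returned objective matches an exact active-set QP
oracle to ~1e-12.

## Message passing

One round: `Z_ghost = Z^T Z`, degree `D_kk` = column sums of `Z_ghost`,
`Z_G = D^{-1/2} Z_ghost D^{-1/2}`, `Z_W = Z Z_G`, then each row of `Z_W` is
scaled to unit L2 norm (`Z_norm`).  Zero-degree ghosts take a 0 entry in
`D^{-1/2}` (pseudo-inverse convention) and carry no message; all-zero rows
are left at zero with a warning.  A single round is used; the smoothing
operator's spectral radius is at most 1, and no iteration count is defined
by the scheme.

## Clustering and differential expression

Clustering is K-means on `Z_norm` rows (10 restarts, fixed seed); any other
clustering can be substituted by passing its labels downstream.  The DE
statistic per cluster `C` and gene `j` is the squared in/out mean difference
over the **population** (1/N) variance; genes with zero global variance get
`T := 0`.  `T` is invariant to shifting or rescaling a gene column.  It is a
ranking score, not a calibrated test — no p-values or FDR are produced.  By
default `T` is computed on the normalized matrix `x_ij`, which is the scale
the statistic is defined on; the log-transformed raw matrix can be passed
instead when marker ranking on unnormalized expression is wanted.

## Trajectory and pseudotime

Cluster similarity `A[p,q]` averages all pairwise cosine similarities
between the two clusters' embedding rows (computed as an inner product of
per-cluster means of unit rows; an explicit double loop is the test oracle).
The lineage tree is the spanning tree connecting the most similar clusters,
computed as the minimum spanning tree on `w = 1 − A`; a literal minimum
spanning tree on similarity weights would join the *least* similar clusters,
so the transformed weights implement the biologically coherent reading.
The root cluster should be supplied when known (accuracy is better with a
known root).  `auto` mode picks a maximum-eccentricity node of the tree — a
lineage endpoint, where the least differentiated type is expected to sit —
with ties to the lowest cluster id.  This is a documented heuristic, not a
biological inference.

The root **cell** of the root cluster maximizes the Pearson correlation
between its Euclidean distances to all cells and the cells' cluster
hop-depth from the root (degenerate correlations fall back to the lowest
cell index).  This "best accordance with the lineage ordering" criterion is
itself a design choice; note it trades distance to later clusters against
within-root-cluster distances, so the selected cell sits early in the root
cluster but not necessarily at its extreme tip.  Each non-root cluster's
landmark is its cell with the smallest mean distance to the parent cluster's
cells; a cell's distance is its distance to its own landmark plus the summed
landmark-to-landmark path back to the root; min-max scaling gives pseudotime
in `[0, 1]` (all-equal distances give all-zero pseudotime with a warning).
Cycles, multiple roots and probabilistic branch assignment are out of scope.

## Label transfer

The reference pipeline is fitted once; the stored model keeps the
projection, the ghost set, the smoothing operator `Z_G` and a classifier
trained on the reference `Z_W` rows.  Query cells are normalized (their own
column sums by default; the pooled reference column sums via
`normalization="reference"` — with the reference sums, a cell copied
verbatim from a single-batch reference embeds identically), projected with
the reference transform, encoded against the reference ghosts only, and
smoothed with the reference `Z_G`.  The classifier is a linear one-vs-rest
SVM (C=1, balanced class weights, fixed seed): linear for determinism and
speed, and because the embedding is already the learned representation.  A
single-class reference yields a constant classifier; classes with fewer
than two cells trigger a warning.

## Synthetic data generator

The generator is the package's study-condition definition, not a dial.  A
latent Gaussian construction separates the two things one needs to control
independently: geometry (cluster means are mutually orthogonal latent
directions at distance `separation·√2`, cells scatter with `within_sd`,
and a random loading matrix lifts latent positions to per-gene log-rates)
and DE ground truth (per-cluster marker genes receive an additive
natural-log boost).  Batch effects are additive per-batch, per-gene offsets
on the log-rate scale; counts are Poisson (or gamma-Poisson for
negative-binomial overdispersion).  Trajectory modes place cells along a
latent chain (or a branching tree with a shared trunk) and emit each cell's
continuous latent time.

Defaults — 2×300 cells, 600 genes, 4 types, separation 5.0 vs within-type
spread 1.0, batch offsets of sd 0.4, 10 markers/type at +1.5 — encode a
"clearly resolvable cell types under a moderate technology shift" scenario:
types that a competent method should separate, with batch offsets large
enough to confound naive concatenation.  What the generator does **not**
emulate: library-size variation, dropout/zero inflation, gene-gene
correlation structure beyond the low-rank lift, ambient RNA, or doublets.
Passing tests therefore show the machinery is correct and batch-robust under
controlled conditions; they do not certify performance on any particular
real dataset.

## Problem sizes and determinism

Tests and the acceptance script run at a few hundred cells and a few hundred
genes per condition — large enough that every stage (including the default
`d=30`, `m=20` recommendations) is exercised on its intended scale, small
enough to re-run anywhere.  All randomness funnels through explicit integer
seeds (per-stage seeds derived deterministically where needed); two runs
with the same seed reproduce the embedding, labels and pseudotime bitwise.

## Known limitations

* FSM quality depends on the learning-rate schedule; pathological spectra
  (near-flat eigenvalues around the cut at `d`) converge more slowly.  The
  Gram-error check against the exact eigensolver is the guard.
* Batch mixing is measured by `1 − NMI(clusters, batch)`; when a cell type
  is genuinely batch-unique, perfect clustering *must* retain some batch
  information, so 1 is not attainable by construction in that scenario.
* `auto` root selection is a topology heuristic; supply the root cluster
  when the least differentiated type is known.
* HDF5/loom ingestion, highly-variable-gene selection, GPU paths, and
  benchmark wrappers for external tool suites are out of scope.
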