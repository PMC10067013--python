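# Methods

## Problem setting

Mass cytometry (CyTOF) measures 13–60 protein markers on 10⁴–10⁶ single
cells. The first analysis step is almost always a reduction of the
cells × markers matrix to two dimensions for visualization, clustering
and cell-type assignment. Different dimension-reduction (DR) back-ends
distort different aspects of the data, and at CyTOF sample sizes many
classical evaluation statistics are not computable as written. This
package provides (a) a metric suite that stays linear in the number of
cells, (b) a bootstrap stability protocol, (c) hierarchical rank
aggregation with a complementarity analysis, and (d) a generative
simulator that produces ground-truthed CyTOF-like data so that every
metric can be exercised without any external dataset.

## Point-Cluster Distance (PCD)

Full pairwise-distance comparisons need O(N²) memory, which is
impossible at 10⁶ cells. PCD replaces them with the N × C matrix of
Euclidean distances from every cell to every original-space cluster
centroid. It keeps per-cell granularity (each cell's position relative
to all clusters) at O(N) memory. Both global metrics operate on the two
flattened PCD vectors, one from the original space and one from the
embedding, computed against the *same* original-space cluster
memberships:

* **COR** — Spearman correlation of the two vectors (rank-based, so no
  normality assumption; higher is better). Undefined on a constant
  vector; returned as NA.
* **EMD** — 1-D Wasserstein distance between the two vectors after
  min-max normalization of each (the two spaces have arbitrary,
  incomparable scales). Lower is better. A constant vector min-max
  normalizes to all zeros, so two degenerate vectors compare equal.

## Local structure

* **KNN preservation** — each cell's k nearest neighbors (Euclidean,
  self excluded, k = 100 by default) are found in both spaces; the score
  is the mean over cells of |intersection| / k.
* **NPE (neighborhood proportion error)** — for each cell, the fraction
  of its k neighbors sharing the cell's original-space cluster, in both
  spaces; per cluster, Gaussian kernel density estimates (Scott's
  bandwidth) of the two proportion vectors are evaluated on a 1024-point
  uniform grid over [0, 1] and the supremum of the absolute density
  difference is taken; per-cluster values are averaged. A cluster whose
  proportion vector has zero variance in either space is a point mass
  with no density estimate and is skipped; if every cluster is skipped
  the metric is NA. The sup-of-density-difference form is implemented
  exactly as stated by its formula even though the quantity is described
  as a total-variation distance; a CDF-based Kolmogorov–Smirnov variant
  would be a different statistic, and we deliberately do not substitute
  it.

Exact neighbor search (scikit-learn) is used up to 20,000 cells so
results are brute-force verifiable; above that an approximate
nearest-neighbor index (pynndescent) is used, which on Gaussian-mixture
data keeps mean recall ≥ 0.95 versus exact search. Distance ties are
broken by lowest cell index for determinism.

## Downstream metrics

Cluster reconstruction scores the original-space clustering as seen in
the embedding: silhouette, Davies–Bouldin, Calinski–Harabasz (all
standard definitions; CH returns NA when within-cluster variance is
exactly zero, where the index diverges), and random-forest cluster
prediction — a 100-tree forest trained on a stratified 67% split of the
embedding predicting the cluster labels of the held-out 33%.

Cluster concordance and cell-type concordance both use ARI and NMI
(NMI normalized by the arithmetic mean of the marginal entropies; a
constant labeling yields 0 by convention), applied to original-space vs
embedding-space clusterings, and to annotated cell types vs
embedding-space clusterings, respectively.

Embedding-space clustering uses a SOM-plus-meta-clustering recipe (the
cytometry standard): a 10×10 self-organizing map is trained on the
embedding, then the codebook vectors are consolidated by Ward
agglomeration down to the requested number of clusters. k-means is
provided as a deterministic fallback and is what controlled comparisons
in the test suite use, so metric correctness is never hostage to SOM
stochasticity.

## Cross-modality concordance

When a matched scRNA-seq reference exists, absolute distances carry no
meaning across modalities, so the comparisons are rank-based over the
cell types the two datasets share (exact, case-sensitive name
intersection):

* **Cluster Distance** — per ordered type pair (a, b), the rank of
  d(centroid_a, centroid_b) among a's distances to all other common
  centroids, divided by the number of common types T; the metric is the
  L1 distance between the two modalities' length-T(T−1) rank vectors.
  Ranks are asymmetric by construction: a crowded type sees its partner
  at a higher rank than an isolated one does.
* **concordance EMD** — the distribution-level analogue: distances from
  a's centroid to *every* cell are ranked (1-based, ties broken by cell
  index); the ranks of b's cells, divided by the modality's total cell
  count N, are pooled over all ordered pairs; the two pooled vectors are
  compared by the 1-D Wasserstein distance. "Normalized by sample size"
  is read as division by N, consistent with the centroid version's
  normalization by the candidate count.
* **gating concordance** — ARI/NMI between original-space and
  embedding-space cell typings. In the pipeline, embedding-space types
  are assigned by majority cell type within each embedding-space
  cluster.

## Stability

The sample is bootstrapped B times (size-N draws with replacement,
B = 100 by default); the DR method re-runs on each resample with
unchanged tuning parameters; each embedding is summarized by its
flattened PCD vector, with every resampled cell keeping its source
cell's cluster label (re-clustering each bootstrap would confound
method stability with clustering stochasticity); and each bootstrap
vector is compared with the reference embedding's via
EMD(minmax(P), minmax(Q)). The score is the mean over completed
bootstraps; iterations where the method aborts are excluded and counted.

## Rank aggregation

Per metric, methods are ranked with higher rank = better. Ties take the
maximum rank of their tied block (values (0.3, 0.5, 0.5) over three
methods rank (1, 3, 3)). A method that failed a metric ranks below every
finite value; multiple failures tie among themselves, so under the
maximum-rank rule each receives rank = (number of failures). Ranks are
then averaged with equal weights: metrics within a sub-category,
sub-categories within a major category (Global and Local have no
sub-categories and average their metrics directly), and the available
major categories into the overall accuracy score. When no matched
scRNA-seq reference exists, the overall score is the mean of the three
remaining major categories.

Complementarity over D datasets is the greedy coverage curve: at each
step, add the method whose selection covers the most additional
datasets' top performers (ties broken lexicographically) and report the
cumulative covered fraction.

## Simulator

The generative model (documented in `cytomulate.py`) draws, per cell: a
type from Categorical(π); per marker, a base expression from
Normal(μ, σ²) with μ = σ = 0 on the type's null-marker set; if the type
has children in the differentiation forest, a uniformly chosen child
and, per marker, a pseudotime t ~ Beta(0.4, 1) evaluated through a path
g with g(0) = 0 and g(1) = μ_child − μ_parent; and additive noise
Normal(0, noise_sd²). The Beta(0.4, 1) prior places most cells near the
parent state with a decaying tail toward the child, as along real
differentiation trajectories.

Design points that were genuinely open:

* The path process is only constrained at its endpoints. The default
  realization is the straight line g(t) = t·Δμ; a Brownian-bridge
  perturbation pinned at both endpoints is available
  (`path_kind="bridge"`, scale `bridge_sd`), and collapses to the line
  at `bridge_sd = 0`.
* Pseudotime is drawn independently per marker per cell (the literal
  model); a shared-per-cell draw is available behind
  `shared_pseudotime=True` as the biologically smoother alternative.
* Child selection is uniform over the parent's children.
* Noise and pseudotime are drawn per marker.

`default_model` builds randomized fixtures: types partitioned into a
requested number of differentiation trees; root marker means
Normal(3, 1) truncated at zero (typical arcsinh-scale magnitudes for
expressed markers) and child means perturbing the parent's by
Normal(0, 1); marker SDs Uniform(0.2, 0.6); 30% of markers silenced per
type (at least one expressed); noise_sd = 0.2, small relative to
typical means; and a Dirichlet(1) type prior mixed toward uniform so
every type keeps ≥ 2% abundance — without the floor a draw can leave a
type with one cell in modest samples, which makes stratified downstream
metrics degenerate rather than informative. All of these are
constructor arguments.

What the simulator does *not* emulate: batch effects, acquisition-time
signal drift, doublets, spillover, or fitting of model parameters to a
real dataset. Tests passing on simulated data therefore certify the
metric and aggregation machinery and the simulator's own distributional
claims — not the real-data rankings of any particular DR method.

## Numerical and policy choices

* arcsinh(x/5) is the preprocessing transform (cofactor 5, the mass
  cytometry convention; inputs are assumed pre-gated — debris gating
  and bead normalization are instrument-pipeline steps out of scope).
* The subsample-fit-then-map policy fits a mapping-capable back-end on
  floor(0.1·N) cells sampled without replacement and maps all N cells,
  preserving row order; it exists for back-ends that abort at full N.
* All randomness in a benchmark run derives from one master seed through
  CRC-based child seeds keyed by stage and method name, so adding a
  method never perturbs another method's results.
* DR back-end exceptions are captured per method; metric-level failures
  (degenerate geometry, singleton classes) become NA for that metric
  only.
* FCS support is a built-in minimal FCS 3.0/3.1 reader (float list-mode
  data segments, the modern CyTOF export format); compensation keywords
  are ignored since CyTOF has minimal spillover.

## Problem sizes used in the test suite

Unit tests run on 4–200-cell fixtures where brute-force oracles are
exact. The system-level checks use simulated samples of 2,000 cells
(stability, 20 bootstraps), 5,000 cells (noise-degradation
monotonicity, k = 100, 10 seeds × 6 noise levels) and 10,000 cells × 30
markers × 8 types (end-to-end ranking against a shuffled random
projection baseline, 5 seeds); simulator parameter recovery uses 10⁶
pseudotime draws. These sizes are the package's own choice of the
smallest scales at which each property is cleanly measurable.

## Known limitations

* The NPE density-difference supremum depends on the KDE bandwidth;
  Scott's rule is fixed, and values are comparable only across methods
  evaluated with the same settings.
* The SOM implementation is a minimal online map intended for
  meta-clustering embeddings, not a full cytometry clustering toolkit.
* t-SNE and spectral embedding have no out-of-sample mapping here, so
  they cannot use the subsample-fit-then-map policy.
* Approximate neighbor mode trades exactness for speed; oracle
  verification applies to exact mode only.
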