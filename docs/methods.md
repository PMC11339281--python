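# Methods

## Scope and data model

`nkfate` analyses droplet-based scRNA-seq UMI count matrices (genes × cells,
sparse integers) with per-cell metadata (sample, time-point group, batch).
The pipeline order is: QC → log-normalization → highly variable genes →
scaling + PCA → (optional batch correction) → cell-type annotation → NK
subset → death-state classification → composition → pseudo-bulk DE →
co-expression modules → MST pseudotime → ligand–receptor communication.
Every stage writes plain TSV/JSON and a manifest (parameters, seed, input
checksums), so runs are auditable and any stage can be re-executed in
isolation.

## Preprocessing

* **QC windows.** Cells are kept when they have 200–2500 detected genes,
  800–10,000 total UMIs (both inclusive) and a mitochondrial UMI fraction
  strictly below 5% (genes with the configurable `MT-` prefix).  QC is
  idempotent.
* **Normalization.** x_gc = ln(1 + c_gc·s/T_c) with scale factor s = 10⁴ and
  T_c the per-cell total.  Normalization commutes with gene subsetting.
* **HVGs.** Dispersion (variance/mean of normalized values) standardized
  within equal-frequency mean bins; 20 bins, reduced so every bin keeps at
  least ~20 genes (z-scores inside 5-gene bins are noise).  Constant genes
  are never selected.  Default n = 2000.
* **Scaling/PCA.** Per-gene centering and unit variance, values clipped at
  ±10 to bound outlier leverage, then exact (full-SVD) PCA; the top k = 10
  components feed every downstream stage.  Component signs are fixed by a
  largest-loading convention; requesting components beyond the data rank is
  an error.
* **Batch correction (optional, off by default).** A deliberately simple
  iterative mutual-nearest-neighbor scheme in PC space: each moving-batch
  cell's closest mutual pair with the reference batch defines a correction
  vector; cells receive Gaussian-kernel-weighted averages of those vectors,
  repeated until corrections vanish (a single pass under-corrects when the
  shift exceeds the cloud spread, because mutual pairs connect facing
  boundaries).  A constant shift is only identifiable when it is small
  relative to the between-population structure — this is inherent to MNN
  logic, not to this implementation.
* **Annotation.** Marker genes are z-scored; a type's score is the mean z of
  its markers; clusters take the best-scoring type, clusters expressing two
  or more conflicting marker programs (two type scores above threshold) are
  flagged ambiguous, and clusters with no positive score are unassigned.

## Death-state classification

1. **Two-step clustering.**  k-means (k_micro = min(200, n/10), k-means++,
   10 restarts, fixed seed) quantizes the NK cells in PC space; a
   shared-nearest-neighbor graph is built over the micro-cluster centroids
   with Jaccard weights, with edges restricted to *mutual* kNN pairs
   (at centroid granularity a small population contributes few nodes, and
   one-directional forced links would wire it into its nearest large
   neighborhood); Leiden modularity (resolution 1.0) yields communities and
   cells inherit their micro-cluster's community.
2. **Ranking.**  Per cluster, genes are ordered by log2 fold change of mean
   un-logged expression against all remaining NK cells (ε = 10⁻⁹
   regularized), ties broken by two-sided Wilcoxon rank-sum p, then gene
   name.  A signal-to-noise metric is available behind a flag.
3. **Enrichment.**  The weighted KS-like running-sum statistic (weight
   w = 1, minimum intersection 5) scores each of the twelve RCD signatures.
   Significance comes from a true phenotype permutation: cluster-vs-rest
   labels are shuffled and the *ranking is recomputed* for each of n_perm
   permutations (default 1000; permuted rankings skip the Wilcoxon
   tie-break, which is measure-zero on continuous data).  p is the add-one
   same-sign tail frequency; NES divides the observed ES by the mean
   same-sign |ES_perm|.  Before ranking, the tested universe is restricted
   to genes detected in ≥5% of the cells (and signatures intersected with
   it): detection-limit genes produce ε-dominated fold changes that only add
   rank noise to the running sum.
4. **Assignment.**  Within each cluster, BH adjustment runs across the
   twelve signatures **in the enrichment direction**: the decision rule can
   only ever select positive enrichment, so depleted signatures enter the BH
   family with p = 1 rather than with their (often tiny) depletion tails,
   which would otherwise shrink the family and promote weak positive
   artifacts in healthy clusters.  The cluster label is the max-NES
   signature among {NES > 0, p_adj < 0.05}; ties break by a fixed canonical
   paradigm order; no qualifying signature ⇒ healthy.  Intrinsic and
   extrinsic apoptosis report together as "apoptosis", MPT-driven necrosis
   and necroptosis as "necrotic"; the remaining paradigms keep their own
   names.  Clusters smaller than `min_cells` (10) cannot be ranked and
   default to healthy with a warning.

Permutation-resolution note: with the add-one same-sign formula, the
smallest attainable p at n_perm permutations is ≈ 2/n_perm.  After BH across
twelve signatures at α = 0.05, fewer than ~600 permutations can never reach
significance; the default of 1000 leaves headroom (p_adj ≈ 0.024 at the
floor).

Known limitation (observed on the synthetic test bed): when a small death
population fails to separate in the 10-PC embedding, its cells land inside
a healthy cluster and the max-NES rule can label that whole cluster by the
contaminant's signature, which is genuinely (if undesirably) enriched
relative to the remaining cells.  At the default conditions this affected
one cluster in one of ten sweep seeds.

## Composition

Exact count ratios per (group[, sample]) × state, absent states included
with zero.  Group comparisons: two-sided Wilcoxon rank-sum with exact
enumeration when both n ≤ 10 (asymptotic otherwise), Welch t, or one-way
ANOVA.  Fraction-vs-covariate (e.g. lactate) uses ordinary least squares
with Pearson R and its two-sided p.

## Co-expression modules

Unsigned adjacency a_ij = |cor(x_i, x_j)|^β (Pearson, β = 6; a soft-
threshold scan with a log-binned scale-free-fit R² ≥ 0.8 criterion is
provided), topological overlap
t_ij = (Σ_u a_iu·a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij) with self-edges
excluded from connectivity, average-linkage clustering of 1 − TOM with a
static cut (default height 0.9, the `cutreeStatic` convention; a
permutation-calibrated cut — the quantile of the shuffled-gene null
dissimilarity — is available and sharper for small sample counts, but
collapses once weak systematic factors such as batch beat chance).
Clusters under `min_module_size` fall into module 0.  Eigengenes are the
first PC of the standardized module submatrix, unit norm, oriented to
correlate positively with the module's mean profile; module–trait
association uses Spearman's ρ with the Student-t approximation
t = ρ√((n−2)/(1−ρ²)).  ORA is the upper-tail hypergeometric with BH across
sets.  Loess trends are locally weighted (tricube) linear fits, span 0.75,
with a seeded 200-replicate residual-bootstrap 95% band.

Resolution choice: module analysis runs on **sample × state pseudo-bulk**
of the NK cells (thin columns with <10 cells dropped).  Sample-only
aggregation makes the group-driven signature profiles collinear with any
group-level trend (the module structure then merges), while per-cell
analysis degenerates the permutation null; the sample × state design
decouples state-driven from trend-driven co-variation.  The pipeline feeds
the top 1500 genes by pseudo-bulk variance (the planted hypoxia-like module
sits below the top 500 because on/off death programs dominate variance) and
uses `min_module_size` 20 so signature-sized (25-gene) modules are
detectable.

## Trajectory

State centroids in the (corrected) PC embedding are joined by a complete
Euclidean graph; the MST is exact (Kruskal over lexicographically sorted
edges, making tie-breaks deterministic).  Rooted at healthy NK cells, each
cell is orthogonally projected onto the nearest point of the MST edges
incident to its own state's node (preventing pseudotime jumps across
unrelated branches), and pseudotime is the tree-geodesic distance from the
root centroid to the projection.  Decision points are nodes of degree ≥ 3,
ordered by centroid pseudotime.  Pseudotime is invariant to rigid rotations
of the embedding.  On the default synthetic data the state programs are
mutually orthogonal, so the MST is a star around healthy — branch-point
counts there say nothing about real data, whose geometry sets its own tree.

## Communication

Candidate channels require the ligand over-expressed in the source *and*
every receptor subunit over-expressed in the target (one-sided Wilcoxon vs
all other cells, p < 0.05, detected in ≥10% of the population; populations
under 10 cells are skipped).  Population expression is Tukey's trimean
(Q1 + 2·Q2 + Q3)/4 with type-7 quartiles; multi-subunit receptors use the
geometric mean of subunit trimeans.  The interaction probability follows the
mass-action form p = L·R/(Kh + L·R) with Kh = 0.5 and Hill coefficient 1
(both configurable); significance is a label-permutation test (default 100
permutations, add-one corrected, so the smallest attainable p is 1/101);
significant pair probabilities sum into pathway weights per
(source, target).  Cofactor/agonist terms are out of the model.

## Pseudo-bulk DE

Counts are summed per (sample, state); columns with <10 cells are flagged.
Contrasts use log2 CPM (prior 1), a two-sided Wilcoxon rank-sum across
replicate columns (exact when both sides have ≤10 columns), BH across
genes, and the DEG rule |log2FC| > 1 ∧ p_adj < 0.05.  The rank-based test
is a deliberate substitute for parametric negative-binomial models: DEG
*counts* on real data will agree in spirit, not in number, with analyses
built on such models.  Note the rank-sum's granularity: at 5-vs-5
replicates the smallest two-sided p is 2/252, so genome-wide BH
significance requires more replicates or smaller universes.

## Synthetic data: what it emulates, and what it does not

The generator draws Gamma–Poisson (negative binomial, dispersion 10) counts
with log-normal library sizes (μ = ln 3000, σ = 0.3; the expected per-cell
total is exp(μ + σ²/2)).  A cell's mean vector is built in log-space from:
a shared gamma-law baseline; a per-type transcriptome-wide identity
(σ = 0.4) plus boosted canonical markers (+3 log-units); the cell's death
program (+2.0 log-units on its 25-gene signature; healthy NK cells carry no
program); a 40-gene hypoxia-like module driven by a latent that rises then
falls over the groups (0, 0.8, 1.2, 0.5, 0.2) with per-cell noise; a
two-batch per-gene offset (σ = 0.1); and planted ligand/receptor boosts.
Signature genes follow the same baseline-expression law as the rest of the
transcriptome — granting them a privileged expression tier makes unplanted
signatures an artificially coherent block that picks up spurious enrichment
through the library-share drain of active programs.  Ligand/receptor genes
are exempt from the per-type identity so the planted channels stay the only
population-differential LR signal.

Default study conditions: 2000 genes, 5 groups × 1000 cells, NK share 0.40
(deliberately enriched over real PBMC so each death state has enough cells
at this scale), 4 samples per group split over the two batches, and
paradigm mixing that mirrors the published post-trauma time course
(apoptosis 63%/84% at 4 h/6 h; pyroptosis 80%/78% at 24 h/72 h; minor
states ≈5%).  The planted fractions use one apoptotic paradigm and
necroptosis for the necrotic state: with k fixed at 10 PCs, six planted
programs + hypoxia + batch = 8 latent directions leave the embedding slack,
whereas nine planted directions saturate it and a small program loses its
PC direction in some seeds.

Passing the synthetic tests shows the *implementation* recovers planted
structure under this model.  It does not show the model fits real data:
real transcriptomes have correlated background programs (cell cycle,
stress), ambient RNA, doublets, empty droplets, batch effects that are not
mean shifts, signatures that overlap each other, and death states that are
continua rather than discrete programs.  Claims about real tissue need the
real curated signatures (the packaged GMT is a synthetic illustration) and
external validation.

## Numerical and reproducibility notes

* One global seed fixes every stochastic component (simulation, k-means
  restarts, Leiden, permutations, bootstrap); reruns are byte-identical.
* BH adjustment is the standard step-up procedure (cross-checked against
  statsmodels); p_adj ≥ p is enforced.
* Fold changes are ε-regularized (10⁻⁹); float32 BLAS accumulation in the
  permutation engine clips the complement mean at zero.
* Exact Wilcoxon enumeration is used whenever both groups have ≤10
  observations; asymptotic with tie correction otherwise.
* Degenerate inputs (zero-total cells, constant genes in the network,
  rank-0 modules, empty gene sets, disconnected trees, spans too small for
  local fits) raise errors naming the offender rather than propagating NaNs.
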