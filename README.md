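# nkfate

Natural killer (NK) cells are depleted after severe trauma, and the depletion
is not explained by apoptosis alone: single cells distribute over several
regulated cell death (RCD) paradigms — apoptosis, pyroptosis, necrotic death,
ferroptosis, autophagy-dependent and immunogenic cell death — whose mix
shifts over the post-injury time course. `nkfate` is a tested, reusable
implementation of the computational pipeline behind that kind of analysis,
for anyone who wants to classify single cells into death states from
scRNA-seq and study what co-varies with them:

1. **Death-state classification** — two-step clustering of NK cells (k-means
   vector quantization, then modularity communities on a mutual-kNN
   shared-nearest-neighbor graph over the micro-cluster centroids), per-
   cluster gene ranking by log2 fold change, and a weighted
   Kolmogorov–Smirnov-like enrichment statistic with an empirical
   phenotype-permutation test against twelve RCD signatures.  Each cluster
   receives the paradigm with the highest normalized enrichment score (NES)
   among signatures with NES > 0 and BH-adjusted p < 0.05; clusters with no
   enriched signature are healthy.
2. **Composition** over time points, with exact small-sample Wilcoxon,
   one-way ANOVA and fraction-vs-covariate regression.
3. **Co-expression modules** — unsigned weighted network (|cor|^β, β = 6),
   topological overlap, average-linkage modules, eigengenes, and
   module–trait Spearman correlation (the hypoxia-module analysis).
4. **Pseudo-bulk differential expression** (sample × state sums, Wilcoxon on
   log-CPM, BH; DEG = |log2FC| > 1 and adjusted p < 0.05).
5. **MST pseudotime** over state centroids rooted at healthy NK cells, with
   per-cell projection onto incident tree edges and branch (decision) points.
6. **Ligand–receptor communication** between death-state NK populations and
   other immune cells: over-expression detection, Tukey-trimean averaging,
   mass-action interaction probability p = L·R/(Kh + L·R), label-permutation
   significance and pathway-aggregated weights.

Because the statistics above only mean something when they can be checked,
the package ships a first-class synthetic-data generator
(`nkfate.synthdata`): negative-binomial UMI counts with log-normal library
sizes, marker-defined immune cell types, planted death-signature programs
whose mixing shifts across five time-point groups, a hypoxia-like
co-expression module with a rise-then-fall latent trend, a two-batch design
and planted ligand–receptor channels.  Every stage is tested against this
ground truth or against brute-force oracles.

## The core statistic

Genes are ranked for each cluster by r_j = log2 FC against all other NK
cells.  For a signature S, walking the ranked list accumulates

    hit:  + |r_j|^w / N_R      with  N_R = Σ_{g∈S} |r_g|^w   (w = 1)
    miss: − 1 / (N − |S|)

and ES(S) is the signed maximum deviation of this running sum.  Cluster
labels are permuted n_perm times (default 1000) with the ranking recomputed
each time; p is the add-one-corrected same-sign tail frequency and
NES = ES / mean |ES_perm| over same-sign permutations.

## Worked example

`nkfate demo --seed 1 --out run/` executes the whole pipeline on the default
synthetic experiment (2000 genes, 5 groups × 1000 cells).  The same steps as
separate analyses live under `analysis/` (01 simulate → 07 communication).
Running them prints, among other things:

```
QC: retained 5000/5000 cells
annotation accuracy vs ground truth: 1.000
classifying 2028 NK cells
state totals: {'pyroptosis': 668, 'apoptosis': 631, 'healthy': 566,
               'autophagy': 44, 'ferroptosis': 43, 'immunogenic': 43,
               'necrotic': 33}
recovered death-state fractions per time point:
         apoptosis  pyroptosis  necrotic  ferroptosis  autophagy  immunogenic  healthy
control      0.059       0.047     0.010        0.000      0.000        0.000    0.884
PT-4h        0.610       0.000     0.000        0.060      0.065        0.058    0.208
PT-6h        0.859       0.000     0.000        0.045      0.045        0.051    0.000
PT-24h       0.000       0.782     0.023        0.002      0.000        0.000    0.192
PT-72h       0.058       0.788     0.048        0.000      0.000        0.000    0.108
max |recovered - planted| = 4.20 points
module M3 matches the planted hypoxia module (Jaccard 0.93), rho = 0.975
MST over 7 state centroids, rooted at 'healthy'
planted channels recovered: 3/3   (top weight: NK_apoptosis -> neutrophil, CXCL, 1.95)
```

Reading this: the classifier recovers the planted time course — apoptosis
dominating the early phase (61%/86% at 4 h/6 h), pyroptosis the late phase
(78%/79% at 24 h/72 h) — every per-group state fraction is within 4.2
percentage points of the planted truth, the planted hypoxia-like module is
the most trend-correlated co-expression module, and the planted
ligand–receptor channels carry the top communication weights.

## Using your own data

`read_10x()` ingests an MTX-triplet directory (matrix.mtx, genes.tsv,
barcodes.tsv, optional cell_metadata.tsv); signatures load from GMT
(`read_gmt`), ligand–receptor tables from TSV (ligand, receptor with
`;`-separated subunits, pathway).  The packaged death-paradigm GMT and LR
table are synthetic/minimal illustrations — supply curated files for real
studies.  See `docs/methods.md` for the model, parameter and limitation
notes, in particular on what passing the synthetic tests does and does not
imply for real data.
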