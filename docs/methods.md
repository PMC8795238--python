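# Methods

This note records the models behind each stage, the tunable parameters and
their defaults, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was open.

## Quality control

Four rules flag a low-quality droplet, evaluated on raw UMI counts before
normalization: (1) standard deviation of counts across all genes below 1
(sample sd, ddof = 1, matching R's `sd`; the scale is a design choice — the
rules are applied pre-normalization, so raw counts are the natural operand);
(2) fraction of genes with zero count ≥ 0.90; (3) combined mitochondrial +
hemoglobin UMI fraction ≥ 0.10 (MT-prefixed symbols and the HB gene family);
(4) total UMI < 100 or > 20,000. Boundary conventions: rules 2 and 3 remove
at the threshold, rule 4 is strict. Filtering is idempotent and every
removed cell's rule set is reported. Normalization is
`log(1 + c_g / Σ_g c_g · s)` with scale factor `s = 10,000` (the
conventional default; configurable). The immune/non-immune split calls a
cluster immune iff its mean PTPRC expression strictly exceeds the global
per-cell mean — the cluster-level call damps dropout noise; the threshold
and the clustering-before-split order are both configurable.

## Variable genes, clustering, typing

HVGs use the classic binned-dispersion procedure (dispersion = log
variance/mean of de-logged values, z-scored within 20 equal-width mean bins;
cutoffs mean ∈ (0.0125, 6), z > 0.5), via scanpy's `seurat` flavor, which
implements exactly this construction. Clustering: z-scaled HVG submatrix
(clip ±10) → PCA (30 components computed, 20 used, full SVD so results are
deterministic) → exact kNN (k = 20, self included) → SNN graph with Jaccard
weights shared/(2k − shared) → Louvain modularity (igraph
`community_multilevel`) at resolution 0.8 with a seeded RNG. Labels are
re-indexed by cluster size. Marker tests are one-vs-rest Wilcoxon rank-sum
on genes detected in ≥25% of in-cluster cells with natural-log fold change
≥ 0.25 (log of de-logged means, the convention the 0.25 cutoff assumes);
Bonferroni uses the full gene universe, FDR is Benjamini–Hochberg over all
performed tests, and the final marker flag requires ≥2-fold up-regulation
with FDR < 0.01 — the stricter of the two printed criteria, computed both
ways. Cell typing scores each cluster by the mean z-scored expression of
each type's markers; ties break by detected-marker count then name;
clusters with zero marker expression are "unassigned". Composition tests:
per-sample frequency t tests between lesion/Lauren groups and per-cluster
two-proportion z tests.

## Copy-number scores

Genes are ordered by (chromosome, start, gene id; 1-based starts as in the
feature table). Expression is centered on the per-gene mean of a reference
set of presumed copy-neutral cells, clipped to ±3, smoothed by a centered
moving average of `window` genes (default 101; truncated at chromosome
edges, with a notice when a chromosome is shorter than the window),
median-centered per cell, then re-centered on the reference cells so the
reference per-gene mean is zero to machine precision. Burden is the mean
squared score. The construction is the standard expression-CNV
moving-window method; it detects relative dosage, not integer copy number.
Gene-level calls threshold the cluster-mean score at ±0.15 (configurable).
Reference-only input leaves only smoothed sampling noise of order
1/√window in the scores — "zero" only relative to planted-signal burden.

## Trajectory and progression states

Cells are reduced to 2-D (default: plain PCA on the scaled HVG submatrix;
PCA→ICA available via `reduction="ica"` — ICA occasionally folds an
elongated lineage back on itself, so PCA is the safer default), summarized
by 30 representative cells (k-means centers snapped to the nearest real
cell; true PAM k-medoids is not available in the installed stack and the
snap preserves the "tree over real cells" property), and joined by a
Euclidean minimum spanning tree. The root is the medoid whose assigned
cells are richest in the configured benign types (GMC/enteroendocrine by
default) or an explicit node. Pseudotime = tree geodesic distance from the
root medoid plus the cell's offset to its own medoid; cells are internally
sorted by barcode first, so pseudotime is invariant to input order at a
fixed seed. Branch segments are the components left after removing
degree-≥3 nodes. Progression states are equal-count pseudotime quantile
bins over non-excluded cells (excluded stromal types get terminal
`excluded:<type>` labels), ordered by mean pseudotime; within-branch
quantiles were considered and rejected because spurious micro-branches of
the medoid MST make the allocation unstable — branch membership is reported
separately so terminal branches (the D3-vs-D4 style distinction) can be
cross-tabulated against states. Pseudotime-dependent genes use a Gaussian
working model on the log scale: LRT of a natural cubic spline basis (3 df,
`patsy cr`) against intercept, n·log(RSS₀/RSS₁) ~ χ²₃; constant genes get
p = 1 by convention.

## Mutations

VAF = alt/(alt+ref) where depth > 0; zero-depth sites are missing, not
zero. "Mutated" means ≥1 alt read (no depth floor by default; a minimum
depth is exposed). Hotspot filtering keeps catalog variants with at least
one alt read somewhere and drops immune cells from tabulation. Fisher's
exact test is two-sided hypergeometric; the odds ratio takes a Haldane 0.5
correction when any cell is zero, and a zero margin returns p = 1 with a
degeneracy flag.

## Signatures and deconvolution

A gene-set score is the mean of per-gene z-scores over the set (so a cell
at the global mean of every set gene scores 0, and the score ignores genes
outside the set). Deconvolution is a single-pass variance-weighted NNLS
onto the signature columns over shared genes (weights = inverse per-gene
variance across reference columns, floor-clamped at 1e-6), weights
normalized to sum 1; this is a deterministic stand-in for iterative
subject-weighted deconvolution schemes and recovers noiseless mixtures
exactly. Tumor grouping standardizes the intestinal/EMT/EmyoT scores and
takes the argmax, with the EmyoT call additionally requiring the EmyoT
score to beat the EMT score (the class is defined as myofibroblast-high,
EMT-low); exact ties break EmyoT > EMT > intestinal and are flagged.
Pathway enrichment is the one-sided hypergeometric tail with a BH column.
The "NOS" companion to the NANOG/OCT4/SOX2 target sets is ambiguous in the
literature naming and is treated as a fourth configurable target set rather
than guessed; bulk stemness is the same z-score gene-set score applied to
a stemness set.

## Bulk cohorts and survival

Cohorts are merged by gene intersection, quantile-normalized within batch
(rank–mean), then each gene is standardized per batch and rescaled to the
pooled mean/sd — a shrinkage-free batch adjustment chosen because no
specific method is mandated; it is swappable. Survival uses lifelines: Cox
partial likelihood with Efron ties (appropriate with month-resolution
ties), Kaplan–Meier with Greenwood bands, multivariate log-rank. Five-year
analyses apply administrative censoring at 60 months (configurable).
Score association reports Pearson R with p plus a median-split two-sample
t test.

## IHC tiles

Images are assumed pre-aligned. The grid is n_cols × n_rows axis-aligned
integer-pixel tiles (reference 45 × 34 = 1530; orientation configurable,
the count is unaffected), remainder pixels absorbed by the last row and
column. A tile is positive when ≥ `positive_fraction` (default 0.1) of its
pixels exceed the intensity threshold (per-channel Otsu by default; a
constant image cannot be thresholded and returns all-negative with a
warning). Co-localization is the tile-set intersection; positivity is
monotone in the threshold and double-positives are subsets of each
single-positive set by construction.

## Synthetic data: what it emulates, and what it does not

Counts are negative-binomial via gamma–Poisson with a shared overdispersion
(default θ = 2, so var = μ + μ²/2) and log-normal library size (σ = 0.25).
Each cell type's program is a shared log-normal baseline (mean 2 per gene)
plus +8 on its markers and log-normal differential-expression factors
(σ = 1.3) on a random 10% of background genes — major lineages in real
tissue differ in hundreds of genes, and this is what makes them as
separable as real cell types are; mitochondrial/hemoglobin genes are kept
near zero so clean cells pass the contamination rule. The lineage is
piecewise-linear interpolation between anchor programs at a latent time in
[0, 1]; the planted "stage" is the equal-width latent-time phase (one per
anchor). QC failures are crafted per rule (e.g. 50-UMI droplets, 30,000-UMI
multiplets, 50% mitochondrial cells, constant-count cells, 92%-zero cells)
and the recorded truth is the exact rule evaluation on the generated
counts. CNV blocks multiply contiguous genomic gene means in carrier types;
variant carriers draw binomial alt reads at a configured VAF over Poisson
depth. Bulk samples are Dirichlet-jittered convex mixtures of reference
profiles with per-batch location/scale shifts and exponential survival with
independent exponential censoring tuned to the requested censoring
fraction. Stain channels are Gaussian-noise backgrounds with planted
rectangles; tile truth is computed from exact geometry.

Not modeled: ambient RNA, doublets, UMI collisions, sequencing error,
batch chemistry effects in the single-cell data, non-proportional hazards,
competing risks, and stain bleed-through. Passing tests therefore
demonstrate algorithmic correctness and recovery under idealized noise, not
robustness to those real-data artifacts.

## Problem sizes and determinism

The bundled demo and test sizes — ~1,000 genes, 25–160 cells per type,
600-cell lineages, 2,000 samples per survival arm, 450×340-pixel images —
were chosen as the smallest scales at which each statistical property is
comfortably measurable (e.g. the Cox sampling sd of log HR at n = 2000 is
~0.045, well inside the ±10% recovery band). All generators and all
stochastic steps (PCA/k-means/Louvain/ICA) are seeded; the clustering seed
default 12345 follows the convention of fixing one seed for every
dimensionality-reduction step. Identical (config, seed) reproduces
byte-identical outputs.

## Known limitations

* The CNV scorer is a relative-dosage method: it cannot call integer copy
  number, and focal events smaller than the smoothing window are damped.
* The progression-state split assumes pseudotime quantiles are meaningful
  across branches; heavily imbalanced branch sizes can place a boundary
  inside a branch.
* The deconvolution weights use variance across reference columns (not
  cross-subject variance), which slightly down-weights the most
  discriminative genes in noisy data; exact on noiseless mixtures.
* The EmyoT group call depends on score standardization across the cell
  population analyzed; it is a relative, not absolute, classification.
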