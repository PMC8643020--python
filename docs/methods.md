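# Methods

This note records the modeling choices behind each pipeline stage, the
defaults and their rationale, what the synthetic generator does and does not
emulate, and the numerical conventions that make runs reproducible.

## Preprocessing

Cell QC fits a normal distribution to per-cell detected-gene counts (sample
mean and SD) and removes cells with a one-sided lower-tail
Benjamini–Hochberg q < 0.05.  Only cells below the fitted mean can be
removed; if all counts are equal (SD = 0) nothing is removed and a warning
is logged.  The normal fit is a deliberate simplification: detected-gene
counts are sums of many weakly dependent indicators and are close to normal
for realistic gene numbers, and the test only needs the lower tail.  Note a
caveat: with very few cells a single extreme outlier inflates the fitted SD
and can escape the threshold; the test suite documents this regime.

The gene filter keeps genes detected in ≥ 3 cells whose mean within-cell
expression *share* (value divided by the cell's total) exceeds 10⁻⁵ — the
threshold only makes sense on a relative scale.  Cells with zero totals
contribute a share of 0 and trigger a warning.

Feature selection uses a Michaelis–Menten dropout model: the global
constant K is fitted by least squares on (S_g, D_g) over genes, with the
optimization over log K on [e⁻¹⁰, e¹⁵] to keep the fit positive and
well-conditioned.  Each gene's zero count is then tested against
Binomial(n_cells, D(S_g)) on the right tail; BH q < 0.01 selects features.
This reproduces the published model class of dropout-based feature
selection without depending on its implementation.  The log transform uses
base 2 with offset exactly 1, consistent with the log₂ fold-change
thresholds downstream.

Order of operations per sample: split → cell QC → gene filter → feature
selection (on pre-log values) → log transform.

## Consensus genes

PCA runs on per-gene z-scored data (zero-variance genes dropped with a
warning); component signs are fixed so each component's largest-magnitude
loading is positive, making embeddings deterministic.  The number of
components is min(first m with cumulative variance > 90 %, first i with
ratio gap < 0.1 %), floored at 2 because nearest-neighbor search in one
dimension is unstable.

The SNN graph includes each cell in its own neighbor set (standard
convention) plus its k = 20 nearest neighbors by Euclidean distance, ties
broken by lexicographic cell id; edges require Jaccard ≥ 1/15 (a common
prune default; only k is prescribed by the framework).  Louvain modularity
clustering (igraph multilevel, resolution 1.0) runs with an explicitly
seeded RNG.

Differential expression is a two-sample Welch t-test on log₂ values with
log₂FC = mean(in) − mean(out); an optional `moderate=True` flag shrinks
per-gene variances halfway toward their mean as a light empirical-Bayes
stand-in for a moderated linear-model fit.  Raw p-values are thresholded
(|log₂FC| > 1, p < 0.05) without multiplicity adjustment, matching the
stated screening rule; the fold-change gate keeps the null false-positive
rate far below the nominal level.  Consensus genes need support in ≥ 2
samples.

## Specific regulatory network

Imputation replaces zeros by Ê᎐ᵢⱼ = ḡᵢ·cⱼ/c̄ with the proportionality
constant fixed to 1, preserving each gene's mean scale; nonzero values are
untouched.  Edge similarity is computed on the imputed log matrix over all
cells pooled across samples; distances are min-max normalized across the
restricted pair set and similarity = 1 − normalized distance, cutoff 0.6.
Because of the min-max step the similarity of one pair depends on the full
pair set — the cutoff is a relative, not absolute, criterion.  TF–TF pairs
are not constrained to consensus membership by default (only targets are);
`constrain_tf_tf=True` selects the stricter reading.  The final network is
exactly the union of edges participating in at least one feed-forward
loop; duplicate pairs appearing as both TF–TF and TF–gene resolve to TF–TF.

## Cell types

RMM scores follow the bin-matched control scheme: genes are ranked by mean
expression into 25 equal-size bins and 100 control genes per module gene
are sampled from the module gene's bin (with replacement when the bin is
smaller), the score being mean(module) − mean(controls) per cell.  Binning
and sampling operate in canonical (lexicographic) gene order so scores are
invariant to matrix row order and fully determined by the seed.  Scores are
computed on the pooled log-normalized (non-imputed) matrix; the imputed
layer is used for edge similarity only.

Canopy clustering visits candidates in row order; T1 admits members, T2
retires candidates.  The (T1, T2) grid is derived from pairwise-distance
quantiles: T1 ∈ {q50, q60, q70, q80, q90} × T2 ∈ {T1/2, 3T1/4}.  The grid
is wider than the minimal three-point version because a tight T2 (half a
median-scale T1) oversegments whenever within-cluster spread approaches
half the between-cluster distance — on separable data that produced dozens
of canopies while the CH-optimal k was available one grid step away.
k-means is Lloyd's algorithm initialized solely with the canopy centroids
(no k-means++ restarts — providing centers is canopy's purpose), max 300
iterations, tol 10⁻⁴.  The CH index selects the winner; exact ties prefer
smaller k (parsimony), then grid order.

ROTS marker detection uses the statistic family d = |Δmean|/(α₁ + α₂·s)
with s the pooled SE, α₁ ∈ {0, 0.25, …, 3}, α₂ ∈ {0.01, 0.1, 0.25, 0.5, 1},
and geometric top-list sizes up to min(1000, genes/2).  Reproducibility R
is the mean top-k overlap over 100 within-group bootstrap pairs; the null
R₀ comes from 5 label permutations with 20 bootstrap pairs each, and the
(α₁, α₂) maximizing Z = (R − R̄₀)/sd(R₀) over k wins.  Per-gene significance
uses a pooled permutation null (200 permutations of the selected statistic)
with a +1 pseudo-count and BH adjustment.  Zero-variance genes fall back to
the α₁ offset; fully degenerate genes score 0.  The bootstrap count (100)
is reduced from the customary 500–1000 to keep the full pipeline in
minutes; the calibration tests show the nominal FDR level is held.

## Biomarkers and survival

Bulk preprocessing drops genes below 1 in more than half the samples, then
z-scores per gene (zero-variance genes dropped).  The tumor eigenvector is
the first principal component of the disease-gene submatrix with samples as
observations, the unit-norm loading vector sign-fixed to positive sum; PC1
is computed on the z-scored layer, consistent with the stated bulk
normalization.  Candidates are ranked by |Pearson r| with the eigenvector,
descending, ties broken lexicographically; constant rows get score 0 with a
warning.  The Kaplan–Meier split sends expression strictly above the median
to the high group and ties to the low group (deterministic and documented);
the split uses the same z-scored layer as the ranking.  A two-sided
log-rank p accompanies each curve pair as a machine-readable comparison,
and the reported direction ("high-worse"/"low-worse") compares the two
step functions at the last event time both curves reach.

## Synthetic data generator

The generator emulates the study design: 6 samples × ~200 cells, 1500
genes, 4 planted cell types with 40 markers each, per-sample batch effects
(gene-wise 2^N(0, 0.2) multipliers), and Michaelis–Menten dropout with
K = 5.  For each gene a target observed mean S is drawn log-normally;
dropout is Bernoulli(K/(K+S)) and nonzero counts are negative binomial
(size 10) with mean K + S, so the observed mean stays S and the emitted
dropout rates sit on the curve at the known K.  Markers are drawn from a
well-expressed band (an undetectable marker is not a marker), gain
`type_effect` = 2 log₂ units of mean in their own type, and show 0.25 extra
dropout outside it — silent genes have excess zeros, which is exactly the
signal dropout-based feature selection keys on, so the planted markers are
simultaneously the features, the DE genes and the consensus set.  Three
spiked low-complexity cells per sample (95 % of genes zeroed) exercise the
cell QC.

Planted feed-forward loops use same-type marker TFs and targets matched on
base expression, so the member profiles are genuinely co-expressed and
survive the 0.6 similarity cutoff; decoy edges connect markers of different
types (anti-correlated) and anchor the upper end of the distance range.
Bulk rows share one latent factor: disease-gene rows load at |r| = 0.9,
planted biomarker rows at ±0.85, all other rows are independent noise on a
base of Uniform(5, 50) — the linear construction makes the population
|PCC| equal the target by design.  Survival times are exponential with
hazard × 2.5 for samples with an above-median latent factor, censored
administratively at Uniform(24, 80) months, so positively loading
biomarkers are "high-worse" by construction.

What the generator does **not** emulate: empirical library-size
distributions, gene–gene correlation beyond the type programs and the
single bulk factor, realistic marker overlap between types, ambient RNA or
doublets, or the survival-time distribution of a real cohort.  Passing
tests therefore demonstrate that each stage recovers the structure it is
designed to detect under its own model assumptions — not performance on
any particular real dataset.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; the pipeline fans a single
global seed out to per-stage seeds via a seed sequence, so stage resumption
from checkpoints reproduces a fresh run byte for byte.  Default problem
sizes (1200 cells, 1500 genes, 100 ROTS bootstraps, 200 permutations) were
chosen so the complete synthetic pipeline finishes in well under a minute
on one CPU and the full test suite in a few minutes.

## Known limitations

Gene identifiers match exactly (case-sensitive); no alias resolution.  The
min-max similarity makes edge retention depend on the composition of the
candidate pair set.  CH-based model selection can oversplit when batch
structure survives the control-gene subtraction — on some generator seeds
the pipeline reports 5–6 clusters for 4 planted types (adjusted Rand index
≈ 0.8–0.9), splitting one type along sample lines, which mirrors how batch
effects behave in real multi-sample data.  The normal QC fit is unreliable
below ~10 cells.  Enrichment analysis, cross-sample integration, copy-number
calling and Cox modeling are out of scope.
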