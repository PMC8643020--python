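# scregmark

Tumor cell-type identification and gene-biomarker ranking from multi-sample
single-cell RNA-seq data combined with transcription-factor regulation
pairs, with bulk-expression survival validation.

Tumor malignant cells cluster by patient rather than by biology: batch and
inter-individual effects dominate any direct pooled clustering.  This
package implements a four-step framework that works around that problem.
It is a library first — the importable API plus the short scripts in
`examples/` are the main interface — with a thin `scregmark` command for
running the assembled pipeline from a shell.

## Method

**Step 1 — per-sample preprocessing.** The expression matrix is split by
sample.  Per-cell detected-gene counts are fitted by a normal distribution
and cells in the significant lower tail (BH FDR < 0.05) are removed.  Genes
must be detected in ≥ 3 cells with mean within-cell expression share
> 10⁻⁵.  Feature genes are selected by a Michaelis–Menten dropout model,

    D(S) = 1 − S / (K + S),

fitting a global constant *K* over (mean expression *S*, dropout rate *D*)
and keeping genes whose observed dropout significantly exceeds the curve
(binomial right tail, BH FDR < 0.01) — the signature of on/off biological
expression.  Values are then log₂(x+1)-transformed.

**Step 2 — consensus genes.** Within each sample, cells are embedded by PCA
(components chosen by a 90 % cumulative-variance rule with a 0.1 %
consecutive-gap cutoff), joined in a shared-nearest-neighbor graph (k = 20,
edges weighted by the Jaccard similarity of neighbor sets) and partitioned
by Louvain modularity clustering.  One-vs-rest differential expression per
cluster (Welch t-test, |log₂FC| > 1, p < 0.05) gives a per-sample DEG union;
genes differential in ≥ 2 samples are the **consensus genes**.

**Step 3 — specific regulatory network and cell types.** TF→target pairs
are restricted to consensus-gene targets.  Dropout zeros are imputed as
Ê₍ᵢⱼ₎ = ḡᵢ · cⱼ / c̄ (gene mean scaled by relative cell complexity); each
pair is scored by 1 minus the min-max-normalized Euclidean distance between
its two expression rows, and pairs with similarity < 0.6 are dropped.  The
network is reduced to its **feed-forward loops** — triples where TF *M*
regulates TF *N* and both regulate a target *G*.  Every TF then defines a
**regulation meta module** (RMM): itself plus its direct targets.  Per-cell
RMM activity is the mean module expression minus the mean of
expression-bin-matched control genes.  Cells are clustered in RMM-score
space by canopy-initialized k-means, with the Calinski–Harabasz index

    CH = [B/(k−1)] / [W/(n−k)]

selecting the best canopy thresholds.  Per-type markers come from the
reproducibility-optimized test statistic (ROTS) family
d = |x̄₁ − x̄₂| / (α₁ + α₂·s), with (α₁, α₂) chosen to maximize bootstrap
top-list reproducibility against a permutation null.

**Step 4 — biomarker ranking and survival.** The **tumor eigenvector**
(TEV) is the first principal component of the known-disease-gene rows of a
z-scored bulk matrix.  Candidate genes (the per-type markers) are ranked by
|Pearson r| with the TEV; the top 20 are checked by median-expression-split
Kaplan–Meier curves with a log-rank test.

A fully synthetic data generator (`scregmark.synthetic`) emits all four
inputs with planted cell types, consensus genes, feed-forward loops and
biomarkers, so the entire pipeline is testable without any downloads.

## Worked example

`python examples/06_full_pipeline.py` generates the default synthetic study
(6 samples × 200 cells, 1500 genes, 4 planted cell types) and runs the full
pipeline:

```
cells kept: 1182; consensus genes: 159
specific network: 28 TFs, 15 targets, 51 edges, 20 FFLs
cell types: 4 (planted: 4)
clustering ARI: 0.993
top-20 biomarker recall: 15/15
result tables written to scratch/example_run
```

Reading: of 1200 simulated cells, 18 low-complexity cells were removed by
QC; 159 consensus genes were found (the generator planted 160 markers); the
similarity-filtered network retains 20 feed-forward loops; hybrid
clustering recovers the 4 planted types nearly perfectly (adjusted Rand
index 0.993); and all 15 planted bulk biomarkers appear in the top-20
|PCC| ranking.  Each `examples/0*.py` script exercises one stage the same
way and prints what its numbers mean.

The pipeline can also be driven from a YAML config:

```sh
scregmark synth --out fixtures --seed 7     # emit input files + truth
scregmark run --config config.yaml --seed 7 --out results
```

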