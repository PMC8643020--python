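"""Biomarker ranking against the tumor eigenvector, with KM validation.

The tumor eigenvector (TEV) is the first principal component of the known
disease genes' rows of a z-scored bulk matrix.  Candidates are ranked by
|Pearson r| with the TEV; the top genes are checked by median-expression
Kaplan-Meier splits with a log-rank test.
"""

from scregmark import biomarker as bm
from scregmark.datatypes import GeneSet
from scregmark.synthetic import generate_bulk_survival, generate_single_cell

_, sc_truth = generate_single_cell(
    n_samples=1, cells_per_sample=50, n_genes=600, seed=4
)
genes = [f"G{i:04d}" for i in range(600)]
bulk, kggs, survival, truth = generate_bulk_survival(sc_truth, genes, seed=4)

z = bm.preprocess_bulk(bulk)
print(f"bulk: {len(z.gene_ids)} genes x {z.n_samples} samples after filtering")

tev = bm.compute_tev(z, kggs)
print(f"TEV from {tev.n_genes_used}/{tev.n_genes_requested} disease genes; "
      f"PC1 explains {tev.explained_ratio:.1%} of their variance")

candidates = GeneSet("candidates", sc_truth.consensus_genes)
ranking = bm.rank_candidates(z, candidates, tev, top_n=20)
planted = set(truth.biomarker_direction)
top = set(ranking.head(20)["gene"])
print(f"top-20 |PCC| ranking captures {len(top & planted)}/{len(planted)} "
      f"planted biomarkers; leaders:")
print(ranking.head(5).to_string(index=False))

gene = ranking["gene"].iloc[0]
hi, lo, p, direction = bm.median_split_km(z, gene, survival)
print(f"{gene}: log-rank p = {p:.2e}, direction = {direction} "
      f"(planted: {truth.biomarker_direction.get(gene, 'n/a')})")
# A score near the planted |PCC| of 0.85 plus a concordant KM direction is
# the full evidence chain the pipeline reports for each candidate.
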