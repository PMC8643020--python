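"""Cross-sample consensus genes from per-sample cluster markers.

For each sample: PCA embedding, shared-nearest-neighbor graph, Louvain
clustering, and one-vs-rest differential expression.  Genes differential in
at least two samples are the consensus genes.
"""

from scregmark import consensus as cs
from scregmark import preprocess as pp
from scregmark.synthetic import generate_single_cell

expr, truth = generate_single_cell(
    n_samples=3, cells_per_sample=250, n_genes=600, seed=1
)

deg_by_sample = {}
for sample, sub in pp.split_by_sample(expr).items():
    sub, _ = pp.qc_filter_cells(sub)
    sub = pp.filter_genes(sub)
    feats, _ = pp.select_features_dropout(sub)
    mat = pp.log_normalize(feats)
    n_pcs = cs.select_num_pcs(cs.explained_variance_ratios(mat))
    emb = cs.embed_pca(mat, n_pcs)
    graph = cs.build_snn_graph(emb, mat.cell_ids, k=20)
    labels = cs.cluster_louvain(graph, seed=0)
    degs = cs.de_one_vs_rest(mat, labels, lfc=1.0, p_threshold=0.05)
    deg_by_sample[sample] = {r.gene for r in degs}
    print(f"{sample}: {n_pcs} PCs, {labels.nunique()} clusters, "
          f"{len(deg_by_sample[sample])} DEGs")

result = cs.consensus_genes(deg_by_sample, min_samples=2)
planted = truth.consensus_genes
hits = result.genes.genes & planted
print(f"consensus genes: {len(result.genes)} "
      f"(recall {len(hits)/len(planted):.2f} of {len(planted)} planted markers)")
print("pairwise DEG overlap proportions:")
print(result.overlap.round(2))
# High off-diagonal overlap mirrors shared biology across samples; the
# consensus set is the genes driving it.
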