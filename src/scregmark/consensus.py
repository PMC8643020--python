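"""Per-sample cell clustering and cross-sample consensus-gene screening.

Within each sample: genes are z-scored, cells embedded by PCA (the number of
components chosen from the explained-variance profile), a shared-nearest-
neighbor (SNN) graph is built with Jaccard-weighted edges, and Louvain
community detection gives an initial partition.  One-vs-rest differential
expression per cluster (Welch t-test on log2 values, |log2FC| > 1 and
p < 0.05) yields a per-sample DEG union; genes differential in at least two
samples are the tumor consensus genes.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .datatypes import ExpressionMatrix, GeneSet, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "select_num_pcs",
    "embed_pca",
    "build_snn_graph",
    "cluster_louvain",
    "de_one_vs_rest",
    "consensus_genes",
    "overlap_matrix",
    "CellGraph",
    "DEGRecord",
    "ConsensusResult",
]


@dataclass
class CellGraph:
    """Undirected SNN graph over cells; edge weight = Jaccard of kNN sets."""

    cell_ids: list[str]
    edges: list[tuple[str, str, float]]
    k: int

    def __post_init__(self) -> None:
        for a, b, w in self.edges:
            if a == b:
                raise ValidationError("self-edge in cell graph")
            if not (0 < w <= 1):
                raise ValidationError(f"edge weight {w} outside (0, 1]")


@dataclass(frozen=True)
class DEGRecord:
    sample_id: str
    cluster_id: int
    gene: str
    log2fc: float
    p: float


@dataclass
class ConsensusResult:
    genes: GeneSet
    support: dict[str, int]
    overlap: pd.DataFrame


def select_num_pcs(explained_ratios: "list[float] | np.ndarray") -> int:
    """Number of PCs from two rules: cumulative variance > 90 %, or the first
    consecutive-ratio gap below 0.1 %; the smaller of the two, floored at 2."""
    r = np.asarray(explained_ratios, dtype=float)
    if r.size < 2:
        raise ValidationError("need at least 2 explained-variance ratios")
    cum = np.cumsum(r)
    above = np.nonzero(cum > 0.90)[0]
    n1 = int(above[0]) + 1 if above.size else r.size
    gaps = r[:-1] - r[1:]
    small = np.nonzero(gaps < 0.001)[0]
    n2 = int(small[0]) + 1 if small.size else r.size
    return max(2, min(n1, n2))


def zscore_genes(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene z-score across cells; returns (z, keep_mask) with
    zero-variance genes dropped."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance genes before PCA", int((~keep).sum()))
    z = (values[keep] - mu[keep]) / sd[keep]
    return z, keep


def embed_pca(expr: ExpressionMatrix, n_pcs: int) -> np.ndarray:
    """Cells x n_pcs PCA scores of the z-scored gene matrix.

    Components are sign-fixed so each component's largest-magnitude loading
    is positive, making the embedding deterministic.
    """
    z, _ = zscore_genes(expr.values)
    n_genes, n_cells = z.shape
    if n_pcs >= min(n_genes, n_cells):
        raise ValidationError(f"n_pcs={n_pcs} >= min(genes, cells)")
    x = z.T  # cells as observations
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(n_pcs):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    return u[:, :n_pcs] * s[:n_pcs]


def explained_variance_ratios(expr: ExpressionMatrix) -> np.ndarray:
    z, _ = zscore_genes(expr.values)
    x = z.T - z.T.mean(axis=0, keepdims=True)
    s = np.linalg.svd(x, compute_uv=False)
    var = s**2
    return var / var.sum()


def _knn_sets(embedding: np.ndarray, cell_ids: list[str], k: int) -> list[set[int]]:
    n = embedding.shape[0]
    d2 = cdist(embedding, embedding, metric="sqeuclidean")
    id_rank = np.argsort(np.argsort(cell_ids))  # lexicographic tie-break
    sets: list[set[int]] = []
    for i in range(n):
        order = np.lexsort((id_rank, d2[i]))
        nn = [j for j in order if j != i][:k]
        sets.append({i, *nn})
    return sets


def build_snn_graph(
    embedding: np.ndarray,
    cell_ids: list[str],
    k: int = 20,
    prune: float = 1.0 / 15.0,
) -> CellGraph:
    """Shared-nearest-neighbor graph: each cell's neighbor set is itself plus
    its k nearest (Euclidean, ties by cell-id order); an edge joins two cells
    whose neighbor-set Jaccard similarity reaches ``prune``."""
    n = embedding.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than #cells={n}")
    sets = _knn_sets(embedding, cell_ids, k)
    member = np.zeros((n, n), dtype=np.int32)
    for i, s in enumerate(sets):
        member[i, list(s)] = 1
    inter = member @ member.T
    sizes = member.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    jac = inter / union
    edges: list[tuple[str, str, float]] = []
    for i in range(n):
        for j in range(i + 1, n):
            if jac[i, j] >= prune and jac[i, j] > 0:
                edges.append((cell_ids[i], cell_ids[j], float(jac[i, j])))
    return CellGraph(cell_ids=list(cell_ids), edges=edges, k=k)


def cluster_louvain(graph: CellGraph, resolution: float = 1.0, seed: int = 0) -> pd.Series:
    """Louvain modularity clustering of the Jaccard-weighted SNN graph.

    Deterministic for a given seed; isolated cells become their own clusters.
    """
    if not graph.cell_ids:
        raise ValidationError("empty cell graph")
    idx = {c: i for i, c in enumerate(graph.cell_ids)}
    g = ig.Graph(
        n=len(graph.cell_ids),
        edges=[(idx[a], idx[b]) for a, b, _ in graph.edges],
    )
    g.es["weight"] = [w for _, _, w in graph.edges]
    ig.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights="weight" if graph.edges else None, resolution=resolution)
    ig.set_random_number_generator(random)
    return pd.Series(part.membership, index=graph.cell_ids, name="cluster")


def de_one_vs_rest(
    expr: ExpressionMatrix,
    labels: pd.Series,
    lfc: float = 1.0,
    p_threshold: float = 0.05,
    min_cells: int = 3,
    moderate: bool = False,
) -> list[DEGRecord]:
    """One-vs-rest differential expression per cluster.

    log2FC is the in-cluster minus out-of-cluster mean (data already log2);
    p-values come from a two-sample Welch t-test, optionally with a simple
    empirical-Bayes-style shrinkage of per-gene variances toward their mean.
    Records satisfying ``|log2FC| > lfc`` and ``p < p_threshold`` (raw p) are
    returned.  Clusters with fewer than ``min_cells`` cells are skipped.
    """
    labels = labels.reindex(expr.cell_ids)
    clusters = sorted(labels.dropna().unique())
    if len(clusters) < 2:
        return []
    sample = expr.cell_sample[expr.cell_ids[0]]
    records: list[DEGRecord] = []
    lab = labels.to_numpy()
    for cl in clusters:
        in_mask = lab == cl
        n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
        if n_in < min_cells or n_out < min_cells:
            logger.warning("cluster %s too small (%d cells); skipped", cl, n_in)
            continue
        a = expr.values[:, in_mask]
        b = expr.values[:, ~in_mask]
        log2fc = a.mean(axis=1) - b.mean(axis=1)
        va = a.var(axis=1, ddof=1)
        vb = b.var(axis=1, ddof=1)
        if moderate:
            # shrink per-gene variances halfway toward the grand mean
            va = 0.5 * va + 0.5 * va.mean()
            vb = 0.5 * vb + 0.5 * vb.mean()
        se2 = va / n_in + vb / n_out
        with np.errstate(divide="ignore", invalid="ignore"):
            t = log2fc / np.sqrt(se2)
            df = se2**2 / (
                (va / n_in) ** 2 / (n_in - 1) + (vb / n_out) ** 2 / (n_out - 1)
            )
        pvals = np.where(
            np.isfinite(t), 2 * stats.t.sf(np.abs(t), np.where(np.isfinite(df), df, 1)), 1.0
        )
        hits = (np.abs(log2fc) > lfc) & (pvals < p_threshold)
        for g_i in np.nonzero(hits)[0]:
            records.append(
                DEGRecord(
                    sample_id=sample,
                    cluster_id=int(cl),
                    gene=expr.gene_ids[g_i],
                    log2fc=float(log2fc[g_i]),
                    p=float(pvals[g_i]),
                )
            )
    return records


def consensus_genes(
    deg_by_sample: dict[str, set[str]], min_samples: int = 2
) -> ConsensusResult:
    """Genes differentially expressed in at least ``min_samples`` samples."""
    if min_samples > len(deg_by_sample):
        raise ValidationError("min_samples exceeds number of samples")
    support: dict[str, int] = {}
    for genes in deg_by_sample.values():
        for g in genes:
            support[g] = support.get(g, 0) + 1
    kept = {g for g, n in support.items() if n >= min_samples}
    if not kept:
        raise ValidationError("no gene reaches the consensus support threshold")
    return ConsensusResult(
        genes=GeneSet(name="consensus", genes=kept),
        support={g: support[g] for g in sorted(kept)},
        overlap=overlap_matrix(deg_by_sample),
    )


def overlap_matrix(deg_by_sample: dict[str, set[str]]) -> pd.DataFrame:
    """Pairwise DEG overlap proportions: |DEG_s ∩ DEG_t| / |DEG_s|."""
    samples = list(deg_by_sample)
    mat = pd.DataFrame(0.0, index=samples, columns=samples)
    for s in samples:
        ds = deg_by_sample[s]
        if not ds:
            logger.warning("sample %s has no DEGs; overlap defined as 0", s)
        for t in samples:
            mat.loc[s, t] = len(ds & deg_by_sample[t]) / len(ds) if ds else 0.0
    return mat
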