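"""Cell-type identification from regulation meta modules (RMMs).

Each TF in the specific regulatory network defines an RMM: the TF plus every
gene/TF it directly regulates.  Per-cell RMM activities are computed with a
bin-matched control score (mean module expression minus mean expression of
control genes drawn from the same mean-expression bins), giving a cells x
RMMs feature matrix.  Cells are clustered by canopy-initialized k-means, the
Calinski-Harabasz (CH) index selecting the best (T1, T2) grid point, and
per-type gene biomarkers are called with a reproducibility-optimized test
statistic (ROTS): a modified t-statistic ``|dmean| / (a1 + a2 * s)`` whose
(a1, a2) are chosen to maximize bootstrap top-list reproducibility relative
to a permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, ValidationError
from .regnet import RegulatoryNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "extract_rmms",
    "score_modules",
    "canopy_init",
    "calinski_harabasz",
    "hybrid_cluster",
    "rots_biomarkers",
    "rots_statistic",
    "RMM",
    "CellTypeAssignment",
    "ROTSResult",
]


@dataclass
class RMM:
    core_tf: str
    members: set[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"RMM {self.core_tf} has no members")


@dataclass
class CellTypeAssignment:
    labels: pd.Series  # index cell_id -> type id (int)
    k: int
    centers: np.ndarray
    ch: float
    t1: float
    t2: float


@dataclass
class ROTSResult:
    table: pd.DataFrame  # index gene; columns d, p, q
    alpha1: float
    alpha2: float
    z: float  # reproducibility Z of the selected statistic


def extract_rmms(network: RegulatoryNetwork, include_core: bool = True) -> list[RMM]:
    """One RMM per TF with outgoing edges: its out-neighborhood (plus itself)."""
    if not len(network.edges):
        raise ValidationError("empty regulatory network")
    rmms = []
    for tf in sorted(network.tf_nodes):
        members = network.out_neighbors(tf)
        if not members:
            continue
        if include_core:
            members = members | {tf}
        rmms.append(RMM(core_tf=tf, members=members))
    return rmms


def score_modules(
    expr: ExpressionMatrix,
    rmms: list[RMM],
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell module activity with expression-bin-matched controls.

    Genes are ranked by mean expression and cut into ``n_bins`` equal-size
    bins; for each module gene ``n_ctrl`` control genes are sampled from its
    bin (with replacement when the bin is smaller).  The score of a cell for
    an RMM is the mean expression of module genes minus the mean over the
    pooled control genes, so a uniform additive shift of the matrix leaves
    scores unchanged.
    """
    rng = np.random.default_rng(seed)
    # canonical (lexicographic) gene order makes binning and control
    # sampling independent of the matrix row order
    canon = sorted(range(expr.n_genes), key=lambda i: expr.gene_ids[i])
    row_of_rank = np.array(canon)
    means = expr.values.mean(axis=1)[row_of_rank]
    ids_ranked = [expr.gene_ids[i] for i in canon]
    order = np.lexsort((ids_ranked, means))
    bins = np.empty(expr.n_genes, dtype=int)
    bins[order] = (np.arange(expr.n_genes) * n_bins) // expr.n_genes
    rank_of_gene = {g: r for r, g in enumerate(ids_ranked)}
    bin_members = [np.nonzero(bins == b)[0] for b in range(n_bins)]
    cols: dict[str, np.ndarray] = {}
    for rmm in rmms:
        present = sorted(m for m in rmm.members if m in rank_of_gene)
        missing = rmm.members - set(present)
        if missing:
            logger.warning(
                "RMM %s: %d members missing from matrix", rmm.core_tf, len(missing)
            )
        if not present:
            logger.warning("RMM %s fully absent; dropped", rmm.core_tf)
            continue
        mod_ranks = np.array([rank_of_gene[m] for m in present])
        ctrl_ranks = []
        for r in mod_ranks:
            pool = bin_members[bins[r]]
            replace = len(pool) < n_ctrl
            ctrl_ranks.append(rng.choice(pool, size=n_ctrl, replace=replace))
        mod_rows = row_of_rank[mod_ranks]
        ctrl_rows = row_of_rank[np.concatenate(ctrl_ranks)]
        cols[rmm.core_tf] = (
            expr.values[mod_rows].mean(axis=0) - expr.values[ctrl_rows].mean(axis=0)
        )
    if not cols:
        raise ValidationError("no RMM could be scored")
    return pd.DataFrame(cols, index=expr.cell_ids)


def canopy_init(points: np.ndarray, t1: float, t2: float) -> tuple[int, np.ndarray]:
    """Classic single-pass canopy clustering.

    Candidates are visited in row order; the first remaining candidate seeds
    a canopy, every point within ``t1`` joins it, and points within ``t2``
    leave the candidate pool.  Returns the number of canopies and their
    member centroids as k-means starting centers.
    """
    if t1 <= t2:
        raise ValidationError("canopy requires T1 > T2 > 0")
    n = points.shape[0]
    remaining = list(range(n))
    centers = []
    while remaining:
        seed_i = remaining[0]
        d = np.linalg.norm(points - points[seed_i], axis=1)
        members = np.nonzero(d <= t1)[0]
        centers.append(points[members].mean(axis=0))
        remaining = [i for i in remaining if d[i] > t2]
    return len(centers), np.vstack(centers)


def calinski_harabasz(points: np.ndarray, labels: np.ndarray) -> float:
    """CH index: between-cluster over within-cluster dispersion, normalized
    by degrees of freedom.  Larger is better; W = 0 returns +inf."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k, n = len(uniq), points.shape[0]
    if k < 2 or n <= k:
        raise ValidationError("CH needs 2 <= k < n")
    mu = points.mean(axis=0)
    between = 0.0
    within = 0.0
    for c in uniq:
        pts = points[labels == c]
        mu_c = pts.mean(axis=0)
        between += len(pts) * float(np.sum((mu_c - mu) ** 2))
        within += float(np.sum((pts - mu_c) ** 2))
    if within == 0:
        logger.warning("zero within-cluster dispersion; CH set to +inf")
        return float("inf")
    return (between / (k - 1)) / (within / (n - k))


def default_t1t2_grid(
    points: np.ndarray, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Default (T1, T2) grid from quantiles of sampled pairwise distances.

    T1 spans the 50th-90th distance percentiles and T2 is 1/2 or 3/4 of T1;
    the wide T2 options matter when within-cluster spread approaches half
    the between-cluster distance, where a tight T2 oversegments.
    """
    n = points.shape[0]
    if n > 600:
        idx = rng.choice(n, size=600, replace=False)
        pts = points[idx]
    else:
        pts = points
    d = cdist(pts, pts)
    vals = d[np.triu_indices_from(d, k=1)]
    t1s = [float(np.quantile(vals, q)) for q in (0.5, 0.6, 0.7, 0.8, 0.9)]
    return [(t1, frac * t1) for t1 in t1s for frac in (0.5, 0.75)]


def hybrid_cluster(
    scores: pd.DataFrame,
    t1t2_grid: "list[tuple[float, float]] | None" = None,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> CellTypeAssignment:
    """Canopy-initialized k-means over a (T1, T2) grid, selected by CH.

    For every grid point, canopy clustering provides k and the initial
    centers for Lloyd's k-means (single initialization); the assignment with
    the largest CH index wins, ties broken by smaller k then grid order.
    """
    points = scores.to_numpy(dtype=float)
    if points.shape[0] < 10:
        raise ValidationError("hybrid_cluster needs >= 10 cells")
    rng = np.random.default_rng(seed)
    if t1t2_grid is None:
        t1t2_grid = default_t1t2_grid(points, rng)
    if not t1t2_grid:
        raise ValidationError("empty T1/T2 grid")
    best: CellTypeAssignment | None = None
    for t1, t2 in t1t2_grid:
        k, centers = canopy_init(points, t1, t2)
        if k < 2 or k >= points.shape[0]:
            continue
        km = KMeans(
            n_clusters=k,
            init=centers,
            n_init=1,
            max_iter=max_iter,
            tol=tol,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(points)
        labels = km.labels_
        if len(np.unique(labels)) < 2:
            continue
        ch = calinski_harabasz(points, labels)
        cand = CellTypeAssignment(
            labels=pd.Series(labels, index=scores.index, name="type"),
            k=int(len(np.unique(labels))),
            centers=km.cluster_centers_,
            ch=ch,
            t1=t1,
            t2=t2,
        )
        if best is None or (cand.ch, -cand.k) > (best.ch, -best.k):
            best = cand
    if best is None:
        raise ValidationError("no grid point produced k >= 2 clusters")
    return best


def rots_statistic(
    a: np.ndarray, b: np.ndarray, alpha1: float, alpha2: float
) -> np.ndarray:
    """ROTS statistic family d = |mean(a) - mean(b)| / (a1 + a2 * s),
    with s the pooled standard error of the mean difference."""
    diff = np.abs(a.mean(axis=1) - b.mean(axis=1))
    s = _pooled_se(a, b)
    return _apply_alpha(diff, s, alpha1, alpha2)


def _apply_alpha(diff: np.ndarray, s: np.ndarray, a1: float, a2: float) -> np.ndarray:
    denom = a1 + a2 * s
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / denom
    # zero-variance genes fall back to the alpha1 offset; fully degenerate
    # (zero denominator, zero difference) genes score 0
    return np.where(denom > 0, d, np.where(diff > 0, np.inf, 0.0))


def _pooled_se(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n1, n2 = a.shape[1], b.shape[1]
    sp2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    return np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))


def _top_overlap(d1: np.ndarray, d2: np.ndarray, k_list: np.ndarray) -> np.ndarray:
    """Proportion of shared genes among the top-k of two rankings, per k."""
    o1 = np.argsort(-d1, kind="stable")
    o2 = np.argsort(-d2, kind="stable")
    n = len(d1)
    rank2 = np.empty(n, dtype=int)
    rank2[o2] = np.arange(n)
    pos_of_o1 = rank2[o1]  # rank in list 2 of the gene at each rank of list 1
    out = np.empty(len(k_list))
    for i, k in enumerate(k_list):
        out[i] = np.count_nonzero(pos_of_o1[:k] < k) / k
    return out


def _default_alpha_grid() -> list[tuple[float, float]]:
    a1s = np.arange(0.0, 3.01, 0.25)
    a2s = [0.01, 0.1, 0.25, 0.5, 1.0]
    return [(float(a1), float(a2)) for a1 in a1s for a2 in a2s]


def rots_biomarkers(
    expr: ExpressionMatrix,
    labels: pd.Series,
    type_id,
    n_bootstrap: int = 100,
    k_grid: "np.ndarray | None" = None,
    alpha_grid: "list[tuple[float, float]] | None" = None,
    n_perm: int = 200,
    seed: int = 0,
) -> ROTSResult:
    """Reproducibility-optimized marker detection for one cell type vs rest.

    For every (a1, a2) on the grid, top-k list reproducibility R is the
    average top-list overlap across ``n_bootstrap`` pairs of within-group
    bootstrap resamples; a null R0 is computed identically on permuted
    labels and the statistic maximizing Z = (R - mean R0) / sd R0 (over the
    k grid) is selected.  Per-gene significance uses a pooled permutation
    null on the selected statistic with BH adjustment.
    """
    labels = labels.reindex(expr.cell_ids)
    in_mask = (labels == type_id).to_numpy()
    n1, n2 = int(in_mask.sum()), int((~in_mask).sum())
    if n1 < 3 or n2 < 3:
        raise ValidationError("both groups need >= 3 cells")
    x = expr.values
    a, b = x[:, in_mask], x[:, ~in_mask]
    n_genes = x.shape[0]
    rng = np.random.default_rng(seed)
    if alpha_grid is None:
        alpha_grid = _default_alpha_grid()
    if k_grid is None:
        kmax = max(2, min(1000, n_genes // 2))
        k_grid = np.unique(
            np.clip(np.round(np.geomspace(5, kmax, num=10)).astype(int), 2, kmax)
        )
    k_grid = np.asarray(k_grid, dtype=int)

    def _pair_stats(mat_a, mat_b, rng_):
        """Bootstrap-pair (diff, se) summaries for both members of the pair."""
        out = []
        for _ in range(2):
            ia = rng_.integers(0, mat_a.shape[1], size=mat_a.shape[1])
            ib = rng_.integers(0, mat_b.shape[1], size=mat_b.shape[1])
            ra, rb = mat_a[:, ia], mat_b[:, ib]
            out.append((np.abs(ra.mean(axis=1) - rb.mean(axis=1)), _pooled_se(ra, rb)))
        return out

    def _reproducibility(mat_a, mat_b, rng_):
        """R(alpha, k) averaged over bootstrap pairs."""
        acc = np.zeros((len(alpha_grid), len(k_grid)))
        for _ in range(n_bootstrap):
            (d1, s1), (d2, s2) = _pair_stats(mat_a, mat_b, rng_)
            for ai, (a1, a2) in enumerate(alpha_grid):
                acc[ai] += _top_overlap(_apply_alpha(d1, s1, a1, a2), _apply_alpha(d2, s2, a1, a2), k_grid)
        return acc / n_bootstrap

    r_obs = _reproducibility(a, b, rng)
    # permutation null for the reproducibility itself (a handful of label
    # permutations, each contributing an R surface)
    null_rs = []
    for _ in range(5):
        perm = rng.permutation(x.shape[1])
        pa, pb = x[:, perm[:n1]], x[:, perm[n1:]]
        rng_null = np.random.default_rng(rng.integers(2**31 - 1))
        acc = np.zeros((len(alpha_grid), len(k_grid)))
        nb = max(10, n_bootstrap // 5)
        for _ in range(nb):
            (d1, s1), (d2, s2) = _pair_stats(pa, pb, rng_null)
            for ai, (a1, a2) in enumerate(alpha_grid):
                acc[ai] += _top_overlap(_apply_alpha(d1, s1, a1, a2), _apply_alpha(d2, s2, a1, a2), k_grid)
        null_rs.append(acc / nb)
    null_arr = np.stack(null_rs)
    r0_mean = null_arr.mean(axis=0)
    r0_sd = null_arr.std(axis=0, ddof=1)
    z = (r_obs - r0_mean) / np.where(r0_sd > 0, r0_sd, np.inf)
    z_per_alpha = z.max(axis=1)
    best_ai = int(np.argmax(z_per_alpha))
    a1, a2 = alpha_grid[best_ai]
    d_obs = rots_statistic(a, b, a1, a2)
    # pooled permutation null for per-gene p-values
    null_pool = []
    for _ in range(n_perm):
        perm = rng.permutation(x.shape[1])
        null_pool.append(rots_statistic(x[:, perm[:n1]], x[:, perm[n1:]], a1, a2))
    null_pool = np.sort(np.concatenate(null_pool))
    n_null = len(null_pool)
    exceed = n_null - np.searchsorted(null_pool, d_obs, side="left")
    p = (1.0 + exceed) / (1.0 + n_null)
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({"d": d_obs, "p": p, "q": q}, index=expr.gene_ids)
    return ROTSResult(table=table, alpha1=a1, alpha2=a2, z=float(z_per_alpha[best_ai]))
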