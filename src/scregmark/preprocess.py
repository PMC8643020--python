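"""Per-sample cleaning, feature selection and normalization of scRNA-seq data.

The cleaning model is deliberately simple: per-cell library complexity
(number of detected genes) is fitted by a normal distribution and cells in
the significant lower tail are removed; genes must be detected in a minimum
number of cells and carry a minimum share of their cells' transcript mass;
technical-noise genes are separated from biological features with a
Michaelis-Menten dropout model (dropout rate falls with mean expression as
``D = 1 - S / (K + S)``), flagging genes whose observed dropout significantly
exceeds the curve.  Expression is finally log2(x+1)-transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "split_by_sample",
    "qc_filter_cells",
    "filter_genes",
    "select_features_dropout",
    "log_normalize",
    "QCReport",
    "FeatureSelection",
]


@dataclass
class QCReport:
    detected_counts: pd.Series      # per-cell number of detected genes
    mu: float
    sigma: float
    pvalues: pd.Series
    qvalues: pd.Series
    removed_cells: list[str]


@dataclass
class FeatureSelection:
    table: pd.DataFrame   # index gene; columns: S, D_obs, D_exp, p, q, selected
    K: float
    fdr: float


def split_by_sample(expr: ExpressionMatrix) -> dict[str, ExpressionMatrix]:
    """Partition cells by their sample label (gene set unchanged)."""
    out: dict[str, ExpressionMatrix] = {}
    for sample in expr.samples:
        cells = [c for c in expr.cell_ids if expr.cell_sample[c] == sample]
        out[sample] = expr.subset_cells(cells)
    return out


def qc_filter_cells(
    expr: ExpressionMatrix, fdr: float = 0.05
) -> tuple[ExpressionMatrix, QCReport]:
    """Remove cells with significantly few detected genes.

    Detected-gene counts are fitted by a normal distribution (sample mean and
    SD); each cell gets a one-sided lower-tail p-value, Benjamini-Hochberg
    adjusted, and cells with ``q < fdr`` are removed.  Only low-complexity
    cells can ever be removed.
    """
    if expr.n_cells < 3:
        raise ValidationError("qc_filter_cells needs at least 3 cells")
    counts = (expr.values > 0).sum(axis=0).astype(float)
    mu = float(counts.mean())
    sigma = float(counts.std(ddof=1))
    if sigma == 0:
        logger.warning("all detected-gene counts identical; no cell removed")
        p = np.ones_like(counts)
    else:
        p = stats.norm.cdf(counts, loc=mu, scale=sigma)
    q = multipletests(p, method="fdr_bh")[1]
    removed_mask = (q < fdr) & (counts < mu)
    removed = [c for c, r in zip(expr.cell_ids, removed_mask) if r]
    report = QCReport(
        detected_counts=pd.Series(counts, index=expr.cell_ids),
        mu=mu,
        sigma=sigma,
        pvalues=pd.Series(p, index=expr.cell_ids),
        qvalues=pd.Series(q, index=expr.cell_ids),
        removed_cells=removed,
    )
    kept = [c for c in expr.cell_ids if c not in set(removed)]
    return expr.subset_cells(kept), report


def filter_genes(
    expr: ExpressionMatrix, min_cells: int = 3, min_mean_norm: float = 1e-5
) -> ExpressionMatrix:
    """Keep genes detected in >= ``min_cells`` cells whose mean within-cell
    expression share exceeds ``min_mean_norm``."""
    totals = expr.values.sum(axis=0)
    if np.any(totals == 0):
        logger.warning("%d cells have zero total counts", int((totals == 0).sum()))
    safe_totals = np.where(totals > 0, totals, 1.0)
    shares = expr.values / safe_totals  # zero-total cells contribute 0
    detected = (expr.values > 0).sum(axis=1)
    mean_share = shares.mean(axis=1)
    keep = (detected >= min_cells) & (mean_share > min_mean_norm)
    return expr.subset_genes([g for g, k in zip(expr.gene_ids, keep) if k])


def _mm_dropout(S: np.ndarray, K: float) -> np.ndarray:
    return 1.0 - S / (K + S)


def fit_michaelis_constant(S: np.ndarray, D_obs: np.ndarray) -> float:
    """Least-squares fit of the global Michaelis constant K over genes."""
    if np.all((D_obs == 0) | (D_obs == 1)):
        raise ValidationError(
            "dropout rates are all 0 or 1; Michaelis-Menten fit needs raw counts"
        )

    def loss(logK: float) -> float:
        return float(np.sum((_mm_dropout(S, np.exp(logK)) - D_obs) ** 2))

    res = optimize.minimize_scalar(loss, bounds=(-10, 15), method="bounded")
    return float(np.exp(res.x))


def select_features_dropout(
    expr: ExpressionMatrix, fdr: float = 0.01
) -> tuple[ExpressionMatrix, FeatureSelection]:
    """Dropout-based feature selection (M3Drop-style).

    A global Michaelis-Menten curve ``D_exp(S) = 1 - S/(K+S)`` is fitted to
    (mean expression, observed dropout rate) by least squares; each gene's
    observed dropout count is then tested against ``Binomial(n_cells,
    D_exp(S_g))`` on the right tail.  Genes with BH-adjusted ``q < fdr``
    (excess dropout relative to their expression level) are the features.
    """
    if expr.n_genes < 10:
        raise ValidationError("select_features_dropout needs >= 10 genes")
    n = expr.n_cells
    S = expr.values.mean(axis=1)
    zeros = (expr.values == 0).sum(axis=1)
    D_obs = zeros / n
    K = fit_michaelis_constant(S, D_obs)
    D_exp = np.clip(_mm_dropout(S, K), 1e-12, 1 - 1e-12)
    p = stats.binom.sf(zeros - 1, n, D_exp)  # P(X >= observed zeros)
    q = multipletests(p, method="fdr_bh")[1]
    selected = q < fdr
    table = pd.DataFrame(
        {
            "S": S,
            "D_obs": D_obs,
            "D_exp": D_exp,
            "p": p,
            "q": q,
            "selected": selected,
        },
        index=expr.gene_ids,
    )
    features = [g for g, s in zip(expr.gene_ids, selected) if s]
    return expr.subset_genes(features), FeatureSelection(table=table, K=K, fdr=fdr)


def log_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(value + 1) transform; marks the layer as normalized."""
    if np.any(expr.values < 0):
        raise ValidationError("log_normalize requires nonnegative values")
    return expr.with_values(np.log2(expr.values + 1.0), layer_tag="normalized")
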