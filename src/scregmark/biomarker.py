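"""Bulk-data biomarker ranking and Kaplan-Meier survival validation.

The tumor eigenvector (TEV) is the first principal component of the known
disease genes' rows of a z-scored bulk matrix, one score per bulk sample.
Candidate genes (per-cell-type markers from the single-cell analysis) are
ranked by the absolute Pearson correlation of their bulk expression with the
TEV; the top candidates are checked by median-expression-split Kaplan-Meier
curves with a log-rank comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test

from .datatypes import BulkMatrix, GeneSet, SurvivalTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "preprocess_bulk",
    "compute_tev",
    "rank_candidates",
    "km_curve",
    "median_split_km",
    "TEV",
    "KMCurve",
]


@dataclass
class TEV:
    """Tumor eigenvector: PC1 scores of the disease-gene submatrix."""

    scores: np.ndarray            # one per bulk sample
    sample_ids: list[str]
    explained_ratio: float
    loadings: np.ndarray          # unit-norm, sum of loadings > 0
    n_genes_used: int
    n_genes_requested: int


@dataclass
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    times: np.ndarray     # distinct event times, increasing
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    def __post_init__(self) -> None:
        s = self.survival
        if len(s) and (np.any(s < 0) or np.any(s > 1) or np.any(np.diff(s) > 1e-12)):
            raise ValidationError("survival curve must be nonincreasing in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "survival": self.survival,
            }
        )


def preprocess_bulk(bulk: BulkMatrix) -> BulkMatrix:
    """Drop lowly expressed genes, then z-score each gene across samples.

    A gene is dropped when its expression is below 1 in more than half the
    samples; zero-variance genes cannot be z-scored and are dropped too.
    """
    if np.any(bulk.values < 0):
        raise ValidationError("bulk preprocessing expects nonnegative raw values")
    n = bulk.n_samples
    low = (bulk.values < 1).sum(axis=1)
    keep = low <= n / 2
    values = bulk.values[keep]
    genes = [g for g, k in zip(bulk.gene_ids, keep) if k]
    sd = values.std(axis=1, ddof=0)
    if np.any(sd == 0):
        logger.warning("dropping %d zero-variance genes", int((sd == 0).sum()))
        values = values[sd > 0]
        genes = [g for g, s in zip(genes, sd) if s > 0]
        sd = sd[sd > 0]
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return BulkMatrix(
        gene_ids=genes, sample_ids=list(bulk.sample_ids), values=z, normalized=True
    )


def compute_tev(bulk: BulkMatrix, kggs: GeneSet) -> TEV:
    """First principal component of the known-disease-gene submatrix.

    Samples are the observations; the loading vector is unit-norm with its
    sum fixed positive so the direction is deterministic.
    """
    present = [g for g in kggs.sorted() if g in set(bulk.gene_ids)]
    if len(present) < 2:
        raise ValidationError(
            f"need >= 2 disease genes in bulk; found {len(present)}"
        )
    idx = {g: i for i, g in enumerate(bulk.gene_ids)}
    x = bulk.values[[idx[g] for g in present], :].T  # samples x genes
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    loadings = vt[0]
    if loadings.sum() < 0:
        loadings = -loadings
    scores = xc @ loadings
    var = s**2
    return TEV(
        scores=scores,
        sample_ids=list(bulk.sample_ids),
        explained_ratio=float(var[0] / var.sum()) if var.sum() > 0 else 0.0,
        loadings=loadings,
        n_genes_used=len(present),
        n_genes_requested=len(kggs),
    )


def rank_candidates(
    bulk: BulkMatrix, candidates: GeneSet, tev: TEV, top_n: int = 20
) -> pd.DataFrame:
    """Rank candidates by |Pearson r| between their bulk row and the TEV.

    Returns the full table (columns rank, gene, pcc, score, in_top) sorted by
    descending score with lexicographic gene-id tie-break; genes absent from
    the bulk matrix are listed in ``frame.attrs['missing']``.
    """
    genes_in_bulk = set(bulk.gene_ids)
    present = sorted(candidates.genes & genes_in_bulk)
    missing = sorted(candidates.genes - genes_in_bulk)
    if not present:
        raise ValidationError("no candidate gene is present in the bulk matrix")
    idx = {g: i for i, g in enumerate(bulk.gene_ids)}
    t = tev.scores - tev.scores.mean()
    t_norm = np.linalg.norm(t)
    rows = []
    for g in present:
        x = bulk.values[idx[g]]
        xc = x - x.mean()
        denom = np.linalg.norm(xc) * t_norm
        if denom == 0:
            logger.warning("constant row for %s; correlation undefined, score 0", g)
            r = 0.0
        else:
            r = float(xc @ t / denom)
        rows.append((g, r, abs(r)))
    frame = pd.DataFrame(rows, columns=["gene", "pcc", "score"])
    frame = frame.sort_values(
        ["score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    frame["in_top"] = frame["rank"] <= top_n
    frame.attrs["missing"] = missing
    return frame


def km_curve(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)`` over distinct event times;
    censored subjects (event 0) leave the risk set after their time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0 or np.any(times <= 0):
        raise ValidationError("times must be positive and nonempty")
    event_times = np.unique(times[events == 1])
    n_risk, n_event, surv = [], [], []
    s = 1.0
    for t in event_times:
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / at_risk
        n_risk.append(at_risk)
        n_event.append(d)
        surv.append(s)
    return KMCurve(
        times=event_times,
        n_risk=np.array(n_risk),
        n_event=np.array(n_event),
        survival=np.array(surv),
    )


def median_split_km(
    bulk: BulkMatrix, gene: str, survival: SurvivalTable
) -> tuple[KMCurve, KMCurve, float, str]:
    """Median-expression split into high/low groups with KM curves.

    Samples with expression strictly above the median form the high group
    (level 1), the rest the low group (level 0).  Returns (high curve, low
    curve, two-sided log-rank p, direction), where direction is
    ``"high-worse"`` when the high group's survival is lower at the last
    shared event time, else ``"low-worse"``.
    """
    if gene not in bulk.gene_ids:
        raise ValidationError(f"gene {gene!r} not in bulk matrix")
    surv = survival.frame.set_index("sample_id")
    shared = [s for s in bulk.sample_ids if s in surv.index]
    if len(shared) < 4:
        raise ValidationError("need >= 4 samples with expression and survival")
    expr = pd.Series(bulk.row(gene), index=bulk.sample_ids).loc[shared]
    med = float(expr.median())
    high = expr.index[expr > med]
    low = expr.index[expr <= med]
    if len(high) == 0 or len(low) == 0:
        raise ValidationError("median split produced an empty group")
    t_hi, e_hi = surv.loc[high, "time"].to_numpy(), surv.loc[high, "event"].to_numpy()
    t_lo, e_lo = surv.loc[low, "time"].to_numpy(), surv.loc[low, "event"].to_numpy()
    hi_curve = km_curve(t_hi, e_hi)
    lo_curve = km_curve(t_lo, e_lo)
    res = logrank_test(t_hi, t_lo, event_observed_A=e_hi, event_observed_B=e_lo)
    p = float(res.p_value)
    direction = _direction(hi_curve, lo_curve)
    return hi_curve, lo_curve, p, direction


def _direction(hi: KMCurve, lo: KMCurve) -> str:
    """Compare the two step functions at the last event time both reach."""
    if len(hi.times) == 0 or len(lo.times) == 0:
        return "indeterminate"
    t_star = min(hi.times[-1], lo.times[-1])
    s_hi = _step_at(hi, t_star)
    s_lo = _step_at(lo, t_star)
    if s_hi == s_lo:
        return "indeterminate"
    return "high-worse" if s_hi < s_lo else "low-worse"


def _step_at(curve: KMCurve, t: float) -> float:
    mask = curve.times <= t
    return float(curve.survival[mask][-1]) if mask.any() else 1.0
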