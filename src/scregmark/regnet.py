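"""Tumor-specific regulatory network: imputation, similarity filtering, FFLs.

Regulation pairs are restricted to the consensus genes, weighted by an
expression-similarity score computed on a dropout-imputed matrix, filtered at
similarity >= 0.6, and finally reduced to the union of feed-forward loops
(FFLs): triples where TF M regulates TF N and both regulate a target G.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSet, RegulationTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "impute_expression",
    "restrict_pairs",
    "edge_similarity",
    "enumerate_ffls",
    "build_specific_network",
    "RegulatoryNetwork",
    "FFLTriple",
]


@dataclass(frozen=True)
class FFLTriple:
    M: str  # upstream TF
    N: str  # downstream TF
    G: str  # jointly regulated target


@dataclass
class RegulatoryNetwork:
    """Directed TF->target network with per-edge similarity weights."""

    edges: pd.DataFrame  # columns: tf, target, kind {TF-TF, TF-gene}, similarity

    def __post_init__(self) -> None:
        e = self.edges
        required = {"tf", "target", "kind", "similarity"}
        if not required.issubset(e.columns):
            raise ValidationError(f"network edges need columns {sorted(required)}")
        if (e["tf"] == e["target"]).any():
            raise ValidationError("self-loop in regulatory network")
        sims = e["similarity"].to_numpy(dtype=float)
        if len(e) and (np.any(sims < 0) or np.any(sims > 1)):
            raise ValidationError("similarities must lie in [0, 1]")
        self.edges = e.reset_index(drop=True)

    @property
    def tf_nodes(self) -> set[str]:
        return set(self.edges["tf"])

    @property
    def target_nodes(self) -> set[str]:
        return set(self.edges["target"]) - self.tf_nodes

    def out_neighbors(self, tf: str) -> set[str]:
        return set(self.edges.loc[self.edges["tf"] == tf, "target"])

    def summary(self) -> dict[str, int]:
        kinds = self.edges["kind"].value_counts()
        return {
            "n_tfs": len(self.tf_nodes),
            "n_targets": len(self.target_nodes),
            "n_edges": len(self.edges),
            "n_tf_tf": int(kinds.get("TF-TF", 0)),
            "n_tf_gene": int(kinds.get("TF-gene", 0)),
        }


def impute_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Replace dropout zeros by each gene's expected expression in the cell.

    The expected value scales the gene's mean over cells by the cell's
    relative complexity: ``E_hat[i, j] = mean_i * (detected_j /
    mean(detected))``.  Nonzero entries are untouched.
    """
    v = expr.values
    if not np.any(v > 0):
        raise ValidationError("cannot impute an all-zero matrix")
    gene_mean = v.mean(axis=1)
    complexity = (v > 0).sum(axis=0).astype(float)
    expected = np.outer(gene_mean, complexity / complexity.mean())
    imputed = np.where(v == 0, expected, v)
    return expr.with_values(imputed, layer_tag="imputed")


def restrict_pairs(
    table: RegulationTable,
    consensus: GeneSet,
    measured: set[str],
    constrain_tf_tf: bool = False,
) -> RegulationTable:
    """Keep TF-gene pairs whose target is a consensus gene and TF-TF pairs
    whose members are both measured; every retained node must have expression.

    ``constrain_tf_tf=True`` additionally requires the downstream TF of a
    TF-TF pair to be a consensus gene.
    """
    kept = []
    for r in table.records:
        if r.tf not in measured or r.target not in measured:
            continue
        if r.target_is_tf:
            if constrain_tf_tf and r.target not in consensus:
                continue
            kept.append(r)
        elif r.target in consensus:
            kept.append(r)
    if not kept:
        raise ValidationError(
            f"no regulation pair survived restriction "
            f"({len(table)} input pairs, {len(consensus)} consensus genes, "
            f"{len(measured)} measured genes)"
        )
    return RegulationTable(records=kept)


def edge_similarity(
    expr: ExpressionMatrix,
    pairs: RegulationTable,
    cutoff: float = 0.6,
) -> pd.DataFrame:
    """Expression similarity per regulation pair, filtered at ``cutoff``.

    Similarity is 1 minus the min-max normalized Euclidean distance between
    the two gene rows over all cells, computed across the full set of pairs.
    """
    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = []
    for r in pairs.records:
        if r.tf not in idx or r.target not in idx:
            raise ValidationError(f"pair ({r.tf}, {r.target}) lacks expression")
        d = float(np.linalg.norm(expr.values[idx[r.tf]] - expr.values[idx[r.target]]))
        rows.append((r.tf, r.target, "TF-TF" if r.target_is_tf else "TF-gene", d))
    frame = pd.DataFrame(rows, columns=["tf", "target", "kind", "distance"])
    d = frame["distance"].to_numpy()
    if d.max() == d.min():
        logger.warning("degenerate distances; all similarities set to 1")
        frame["similarity"] = 1.0
    else:
        frame["similarity"] = 1.0 - (d - d.min()) / (d.max() - d.min())
    frame = frame[frame["similarity"] >= cutoff].reset_index(drop=True)
    return frame.drop(columns="distance")


def enumerate_ffls(edges: pd.DataFrame) -> list[FFLTriple]:
    """All feed-forward loops (M, N, G): TF-TF edge M->N with M->G and N->G.

    G may itself be a TF; output is lexicographically sorted.
    """
    out: dict[str, set[str]] = {}
    for tf, tgt in zip(edges["tf"], edges["target"]):
        out.setdefault(tf, set()).add(tgt)
    triples = []
    tf_tf = edges.loc[edges["kind"] == "TF-TF", ["tf", "target"]]
    for m, n_ in zip(tf_tf["tf"], tf_tf["target"]):
        shared = out.get(m, set()) & out.get(n_, set())
        for g in shared:
            if g != m and g != n_:
                triples.append(FFLTriple(M=m, N=n_, G=g))
    return sorted(set(triples), key=lambda t: (t.M, t.N, t.G))


def build_specific_network(
    edges: pd.DataFrame, ffls: list[FFLTriple]
) -> RegulatoryNetwork:
    """Keep exactly the edges participating in at least one FFL."""
    if not ffls:
        raise ValidationError(
            "no FFLs found; consider lowering the similarity cutoff"
        )
    used = set()
    for t in ffls:
        used.update({(t.M, t.N), (t.M, t.G), (t.N, t.G)})
    mask = [(tf, tgt) in used for tf, tgt in zip(edges["tf"], edges["target"])]
    kept = edges.loc[mask].sort_values(["tf", "target"], kind="mergesort").reset_index(drop=True)
    net = RegulatoryNetwork(edges=kept)
    logger.info("specific network: %s", net.summary())
    return net
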