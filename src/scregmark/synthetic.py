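"""Synthetic multi-sample single-cell / regulation / bulk-survival fixtures.

Generates all four pipeline inputs with planted ground truth:

* a multi-sample single-cell count matrix with planted cell types whose
  marker genes are shared across samples (so they are the planted consensus
  genes), negative-binomial counts, per-sample batch effects, Michaelis-
  Menten dropout with a known constant K, and a few spiked low-complexity
  cells to exercise cell QC;
* a TF->target regulation table with planted feed-forward loops whose member
  genes are co-expressed same-type markers (so expression similarity keeps
  them) and decoy edges between markers of different types (so the
  similarity filter removes them);
* a bulk matrix sharing a latent disease factor between known-disease-gene
  (KGG) rows and planted biomarker rows (calibrated population |PCC|), plus
  exponential survival times whose hazard follows the latent factor.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    BulkMatrix,
    ExpressionMatrix,
    GeneSet,
    RegulationRecord,
    RegulationTable,
    SurvivalTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticTruth",
    "generate_single_cell",
    "generate_regulation",
    "generate_bulk_survival",
    "generate_all",
    "write_fixture",
]


@dataclass
class SyntheticTruth:
    """Planted ground truth shared by the three generators."""

    seed: int
    # single cell
    type_labels: pd.Series | None = None          # cell_id -> planted type
    markers_by_type: dict[int, list[str]] = field(default_factory=dict)
    marker_mean: pd.Series | None = None          # marker gene -> base mean
    consensus_genes: set[str] = field(default_factory=set)
    low_quality_cells: list[str] = field(default_factory=list)
    dropout_K: float | None = None
    batch_log2_sd: float | None = None
    # regulation
    tf_genes: list[str] = field(default_factory=list)
    ffl_triples: list[tuple[str, str, str]] = field(default_factory=list)
    decoy_edges: list[tuple[str, str]] = field(default_factory=list)
    # bulk + survival
    biomarker_direction: dict[str, str] = field(default_factory=dict)
    kgg_genes: list[str] = field(default_factory=list)
    target_abs_pcc: float | None = None
    hazard_ratio: float | None = None
    latent_factor: np.ndarray | None = None


def _mm_dropout(s: np.ndarray, K: float) -> np.ndarray:
    return K / (K + s)


def generate_single_cell(
    n_samples: int = 6,
    cells_per_sample: int = 200,
    n_genes: int = 1500,
    n_types: int = 4,
    markers_per_type: int = 40,
    batch_sd: float = 0.2,
    type_effect: float = 2.0,
    dropout_K: float = 5.0,
    marker_dropout_boost: float = 0.25,
    n_lowq_per_sample: int = 3,
    nb_size: float = 10.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Multi-sample scRNA-seq counts with planted types and MM dropout.

    Each gene's target observed mean ``S`` is drawn log-normally; dropout is
    Bernoulli with probability ``K/(K+S)`` while nonzero counts are negative
    binomial with mean ``K + S``, so the observed per-gene mean stays ``S``
    and the dropout rate follows the Michaelis-Menten curve at constant
    ``K``.  Type markers gain ``type_effect`` log2 units of mean in their
    own type and ``marker_dropout_boost`` extra dropout outside it (silent
    genes show excess zeros), which makes the markers both differential and
    dropout-selected features.  Per-sample batch effects multiply gene means
    by ``2**N(0, batch_sd)``.
    """
    if n_types < 2:
        raise ValidationError("need at least 2 planted cell types")
    if n_types * markers_per_type > n_genes:
        raise ValidationError("markers exceed gene count")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    markers_by_type = {
        t: genes[t * markers_per_type : (t + 1) * markers_per_type]
        for t in range(n_types)
    }
    marker_of = np.full(n_genes, -1)
    for t, gs in markers_by_type.items():
        for g in gs:
            marker_of[genes.index(g)] = t

    base_s = np.exp(rng.normal(1.0, 0.8, size=n_genes))  # target observed means
    # markers are well-expressed genes: a planted marker must be detectable
    # to be a marker at all
    is_marker = marker_of >= 0
    base_s[is_marker] = np.exp(rng.normal(1.5, 0.4, size=int(is_marker.sum())))
    cell_ids: list[str] = []
    cell_sample: dict[str, str] = {}
    type_of_cell: list[int] = []
    blocks: list[np.ndarray] = []
    lowq_cells: list[str] = []
    samples = [f"S{j + 1}" for j in range(n_samples)]
    for j, sample in enumerate(samples):
        batch = 2.0 ** rng.normal(0.0, batch_sd, size=n_genes)
        types = rng.integers(0, n_types, size=cells_per_sample)
        s_mat = np.empty((n_genes, cells_per_sample))
        for c in range(cells_per_sample):
            s = base_s * batch
            boost = marker_of == types[c]
            s = np.where(boost, s * 2.0**type_effect, s)
            s_mat[:, c] = s
        drop_p = _mm_dropout(s_mat, dropout_K)
        off_type = (marker_of[:, None] >= 0) & (marker_of[:, None] != types[None, :])
        drop_p = np.where(off_type, np.minimum(1.0, drop_p + marker_dropout_boost), drop_p)
        nonzero_mean = dropout_K + s_mat
        p_nb = nb_size / (nb_size + nonzero_mean)
        counts = rng.negative_binomial(nb_size, p_nb)
        dropped = rng.random(s_mat.shape) < drop_p
        counts = np.where(dropped, 0, counts)
        # spiked low-complexity cells: keep only a small fraction of genes
        for i in range(n_lowq_per_sample):
            c = cells_per_sample - 1 - i
            keep = rng.random(n_genes) < 0.05
            counts[:, c] = np.where(keep, counts[:, c], 0)
            lowq_cells.append(f"{sample}_c{c:03d}")
        blocks.append(counts.astype(float))
        for c in range(cells_per_sample):
            cid = f"{sample}_c{c:03d}"
            cell_ids.append(cid)
            cell_sample[cid] = sample
            type_of_cell.append(int(types[c]))
    values = np.concatenate(blocks, axis=1)
    expr = ExpressionMatrix(
        gene_ids=genes, cell_ids=cell_ids, values=values, cell_sample=cell_sample
    )
    truth = SyntheticTruth(
        seed=seed,
        type_labels=pd.Series(type_of_cell, index=cell_ids, name="type"),
        markers_by_type=markers_by_type,
        marker_mean=pd.Series(
            {g: base_s[genes.index(g)] for gs in markers_by_type.values() for g in gs}
        ),
        consensus_genes={g for gs in markers_by_type.values() for g in gs},
        low_quality_cells=lowq_cells,
        dropout_K=dropout_K,
        batch_log2_sd=batch_sd,
    )
    return expr, truth


def generate_regulation(
    sc_truth: SyntheticTruth,
    all_genes: list[str],
    n_tfs: int = 40,
    n_targets: int = 300,
    n_ffls: int = 25,
    n_decoys: int = 60,
    seed: int = 0,
) -> tuple[RegulationTable, SyntheticTruth]:
    """TF->target pairs with planted FFLs over co-expressed same-type markers.

    TFs are drawn evenly from each type's markers; each planted FFL
    (M, N, G) uses two TFs and one non-TF marker of the same type, so all
    three expression profiles are similar.  Decoy edges connect TFs to
    markers of a different type (anti-correlated profiles) and are expected
    to fall below the similarity cutoff.
    """
    rng = np.random.default_rng(seed)
    types = sorted(sc_truth.markers_by_type)
    if not types:
        raise ValidationError("single-cell truth has no planted markers")
    per_type = max(2, n_tfs // len(types))
    tf_by_type: dict[int, list[str]] = {}
    tfs: list[str] = []
    for t in types:
        pool = sc_truth.markers_by_type[t]
        tf_by_type[t] = list(pool[:per_type])
        tfs.extend(tf_by_type[t])
    tf_set = set(tfs)
    # candidate targets: non-TF markers first, padded with other measured genes
    marker_targets = {
        t: [g for g in sc_truth.markers_by_type[t] if g not in tf_set] for t in types
    }
    extra_pool = [g for g in all_genes if g not in tf_set and g not in sc_truth.consensus_genes]
    n_extra = max(0, n_targets - sum(len(v) for v in marker_targets.values()))
    extra = list(rng.choice(extra_pool, size=min(n_extra, len(extra_pool)), replace=False))

    records: dict[tuple[str, str], bool] = {}
    triples: list[tuple[str, str, str]] = []
    n_pairs = sum(len(v) * (len(v) - 1) for v in tf_by_type.values())
    if n_ffls > n_pairs:
        raise ValidationError("n_ffls exceeds TF-pair capacity")
    mean = sc_truth.marker_mean

    def _nearest(pool: list[str], ref: float, exclude: set[str]) -> str:
        cands = [g for g in pool if g not in exclude]
        if mean is None:
            return cands[int(rng.integers(len(cands)))]
        return min(cands, key=lambda g: (abs(float(mean[g]) - ref), g))

    for i in range(n_ffls):
        t = types[i % len(types)]
        m = tf_by_type[t][int(rng.integers(len(tf_by_type[t])))]
        ref = float(mean[m]) if mean is not None else 0.0
        # co-expressed by construction: the partner TF and the target are the
        # same-type markers closest in base expression to the anchor TF
        n_ = _nearest(tf_by_type[t], ref, {m})
        g = _nearest(marker_targets[t], (ref + float(mean[n_])) / 2 if mean is not None else 0.0, set())
        triples.append((m, n_, g))
        records[(m, n_)] = True
        records[(m, g)] = g in tf_set
        records[(n_, g)] = g in tf_set
    triples = sorted(set(triples))
    decoys: list[tuple[str, str]] = []
    tries = 0
    while len(decoys) < n_decoys and tries < 50 * n_decoys:
        tries += 1
        t = types[int(rng.integers(len(types)))]
        u_choices = [x for x in types if x != t]
        u = u_choices[int(rng.integers(len(u_choices)))]
        tf = tf_by_type[t][int(rng.integers(len(tf_by_type[t])))]
        tgt_pool = marker_targets[u] + (extra if rng.random() < 0.2 else [])
        tgt = tgt_pool[int(rng.integers(len(tgt_pool)))]
        if (tf, tgt) in records or tf == tgt:
            continue
        records[(tf, tgt)] = tgt in tf_set
        decoys.append((tf, tgt))
    table = RegulationTable(
        records=[
            RegulationRecord(tf=a, target=b, target_is_tf=is_tf, source="synthetic")
            for (a, b), is_tf in sorted(records.items())
        ]
    )
    truth = SyntheticTruth(
        seed=seed,
        tf_genes=sorted(tf_set),
        ffl_triples=triples,
        decoy_edges=sorted(decoys),
    )
    return table, truth


def generate_bulk_survival(
    sc_truth: SyntheticTruth,
    all_genes: list[str],
    n_bulk: int = 150,
    n_biomarkers: int = 15,
    n_kggs: int = 30,
    target_abs_pcc: float = 0.85,
    kgg_pcc: float = 0.9,
    hr: float = 2.5,
    base_hazard: float = 1.0 / 36.0,
    seed: int = 0,
) -> tuple[BulkMatrix, GeneSet, SurvivalTable, SyntheticTruth]:
    """Bulk matrix, KGG list and survival table sharing one latent factor.

    KGG rows load on a latent per-sample factor ``f`` at correlation
    ``kgg_pcc`` (so PC1 of the KGG submatrix recovers ``f``); planted
    biomarker rows load at ``+-target_abs_pcc``; all other rows are noise.
    Survival times are exponential with hazard multiplied by ``hr`` for
    samples with ``f`` above its median, so positively loading biomarkers
    are "high-worse".
    """
    if not 0 < target_abs_pcc < 1:
        raise ValidationError("target_abs_pcc must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    candidates = sorted(sc_truth.consensus_genes)
    if n_biomarkers > len(candidates):
        raise ValidationError("more biomarkers than candidate genes")
    biomarkers = list(rng.choice(candidates, size=n_biomarkers, replace=False))
    kggs = [f"KGG{i:03d}" for i in range(n_kggs)]
    samples = [f"B{i:03d}" for i in range(n_bulk)]
    f = rng.standard_normal(n_bulk)
    genes = list(all_genes) + kggs
    n_genes = len(genes)
    base = rng.uniform(5.0, 50.0, size=n_genes)
    sigma = 1.0
    values = base[:, None] + sigma * rng.standard_normal((n_genes, n_bulk))
    gene_pos = {g: i for i, g in enumerate(genes)}

    def plant(row: int, rho: float, sign: float) -> None:
        noise = rng.standard_normal(n_bulk)
        values[row] = base[row] + sigma * sign * (
            rho * f + np.sqrt(1 - rho**2) * noise
        )

    direction: dict[str, str] = {}
    for g in biomarkers:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        plant(gene_pos[g], target_abs_pcc, sign)
        direction[g] = "high-worse" if sign > 0 else "low-worse"
    for g in kggs:
        plant(gene_pos[g], kgg_pcc, 1.0)
    # a few junk genes below the expression floor, to exercise the bulk filter
    junk = rng.choice(
        [g for g in all_genes if g not in set(biomarkers)], size=20, replace=False
    )
    for g in junk:
        values[gene_pos[g]] = np.abs(rng.normal(0.3, 0.2, size=n_bulk))
    values = np.clip(values, 0.0, None)
    bulk = BulkMatrix(gene_ids=genes, sample_ids=samples, values=values)

    high = f > np.median(f)
    rate = base_hazard * np.where(high, hr, 1.0)
    times = rng.exponential(1.0 / rate)
    censor = rng.uniform(24.0, 80.0, size=n_bulk)
    event = (times <= censor).astype(int)
    obs = np.minimum(times, censor)
    obs = np.maximum(obs, 1e-3)
    surv = SurvivalTable(
        frame=pd.DataFrame({"sample_id": samples, "time": obs, "event": event})
    )
    truth = SyntheticTruth(
        seed=seed,
        biomarker_direction=direction,
        kgg_genes=kggs,
        target_abs_pcc=target_abs_pcc,
        hazard_ratio=hr,
        latent_factor=f,
    )
    return bulk, GeneSet(name="kggs", genes=set(kggs)), surv, truth


def generate_all(seed: int = 0, **sc_kwargs):
    """Default fixture: single-cell + regulation + bulk/survival, one seed."""
    ss = np.random.SeedSequence(seed)
    s_sc, s_reg, s_bulk = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)]
    expr, sc_truth = generate_single_cell(seed=s_sc, **sc_kwargs)
    reg, reg_truth = generate_regulation(sc_truth, expr.gene_ids, seed=s_reg)
    bulk, kggs, surv, bulk_truth = generate_bulk_survival(
        sc_truth, expr.gene_ids, seed=s_bulk
    )
    return expr, reg, bulk, kggs, surv, (sc_truth, reg_truth, bulk_truth)


def write_fixture(out_dir: "str | Path", seed: int = 0, **sc_kwargs) -> Path:
    """Emit all input files plus truth tables under ``out_dir``."""
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    expr, reg, bulk, kggs, surv, (sc_t, reg_t, bulk_t) = generate_all(seed, **sc_kwargs)
    expr.to_frame().to_csv(out / "expression.tsv", sep="\t")
    pd.Series(expr.cell_sample).rename("sample_id").rename_axis("cell_id").to_csv(
        out / "cell_samples.tsv", sep="\t", header=False
    )
    reg.to_frame()[["tf", "target"]].to_csv(
        out / "regulation.tsv", sep="\t", header=False, index=False
    )
    (out / "kggs.txt").write_text("\n".join(sorted(kggs.genes)) + "\n")
    bulk.to_frame().to_csv(out / "bulk.tsv", sep="\t")
    surv.frame.to_csv(out / "survival.tsv", sep="\t", index=False)
    sc_t.type_labels.rename_axis("cell_id").to_csv(out / "truth" / "cell_types.tsv", sep="\t")
    pd.Series(sorted(sc_t.consensus_genes)).to_csv(
        out / "truth" / "consensus_genes.tsv", sep="\t", index=False, header=False
    )
    pd.DataFrame(reg_t.ffl_triples, columns=["M", "N", "G"]).to_csv(
        out / "truth" / "ffls.tsv", sep="\t", index=False
    )
    pd.Series(bulk_t.biomarker_direction).rename_axis("gene").rename("direction").to_csv(
        out / "truth" / "biomarkers.tsv", sep="\t"
    )
    return out
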