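"""End-to-end orchestration of the four-step biomarker discovery pipeline.

Stages run in order -- preprocess, consensus, regulatory network, cell
types, biomarkers -- each writing checkpoint TSVs under
``<out_dir>/checkpoints``; with ``resume=True`` a stage whose checkpoint
files exist is loaded instead of recomputed, and a resumed run reproduces a
fresh run bit for bit because every stage draws its seed independently from
the global seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomarker as bm
from . import celltype as ct
from . import consensus as cs
from . import preprocess as pp
from . import regnet as rn
from .datatypes import (
    BulkMatrix,
    ExpressionMatrix,
    GeneSet,
    RegulationTable,
    SurvivalTable,
    ValidationError,
)
from .io import ResultsBundle, write_results

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

_STAGE_NAMES = ("preprocess", "consensus", "regnet", "celltype", "biomarker")


@dataclass
class PipelineConfig:
    """All inputs, thresholds and the global seed for one pipeline run.

    Threshold defaults are the study values: cell-QC FDR 0.05, feature FDR
    0.01, k = 20 SNN neighbors, |log2FC| > 1 and p < 0.05 for DE, consensus
    support >= 2 samples, similarity cutoff 0.6, 25 score bins with 100
    controls per gene, 100 ROTS bootstraps, top 20 ranked candidates.
    """

    expression: str | None = None
    cell_samples: str | None = None
    regulation: list[str] = field(default_factory=list)
    kggs: str | None = None
    bulk: str | None = None
    survival: str | None = None
    out_dir: str = "results"

    qc_fdr: float = 0.05
    feature_fdr: float = 0.01
    min_cells: int = 3
    min_mean_norm: float = 1e-5
    k: int = 20
    resolution: float = 1.0
    lfc: float = 1.0
    p: float = 0.05
    min_samples: int = 2
    sim_cutoff: float = 0.6
    constrain_tf_tf: bool = False
    bins: int = 25
    nctrl: int = 100
    bootstrap: int = 100
    n_perm: int = 200
    rots_q: float = 0.05
    top_n: int = 20
    seed: int = 0
    resume: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.qc_fdr < 1 and 0 < self.feature_fdr < 1):
            raise ValidationError("FDR thresholds must lie in (0, 1)")
        if not (0 <= self.sim_cutoff <= 1):
            raise ValidationError("similarity cutoff must lie in [0, 1]")
        if self.k < 1 or self.min_samples < 1 or self.top_n < 1:
            raise ValidationError("k, min_samples and top_n must be positive")

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed fanned out from the global seed."""
        idx = _STAGE_NAMES.index(stage)
        ss = np.random.SeedSequence(self.seed).spawn(len(_STAGE_NAMES))[idx]
        return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineResult:
    bundle: ResultsBundle
    pooled: ExpressionMatrix
    per_sample_features: dict[str, list[str]]
    dropout_K: dict[str, float]
    deg_by_sample: dict[str, set[str]]
    consensus: cs.ConsensusResult
    network: rn.RegulatoryNetwork
    ffls: list[rn.FFLTriple]
    rmm_scores: pd.DataFrame
    assignment: ct.CellTypeAssignment
    rots_by_type: dict[int, ct.ROTSResult]
    tev: bm.TEV
    log: dict


def _pooled_log_matrix(
    raw: ExpressionMatrix, cells: list[str], features: list[str]
) -> ExpressionMatrix:
    sub = raw.subset_cells(cells).subset_genes(features)
    return pp.log_normalize(sub)


def run_pipeline(
    config: PipelineConfig,
    expression: ExpressionMatrix | None = None,
    regulation: RegulationTable | None = None,
    kggs: GeneSet | None = None,
    bulk: BulkMatrix | None = None,
    survival: SurvivalTable | None = None,
) -> PipelineResult:
    """Run the full pipeline; inputs may be in-memory objects or config paths."""
    from . import io as _io

    if expression is None:
        if config.expression is None:
            raise ValidationError("no expression input given")
        expression = _io.read_expression(config.expression, config.cell_samples)
    if regulation is None:
        regulation = _io.read_regulation_pairs(config.regulation)
    if kggs is None:
        kggs = _io.read_gene_set(config.kggs)
    if bulk is None:
        bulk = _io.read_bulk(config.bulk)
    if survival is None:
        survival = _io.read_survival(config.survival)

    out_dir = Path(config.out_dir)
    ckpt = out_dir / "checkpoints"
    ckpt.mkdir(parents=True, exist_ok=True)
    run_log: dict = {"config": {k: v for k, v in asdict(config).items()}, "counts": {}}

    # ------------------------------------------------------------------ step 1
    pre_files = [ckpt / "preprocess_cells.tsv", ckpt / "preprocess_features.tsv"]
    if config.resume and all(f.exists() for f in pre_files):
        logger.info("resuming preprocess from checkpoint")
        cells_tab = pd.read_csv(pre_files[0], sep="\t")
        feat_tab = pd.read_csv(pre_files[1], sep="\t")
        kept_cells = {
            s: list(g["cell_id"]) for s, g in cells_tab.groupby("sample", sort=False)
        }
        features = {
            s: list(g["gene"]) for s, g in feat_tab.groupby("sample", sort=False)
        }
        dropout_K = dict(
            zip(feat_tab.drop_duplicates("sample")["sample"],
                feat_tab.drop_duplicates("sample")["K"])
        )
    else:
        kept_cells, features, dropout_K = {}, {}, {}
        for sample, sub in pp.split_by_sample(expression).items():
            sub, _qc = pp.qc_filter_cells(sub, fdr=config.qc_fdr)
            sub = pp.filter_genes(sub, config.min_cells, config.min_mean_norm)
            feats, sel = pp.select_features_dropout(sub, fdr=config.feature_fdr)
            kept_cells[sample] = list(sub.cell_ids)
            features[sample] = list(feats.gene_ids)
            dropout_K[sample] = sel.K
        pd.DataFrame(
            [(s, c) for s, cs_ in kept_cells.items() for c in cs_],
            columns=["sample", "cell_id"],
        ).to_csv(pre_files[0], sep="\t", index=False)
        pd.DataFrame(
            [(s, g, dropout_K[s]) for s, gs in features.items() for g in gs],
            columns=["sample", "gene", "K"],
        ).to_csv(pre_files[1], sep="\t", index=False)
    run_log["counts"]["cells_kept"] = sum(len(v) for v in kept_cells.values())
    run_log["counts"]["features_per_sample"] = {s: len(g) for s, g in features.items()}

    # ------------------------------------------------------------------ step 2
    seed_cons = config.stage_seed("consensus")
    deg_file = ckpt / "degs.tsv"
    if config.resume and deg_file.exists():
        logger.info("resuming consensus from checkpoint")
        deg_tab = pd.read_csv(deg_file, sep="\t")
    else:
        deg_records = []
        for sample in kept_cells:
            mat = _pooled_log_matrix(expression, kept_cells[sample], features[sample])
            ratios = cs.explained_variance_ratios(mat)
            n_pcs = cs.select_num_pcs(ratios)
            emb = cs.embed_pca(mat, n_pcs)
            graph = cs.build_snn_graph(emb, mat.cell_ids, k=config.k)
            labels = cs.cluster_louvain(graph, config.resolution, seed=seed_cons)
            deg_records.extend(
                cs.de_one_vs_rest(mat, labels, lfc=config.lfc, p_threshold=config.p)
            )
        deg_tab = pd.DataFrame(
            [(r.sample_id, r.cluster_id, r.gene, r.log2fc, r.p) for r in deg_records],
            columns=["sample", "cluster", "gene", "log2fc", "p"],
        )
        deg_tab.to_csv(deg_file, sep="\t", index=False)
    deg_by_sample = {s: set() for s in kept_cells}
    for s, g in zip(deg_tab["sample"], deg_tab["gene"]):
        deg_by_sample[s].add(g)
    consensus = cs.consensus_genes(deg_by_sample, min_samples=config.min_samples)
    run_log["counts"]["consensus_genes"] = len(consensus.genes)

    # pooled matrix over the union of per-sample feature genes
    union_feats = sorted(set().union(*features.values()))
    all_cells = [c for s in kept_cells for c in kept_cells[s]]
    pooled = _pooled_log_matrix(expression, all_cells, union_feats)

    # ------------------------------------------------------------------ step 3
    net_files = [ckpt / "network_edges.tsv", ckpt / "ffls.tsv"]
    if config.resume and all(f.exists() for f in net_files):
        logger.info("resuming regnet from checkpoint")
        edges = pd.read_csv(net_files[0], sep="\t")
        ffl_tab = pd.read_csv(net_files[1], sep="\t")
        network = rn.RegulatoryNetwork(edges=edges)
        ffls = [rn.FFLTriple(*row) for row in ffl_tab.itertuples(index=False)]
    else:
        imputed = rn.impute_expression(pooled)
        restricted = rn.restrict_pairs(
            regulation,
            consensus.genes,
            measured=set(pooled.gene_ids),
            constrain_tf_tf=config.constrain_tf_tf,
        )
        weighted = rn.edge_similarity(imputed, restricted, cutoff=config.sim_cutoff)
        ffls = rn.enumerate_ffls(weighted)
        network = rn.build_specific_network(weighted, ffls)
        network.edges.to_csv(net_files[0], sep="\t", index=False, float_format="%.10g")
        pd.DataFrame(
            [(t.M, t.N, t.G) for t in ffls], columns=["M", "N", "G"]
        ).to_csv(net_files[1], sep="\t", index=False)
    run_log["counts"].update(network.summary())
    run_log["counts"]["ffls"] = len(ffls)

    # ------------------------------------------------------------------ step 4
    seed_ct = config.stage_seed("celltype")
    ct_files = [ckpt / "cell_types.tsv", ckpt / "rmm_scores.tsv",
                ckpt / "biomarkers_per_type.tsv"]
    rmms = ct.extract_rmms(network)
    if config.resume and all(f.exists() for f in ct_files):
        logger.info("resuming celltype from checkpoint")
        types_tab = pd.read_csv(ct_files[0], sep="\t")
        scores = pd.read_csv(ct_files[1], sep="\t", index_col=0)
        biom_tab = pd.read_csv(ct_files[2], sep="\t")
        labels = pd.Series(
            types_tab["type"].to_numpy(), index=types_tab["cell_id"], name="type"
        )
        assignment = ct.CellTypeAssignment(
            labels=labels, k=int(labels.nunique()),
            centers=np.empty((0, 0)), ch=float("nan"), t1=float("nan"), t2=float("nan"),
        )
        rots_by_type = {}
        for tid, grp in biom_tab.groupby("type"):
            tab = grp.set_index("gene")[["d", "q"]]
            tab["p"] = np.nan
            rots_by_type[int(tid)] = ct.ROTSResult(
                table=tab, alpha1=float("nan"), alpha2=float("nan"), z=float("nan")
            )
    else:
        scores = ct.score_modules(
            pooled, rmms, n_bins=config.bins, n_ctrl=config.nctrl, seed=seed_ct
        )
        assignment = ct.hybrid_cluster(scores, seed=seed_ct)
        rots_by_type = {}
        biom_rows = []
        type_sizes = assignment.labels.value_counts()
        for tid in sorted(assignment.labels.unique()):
            if type_sizes[tid] < 3 or len(assignment.labels) - type_sizes[tid] < 3:
                logger.warning("type %s too small for marker detection; skipped", tid)
                continue
            res = ct.rots_biomarkers(
                pooled,
                assignment.labels,
                tid,
                n_bootstrap=config.bootstrap,
                n_perm=config.n_perm,
                seed=seed_ct + int(tid) + 1,
            )
            rots_by_type[int(tid)] = res
            hits = res.table[res.table["q"] < config.rots_q].sort_values(
                ["q", "d"], ascending=[True, False], kind="mergesort"
            )
            for gene, row in hits.iterrows():
                biom_rows.append((int(tid), gene, row["d"], row["q"]))
        biom_tab = pd.DataFrame(biom_rows, columns=["type", "gene", "d", "q"])
        types_tab = pd.DataFrame(
            {
                "cell_id": assignment.labels.index,
                "sample": [pooled.cell_sample[c] for c in assignment.labels.index],
                "type": assignment.labels.to_numpy(),
            }
        )
        types_tab.to_csv(ct_files[0], sep="\t", index=False)
        scores.to_csv(ct_files[1], sep="\t", float_format="%.10g")
        biom_tab.to_csv(ct_files[2], sep="\t", index=False, float_format="%.10g")
    run_log["counts"]["rmms"] = len(rmms)
    run_log["counts"]["cell_types"] = int(types_tab["type"].nunique())
    run_log["counts"]["cells_per_type"] = (
        types_tab["type"].value_counts().sort_index().to_dict()
    )
    run_log["counts"]["biomarkers_per_type"] = (
        biom_tab.groupby("type")["gene"].count().to_dict() if len(biom_tab) else {}
    )

    # ------------------------------------------------------------------ step 5
    bulk_z = bm.preprocess_bulk(bulk) if not bulk.normalized else bulk
    tev = bm.compute_tev(bulk_z, kggs)
    candidate_genes = sorted(set(biom_tab["gene"])) if len(biom_tab) else []
    if not candidate_genes:
        raise ValidationError("no candidate biomarker genes from cell types")
    ranking = bm.rank_candidates(
        bulk_z, GeneSet(name="candidates", genes=set(candidate_genes)), tev,
        top_n=config.top_n,
    )
    km_tables: dict[str, pd.DataFrame] = {}
    km_summary = {}
    for gene in ranking.loc[ranking["in_top"], "gene"]:
        try:
            hi, lo, p_lr, direction = bm.median_split_km(bulk_z, gene, survival)
        except ValidationError as exc:
            logger.warning("KM skipped for %s: %s", gene, exc)
            continue
        hi_f = hi.to_frame().assign(group="high")
        lo_f = lo.to_frame().assign(group="low")
        km_tables[gene] = pd.concat([hi_f, lo_f], ignore_index=True)
        km_summary[gene] = {"logrank_p": p_lr, "direction": direction}
    run_log["counts"]["candidates"] = len(candidate_genes)
    run_log["km_summary"] = km_summary
    run_log["tev_explained_ratio"] = tev.explained_ratio

    bundle = ResultsBundle(
        consensus_genes=pd.DataFrame(
            sorted(consensus.support.items()), columns=["gene", "support"]
        ),
        network_edges=network.edges,
        ffls=pd.DataFrame([(t.M, t.N, t.G) for t in ffls], columns=["M", "N", "G"]),
        cell_types=types_tab,
        biomarkers_per_type=biom_tab,
        ranked_candidates=ranking.drop(columns="in_top"),
        km_tables=km_tables,
    )
    write_results(bundle, out_dir)
    consensus.overlap.to_csv(out_dir / "overlap_matrix.tsv", sep="\t", float_format="%.10g")
    (out_dir / "run_log.yaml").write_text(yaml.safe_dump(_plain(run_log), sort_keys=True))
    return PipelineResult(
        bundle=bundle,
        pooled=pooled,
        per_sample_features=features,
        dropout_K=dropout_K,
        deg_by_sample=deg_by_sample,
        consensus=consensus,
        network=network,
        ffls=ffls,
        rmm_scores=scores,
        assignment=assignment,
        rots_by_type=rots_by_type,
        tev=tev,
        log=run_log,
    )


def _plain(obj):
    """Recursively convert numpy scalars for YAML serialization."""
    if isinstance(obj, dict):
        return {_plain(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
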