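"""File readers and writers for every pipeline input and output.

Supported inputs: dense TSV/CSV expression matrices (genes as rows by
default) or MatrixMarket MTX with ``genes.tsv``/``cells.tsv`` sidecars;
2-3 column TSV regulation-pair tables; one-gene-per-line gene sets; TSV
survival and bulk tables.  All result tables are plain TSV and round-trip
through the corresponding reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

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
    "read_expression",
    "read_regulation_pairs",
    "read_gene_set",
    "read_survival",
    "read_bulk",
    "ResultsBundle",
    "write_results",
    "read_network_edges",
]


def _collapse_duplicate_genes(frame: pd.DataFrame) -> pd.DataFrame:
    """Sum duplicate gene rows (counts semantics), logging a warning."""
    if frame.index.has_duplicates:
        dups = sorted(frame.index[frame.index.duplicated()].unique())
        logger.warning("collapsing %d duplicate gene ids by sum: %s", len(dups), dups[:5])
        frame = frame.groupby(level=0, sort=False).sum()
    return frame


def _read_sample_labels(sample_labels: "Mapping[str, str] | str | Path") -> dict[str, str]:
    if isinstance(sample_labels, (str, Path)):
        tab = pd.read_csv(sample_labels, sep="\t", header=None, dtype=str, comment="#")
        if tab.shape[1] < 2:
            raise ValidationError(f"sample label file {sample_labels} needs 2 columns")
        if list(tab.iloc[0]) [:2] == ["cell_id", "sample_id"]:
            tab = tab.iloc[1:]
        return dict(zip(tab.iloc[:, 0], tab.iloc[:, 1]))
    return dict(sample_labels)


def read_expression(
    path: "str | Path",
    sample_labels: "Mapping[str, str] | str | Path",
    fmt: str | None = None,
    genes_as_rows: bool = True,
) -> ExpressionMatrix:
    """Read a single-cell expression matrix plus per-cell sample labels.

    ``fmt`` is inferred from the suffix when omitted: ``.mtx`` expects
    ``genes.tsv`` and ``cells.tsv`` sidecars next to the matrix; ``.tsv`` /
    ``.csv`` are dense with gene ids in the first column and cell ids in the
    header.  Duplicate gene rows are collapsed by summation with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "mtx":
        mat = scipy.io.mmread(path)
        genes = pd.read_csv(path.parent / "genes.tsv", sep="\t", header=None)[0].astype(str)
        cells = pd.read_csv(path.parent / "cells.tsv", sep="\t", header=None)[0].astype(str)
        frame = pd.DataFrame(
            np.asarray(scipy.sparse.coo_matrix(mat).todense(), dtype=float),
            index=genes,
            columns=cells,
        )
    elif fmt in {"tsv", "csv", "txt"}:
        sep = "," if fmt == "csv" else "\t"
        try:
            frame = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas names the line
            raise ValidationError(f"malformed expression file {path}: {exc}") from exc
        frame.index = frame.index.astype(str)
    else:
        raise ValidationError(f"unknown expression format {fmt!r}")
    if not genes_as_rows:
        frame = frame.T
    frame = _collapse_duplicate_genes(frame)
    values = frame.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValidationError(f"negative expression value in {path}")
    labels = _read_sample_labels(sample_labels)
    missing = [c for c in frame.columns if c not in labels]
    if missing:
        raise ValidationError(f"cells without sample label in {path}: {missing[:5]}")
    return ExpressionMatrix(
        gene_ids=list(frame.index),
        cell_ids=list(frame.columns),
        values=values,
        cell_sample={c: labels[c] for c in frame.columns},
    )


def read_regulation_pairs(
    paths: "Sequence[str | Path]",
    tf_universe: "GeneSet | Iterable[str] | None" = None,
) -> RegulationTable:
    """Merge TF->target pair files into a deduplicated :class:`RegulationTable`.

    The TF universe defaults to the union of first-column symbols across all
    files; a target is classified as a TF iff it belongs to that universe.
    Self-loop records are dropped with a warning.
    """
    raw_pairs: list[tuple[str, str, str]] = []
    for p in paths:
        p = Path(p)
        tab = pd.read_csv(p, sep="\t", header=None, dtype=str, comment="#")
        if tab.shape[1] < 2:
            raise ValidationError(f"regulation file {p} needs >= 2 columns")
        for tf, tgt in zip(tab.iloc[:, 0], tab.iloc[:, 1]):
            raw_pairs.append((str(tf), str(tgt), p.name))
    if tf_universe is None:
        tfs = {tf for tf, _, _ in raw_pairs}
    elif isinstance(tf_universe, GeneSet):
        tfs = set(tf_universe.genes)
    else:
        tfs = set(tf_universe)
    seen: dict[tuple[str, str], str] = {}
    n_loops = 0
    for tf, tgt, src in raw_pairs:
        if tf == tgt:
            n_loops += 1
            continue
        seen.setdefault((tf, tgt), src)
    if n_loops:
        logger.warning("dropped %d self-loop regulation records", n_loops)
    if not seen:
        raise ValidationError("regulation pair union is empty")
    records = [
        RegulationRecord(tf=tf, target=tgt, target_is_tf=tgt in tfs, source=src)
        for (tf, tgt), src in seen.items()
    ]
    return RegulationTable(records=records)


def read_gene_set(path: "str | Path", name: str | None = None) -> GeneSet:
    path = Path(path)
    genes = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    return GeneSet(name=name or path.stem, genes=set(genes))


def read_survival(path: "str | Path") -> SurvivalTable:
    frame = pd.read_csv(path, sep="\t")
    frame["sample_id"] = frame["sample_id"].astype(str)
    return SurvivalTable(frame=frame)


def read_bulk(path: "str | Path", normalized: bool = False) -> BulkMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame = _collapse_duplicate_genes(frame)
    return BulkMatrix(
        gene_ids=[str(g) for g in frame.index],
        sample_ids=[str(s) for s in frame.columns],
        values=frame.to_numpy(dtype=float),
        normalized=normalized,
    )


@dataclass
class ResultsBundle:
    """Everything the pipeline emits, as plain DataFrames keyed by stage."""

    consensus_genes: pd.DataFrame | None = None     # gene, support
    network_edges: pd.DataFrame | None = None       # tf, target, kind, similarity
    ffls: pd.DataFrame | None = None                # M, N, G
    cell_types: pd.DataFrame | None = None          # cell_id, sample, type
    biomarkers_per_type: pd.DataFrame | None = None # type, gene, d, q
    ranked_candidates: pd.DataFrame | None = None   # rank, gene, pcc, score
    km_tables: dict[str, pd.DataFrame] = field(default_factory=dict)


_BUNDLE_FILES = {
    "consensus_genes": "consensus_genes.tsv",
    "network_edges": "network_edges.tsv",
    "ffls": "ffls.tsv",
    "cell_types": "cell_types.tsv",
    "biomarkers_per_type": "biomarkers_per_type.tsv",
    "ranked_candidates": "ranked_candidates.tsv",
}


def write_results(bundle: ResultsBundle, out_dir: "str | Path") -> list[Path]:
    """Write every populated result table as TSV under ``out_dir``.

    Column order is fixed per table and ``ranked_candidates`` is written
    sorted by descending score with lexicographic gene-id tie-break, so two
    runs with the same inputs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for attr, fname in _BUNDLE_FILES.items():
        frame = getattr(bundle, attr)
        if frame is None:
            continue
        if attr == "ranked_candidates" and len(frame):
            frame = frame.sort_values(
                ["score", "gene"], ascending=[False, True], kind="mergesort"
            ).reset_index(drop=True)
            frame["rank"] = np.arange(1, len(frame) + 1)
        target = out_dir / fname
        frame.to_csv(target, sep="\t", index=False, float_format="%.10g")
        written.append(target)
    if bundle.km_tables:
        km_dir = out_dir / "km_tables"
        km_dir.mkdir(exist_ok=True)
        for gene in sorted(bundle.km_tables):
            target = km_dir / f"{gene}.tsv"
            bundle.km_tables[gene].to_csv(target, sep="\t", index=False, float_format="%.10g")
            written.append(target)
    return written


def read_network_edges(path: "str | Path") -> pd.DataFrame:
    """Round-trip reader for ``network_edges.tsv``."""
    frame = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str, "kind": str})
    return frame
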