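"""Core in-memory containers shared by every pipeline stage.

The pipeline moves four kinds of data around: a genes x cells single-cell
expression matrix with per-cell sample labels, a table of directed TF->target
regulation pairs, plain gene sets (e.g. known disease genes), and bulk
expression plus overall-survival clinical records.  Each container validates
its own invariants on construction so downstream stages can assume clean
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "RegulationTable",
    "GeneSet",
    "SurvivalTable",
    "BulkMatrix",
    "ValidationError",
]


class ValidationError(ValueError):
    """An input object violates a documented invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} id: {dup!r}")


@dataclass
class ExpressionMatrix:
    """Genes x cells nonnegative expression values with sample labels.

    Parameters
    ----------
    gene_ids, cell_ids
        Unique row / column identifiers.
    values
        Dense ``(n_genes, n_cells)`` array of finite, nonnegative reals.
    cell_sample
        Map ``cell_id -> sample_id``; every cell must be labeled.
    layer_tag
        One of ``{"raw", "normalized", "imputed"}``.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    cell_sample: dict[str, str]
    layer_tag: str = "raw"

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if self.layer_tag not in {"raw", "normalized", "imputed"}:
            raise ValidationError(f"unknown layer_tag {self.layer_tag!r}")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be nonnegative")
        missing = [c for c in self.cell_ids if c not in self.cell_sample]
        if missing:
            raise ValidationError(f"cells without sample label: {missing[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def samples(self) -> list[str]:
        """Sample ids in order of first appearance along cells."""
        seen: dict[str, None] = {}
        for c in self.cell_ids:
            seen.setdefault(self.cell_sample[c], None)
        return list(seen)

    def sample_labels(self) -> np.ndarray:
        return np.array([self.cell_sample[c] for c in self.cell_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in genes]
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in keep]
        return replace(self, gene_ids=keep, values=self.values[rows, :])

    def subset_cells(self, cells: Iterable[str]) -> "ExpressionMatrix":
        keep = [c for c in cells]
        idx = {c: i for i, c in enumerate(self.cell_ids)}
        cols = [idx[c] for c in keep]
        return replace(
            self,
            cell_ids=keep,
            values=self.values[:, cols],
            cell_sample={c: self.cell_sample[c] for c in keep},
        )

    def with_values(self, values: np.ndarray, layer_tag: str) -> "ExpressionMatrix":
        return replace(self, values=values, layer_tag=layer_tag)


@dataclass(frozen=True)
class RegulationRecord:
    tf: str
    target: str
    target_is_tf: bool
    source: str = ""


@dataclass
class RegulationTable:
    """Deduplicated directed TF->target regulation pairs.

    Self-loops are rejected; ``target_is_tf`` splits records into TF-TF and
    TF-gene pairs.
    """

    records: list[RegulationRecord]

    def __post_init__(self) -> None:
        keys = [(r.tf, r.target) for r in self.records]
        _check_unique([f"{a}->{b}" for a, b in keys], "regulation pair")
        for r in self.records:
            if r.tf == r.target:
                raise ValidationError(f"self-loop {r.tf!r} not allowed")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def tfs(self) -> set[str]:
        return {r.tf for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.tf, r.target, r.target_is_tf, r.source) for r in self.records],
            columns=["tf", "target", "target_is_tf", "source"],
        )


@dataclass
class GeneSet:
    name: str
    genes: set[str]

    def __post_init__(self) -> None:
        self.genes = set(self.genes)
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def sorted(self) -> list[str]:
        return sorted(self.genes)


@dataclass
class SurvivalTable:
    """Overall-survival records: (sample_id, time > 0, event in {0, 1})."""

    frame: pd.DataFrame  # columns: sample_id, time, event

    def __post_init__(self) -> None:
        f = self.frame
        required = {"sample_id", "time", "event"}
        if not required.issubset(f.columns):
            raise ValidationError(f"survival table needs columns {sorted(required)}")
        self.frame = f = f.loc[:, ["sample_id", "time", "event"]].reset_index(drop=True)
        _check_unique(list(f["sample_id"]), "survival sample")
        if (f["time"] <= 0).any():
            bad = f.loc[f["time"] <= 0, "sample_id"].iloc[0]
            raise ValidationError(f"nonpositive survival time for {bad!r}")
        if not set(f["event"].unique()).issubset({0, 1}):
            raise ValidationError("event indicator must be 0 or 1")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class BulkMatrix:
    """Genes x samples bulk expression; ``normalized`` marks per-gene z-scoring."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("bulk values shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("bulk values must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene), :]
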