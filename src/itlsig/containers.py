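"""Core in-memory containers shared across the pipeline.

The matrix convention throughout the package is genes as rows and cells (or
samples) as columns, matching the 10x features orientation used for on-disk
MatrixMarket triplets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .utils import check_unique


@dataclass
class CountMatrix:
    """Non-negative integer gene-by-cell expression matrix.

    Parameters
    ----------
    values
        2-D array of raw counts, shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Unique identifiers for rows and columns.
    mito_flags
        Boolean per gene marking mitochondrially encoded transcripts; drives
        the per-cell mitochondrial-percentage QC metric.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    mito_flags: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
        if self.values.ndim != 2:
            raise ValidationError("count matrix must be 2-D (genes x cells)")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"count matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.mito_flags.shape != (len(self.gene_ids),):
            raise ValidationError("mito_flags length must equal the gene count")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(np.mod(self.values, 1) == 0):
                raise ValidationError("count matrix entries must be integral")
            self.values = self.values.astype(np.int64)
        if self.values.size and self.values.min() < 0:
            raise ValidationError("count matrix entries must be non-negative")
        check_unique(self.gene_ids, "gene")
        check_unique(self.cell_ids, "cell")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        """Return a copy restricted to the cells where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_cells,):
            raise ValidationError("cell mask length must equal the cell count")
        kept = [c for c, m in zip(self.cell_ids, mask) if m]
        return CountMatrix(
            values=self.values[:, mask].copy(),
            gene_ids=list(self.gene_ids),
            cell_ids=kept,
            mito_flags=self.mito_flags.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class NormalizedMatrix:
    """Log-scale normalized expression, genes x cells, with its provenance.

    ``values[g, c] = log(pseudocount + scale * count[g, c] / total[c])`` with
    the natural logarithm and defaults scale=10,000, pseudocount=1.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    scale: float = 10_000.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError("normalized matrix shape mismatch")
        if self.values.size and self.values.min() < 0:
            raise ValidationError("normalized values must be non-negative")
        check_unique(self.gene_ids, "gene")
        check_unique(self.cell_ids, "cell")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def gene_vector(self, gene: str) -> pd.Series:
        if gene not in self.gene_ids:
            raise ValidationError(f"gene {gene!r} not in matrix")
        return pd.Series(
            self.values[self.gene_ids.index(gene)], index=self.cell_ids, name=gene
        )


@dataclass
class GeneSignature:
    """A named, ordered gene set (the unit of GMT input/output)."""

    name: str
    genes: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        if not self.name:
            raise ValidationError("signature name must be non-empty")
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} has no genes")
        seen: set[str] = set()
        for g in self.genes:
            if g in seen:
                raise ValidationError(
                    f"signature {self.name!r} contains duplicate gene {g!r}"
                )
            seen.add(g)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ModuleScores:
    """Per-cell module scores, one column per signature.

    ``scores`` is indexed by cell identifier; ``control_genes`` records, for
    each signature, the exact control pool drawn for the run so that scores
    can be re-derived step by step.
    """

    scores: pd.DataFrame
    params: dict[str, Any] = field(default_factory=dict)
    control_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy(dtype=float))):
            raise ValidationError("module scores must be finite")

    def columns(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class EnrichmentResult:
    """Preranked GSEA output for one signature."""

    es: float
    nes: float
    p_value: float
    n_permutations: int
    seed: int
    n_genes: int
    n_hits: int
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.es <= 1.0 + 1e-12:
            raise ValidationError(f"enrichment score {self.es} outside [-1, 1]")
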