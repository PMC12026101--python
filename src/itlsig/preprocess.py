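"""Cell-level quality control and normalization.

Cells are excluded when detected features < 500, total counts < 500, or the
mitochondrial read percentage exceeds 20%. All three inequalities are strict,
so boundary cells (exactly 500 features/counts, exactly 20%) pass. Counts are
then library-size normalized to a fixed scale and log-transformed; a
20-component PCA of the gene-centered matrix is available for completeness
but is not required by downstream scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .containers import CountMatrix, NormalizedMatrix
from .exceptions import EmptyResultError, ValidationError


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds; defaults follow the droplet scRNA-seq convention
    of dropping cells with <500 features or counts or >20% mitochondrial reads."""

    min_features: int = 500
    min_counts: int = 500
    max_pct_mito: float = 20.0


def compute_qc(counts: CountMatrix, thresholds: QCThresholds = QCThresholds()) -> pd.DataFrame:
    """Per-cell QC metrics and pass flag; removes nothing.

    Returns a DataFrame indexed by cell identifier with columns
    ``n_features`` (genes with count > 0), ``n_counts`` (column sum),
    ``pct_mito`` (mitochondrial share of total counts, in percent; 0 by
    convention for an all-zero cell) and ``pass_qc``.
    """
    if counts.n_cells == 0 or counts.n_genes == 0:
        raise ValidationError("cannot compute QC on an empty matrix")
    values = counts.values
    n_features = (values > 0).sum(axis=0)
    n_counts = values.sum(axis=0)
    mito = values[counts.mito_flags].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(n_counts > 0, 100.0 * mito / np.maximum(n_counts, 1), 0.0)
    passed = (
        (n_features >= thresholds.min_features)
        & (n_counts >= thresholds.min_counts)
        & (pct_mito <= thresholds.max_pct_mito)
    )
    return pd.DataFrame(
        {
            "n_features": n_features.astype(int),
            "n_counts": n_counts.astype(int),
            "pct_mito": pct_mito,
            "pass_qc": passed,
        },
        index=pd.Index(counts.cell_ids, name="cell_id"),
    )


def filter_cells(counts: CountMatrix, qc: pd.DataFrame) -> CountMatrix:
    """Column-subset to the cells whose QC flag is True.

    The QC report must cover exactly the matrix's cells; the input matrix is
    left unmodified. Raises EmptyResultError if no cell passes.
    """
    if list(qc.index) != list(counts.cell_ids):
        raise ValidationError("QC report cells do not match the count matrix")
    mask = qc["pass_qc"].to_numpy(dtype=bool)
    if not mask.any():
        raise EmptyResultError("no cells pass quality control")
    return counts.subset_cells(mask)


def log_normalize(
    counts: CountMatrix, scale: float = 10_000.0, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """Library-size normalization followed by a natural-log transform.

    ``value(g, c) = log(pseudocount + scale * count(g, c) / total(c))``.
    Cells with zero total counts must be removed by QC first.
    """
    if scale <= 0:
        raise ValidationError("scale must be positive")
    totals = counts.values.sum(axis=0)
    if (totals == 0).any():
        bad = [c for c, t in zip(counts.cell_ids, totals) if t == 0]
        raise ValidationError(
            f"cells with zero total counts (run QC filtering first): {bad[:5]}"
        )
    values = np.log(pseudocount + scale * counts.values / totals[np.newaxis, :])
    return NormalizedMatrix(
        values=values,
        gene_ids=list(counts.gene_ids),
        cell_ids=list(counts.cell_ids),
        scale=scale,
        pseudocount=pseudocount,
    )


def top_principal_components(norm: NormalizedMatrix, k: int = 20) -> pd.DataFrame:
    """Coordinates of cells on the top-k principal components.

    Cells are the observations and genes the (row-centered) variables. The
    sign convention fixes each component so that its largest-magnitude gene
    loading is positive.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > min(norm.n_genes, norm.n_cells):
        raise ValidationError("k cannot exceed min(genes, cells)")
    centered = norm.values - norm.values.mean(axis=1, keepdims=True)
    # cells x genes for SVD; coordinates = U * S.
    u, s, vt = scipy.linalg.svd(centered.T, full_matrices=False)
    tol = s[0] * max(centered.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if k > rank:
        raise ValidationError(f"k={k} exceeds matrix rank {rank}")
    flip = np.sign(vt[np.arange(k), np.argmax(np.abs(vt[:k]), axis=1)])
    flip[flip == 0] = 1.0
    coords = (u[:, :k] * s[:k]) * flip
    return pd.DataFrame(
        coords,
        index=pd.Index(norm.cell_ids, name="cell_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
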