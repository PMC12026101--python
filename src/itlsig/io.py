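"""Format readers and writers: 10x-style MatrixMarket triplets, dense TSV
matrices, GMT gene-set files, DEG tables, and TSV/JSON outputs with embedded
metadata headers.

Conventions: MTX uses 1-based indices with genes as rows (10x features
orientation); dense TSVs have genes as rows with the gene identifier in the
first column. Readers validate and reject malformed input rather than
coercing it. All readers are transparent to ``.gz`` compression.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Any, IO

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CountMatrix, GeneSignature
from .exceptions import ValidationError
from .utils import check_unique

DEFAULT_MITO_PREFIX = "MT-"


def _open_maybe_gz(path: Path, mode: str = "rt") -> IO:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise ValidationError(f"missing {stem}[.gz] in {dir_path}")


# ---------------------------------------------------------------------------
# MTX triplet
# ---------------------------------------------------------------------------

def read_mtx_triplet(dir_path: str | Path, mito_prefix: str = DEFAULT_MITO_PREFIX) -> CountMatrix:
    """Read a matrix.mtx / features.tsv / barcodes.tsv triplet."""
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, "matrix.mtx")
    feat_path = _find(dir_path, "features.tsv")
    bc_path = _find(dir_path, "barcodes.tsv")

    with _open_maybe_gz(mtx_path, "rb") as fh:
        mat = scipy.io.mmread(fh)
    mat = scipy.sparse.coo_matrix(mat)
    dense = np.asarray(mat.todense())
    if not np.all(np.mod(dense, 1) == 0):
        raise ValidationError(f"{mtx_path}: non-integer matrix entries")
    dense = dense.astype(np.int64)

    with _open_maybe_gz(feat_path) as fh:
        feats = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    gene_ids = [row[0] for row in feats]
    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]

    if dense.shape != (len(gene_ids), len(barcodes)):
        raise ValidationError(
            f"dimension mismatch: matrix {dense.shape}, "
            f"{len(gene_ids)} features, {len(barcodes)} barcodes"
        )
    check_unique(gene_ids, "gene")
    check_unique(barcodes, "barcode")
    mito = np.array([g.startswith(mito_prefix) for g in gene_ids])
    return CountMatrix(dense, gene_ids, barcodes, mito)


def write_mtx_triplet(counts: CountMatrix, dir_path: str | Path) -> None:
    """Write a CountMatrix as an uncompressed 10x-style triplet."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(counts.values)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), sparse, field="integer")
    with open(dir_path / "features.tsv", "w") as fh:
        for g in counts.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(dir_path / "barcodes.tsv", "w") as fh:
        for c in counts.cell_ids:
            fh.write(c + "\n")


# ---------------------------------------------------------------------------
# dense TSV matrices
# ---------------------------------------------------------------------------

def read_dense_counts(path: str | Path, mito_prefix: str = DEFAULT_MITO_PREFIX) -> CountMatrix:
    """Dense genes x cells TSV of integer counts (first column = gene id)."""
    df = read_expression_tsv(path)
    values = df.to_numpy()
    if not np.all(np.mod(values, 1) == 0):
        raise ValidationError(f"{path}: counts must be integral")
    mito = np.array([str(g).startswith(mito_prefix) for g in df.index])
    return CountMatrix(values.astype(np.int64), list(df.index), list(df.columns), mito)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Dense genes x samples TSV (first column = gene id, real values)."""
    with _open_maybe_gz(Path(path)) as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0, comment="#")
    if df.empty:
        raise ValidationError(f"{path}: empty expression table")
    check_unique([str(g) for g in df.index], "gene")
    check_unique([str(c) for c in df.columns], "sample")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric expression values: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    write_tsv(df, path, metadata=metadata, index_label="gene")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Read signatures from a tab-delimited GMT file (name, description,
    genes...). Malformed lines and within-set duplicates raise with context."""
    sigs: list[GeneSignature] = []
    with _open_maybe_gz(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            seen: set[str] = set()
            for g in genes:
                if g in seen:
                    raise ValidationError(
                        f"{path}:{lineno}: set {name!r} repeats gene {g!r}"
                    )
                seen.add(g)
            try:
                sigs.append(GeneSignature(name=name, genes=genes, description=desc))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    if not sigs:
        raise ValidationError(f"{path}: no gene sets found")
    check_unique([s.name for s in sigs], "gene set")
    return sigs


def write_gmt(signatures: list[GeneSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            desc = sig.description or "na"
            fh.write("\t".join([sig.name, desc, *sig.genes]) + "\n")


# ---------------------------------------------------------------------------
# DEG tables and generic typed tables
# ---------------------------------------------------------------------------

def read_deg_table(path: str | Path) -> pd.DataFrame:
    from .pipeline import validate_deg_table  # local import avoids a cycle

    with _open_maybe_gz(Path(path)) as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype={"gene": str})
    return validate_deg_table(df)


# ---------------------------------------------------------------------------
# outputs with metadata headers
# ---------------------------------------------------------------------------

def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    metadata: dict | None = None,
    index_label: str | None = None,
) -> None:
    """Write a TSV with '#'-prefixed metadata header lines (config snapshot)."""
    with open(path, "w") as fh:
        if metadata:
            fh.write("# itlsig metadata: " + json.dumps(metadata, sort_keys=True) + "\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    with _open_maybe_gz(Path(path)) as fh:
        # round_trip parsing keeps write/read cycles bit-exact
        return pd.read_csv(
            fh, sep="\t", comment="#", index_col=index_col,
            float_precision="round_trip",
        )


def write_json(obj: Any, path: str | Path, metadata: dict | None = None) -> None:
    payload = {"metadata": metadata or {}, "result": obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
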