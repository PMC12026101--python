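"""Enrichment statistics: per-cell module scores, per-sample ssGSEA, and
preranked GSEA with a permutation-normalized enrichment score.

Module scores
-------------
The per-cell module score of a signature is the mean normalized expression of
the signature genes minus the mean expression of a matched control pool. All
genes are partitioned into ``nbins`` bins of near-equal size by mean
expression across cells; for each signature gene, ``ctrl`` genes are sampled
without replacement from that gene's bin, and the union of these draws (one
shared draw per signature per run, seeded) forms the control pool. Matching
controls on expression level removes the depth/abundance component of the
signature mean, so a score near zero means "no different from expression-
matched background".

ssGSEA
------
The single-sample score ranks a sample's genes by descending expression and
accumulates the difference between a weighted in-set ECDF (weights =
rank value ** alpha, alpha = 0.75 by default) and the uniform out-of-set
ECDF. Being rank-based, it is invariant under strictly monotone transforms
of the expression vector.

Preranked GSEA
--------------
The enrichment score is the maximum deviation of the classic running sum
(hit increments proportional to |metric|, miss decrements uniform). The null
is generated by permuting gene labels, i.e. re-drawing which positions of the
ranked list are signature hits; NES divides the observed ES by the mean
magnitude of same-sign permutation scores, and the p-value is the same-sign
tail frequency with a +1 correction.

Tie-breaking everywhere is by gene identifier so results are deterministic.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .containers import EnrichmentResult, GeneSignature, ModuleScores, NormalizedMatrix
from .exceptions import ValidationError
from .utils import derive_seed

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# module scores
# ---------------------------------------------------------------------------

def bin_genes_by_mean(norm: NormalizedMatrix, nbins: int = 30) -> pd.Series:
    """Partition genes into ``nbins`` near-equal bins by ascending mean
    expression across cells; ties broken by gene identifier.

    Returns a Series gene -> bin index (0-based; bin means non-decreasing in
    the index). Near-equal: bin sizes differ by at most one, with the larger
    bins at the low-expression end.
    """
    if nbins < 1:
        raise ValidationError("nbins must be >= 1")
    if norm.n_genes < nbins:
        raise ValidationError(
            f"need at least nbins={nbins} genes, have {norm.n_genes}"
        )
    means = norm.values.mean(axis=1)
    order = sorted(range(norm.n_genes), key=lambda i: (means[i], norm.gene_ids[i]))
    assignment: dict[str, int] = {}
    for b, chunk in enumerate(np.array_split(np.array(order), nbins)):
        for i in chunk:
            assignment[norm.gene_ids[int(i)]] = b
    return pd.Series(assignment, name="bin").reindex(norm.gene_ids)


def _present_genes(norm: NormalizedMatrix, sig: GeneSignature) -> list[str]:
    present = [g for g in sig.genes if g in set(norm.gene_ids)]
    missing = [g for g in sig.genes if g not in set(norm.gene_ids)]
    if missing:
        logger.warning(
            "signature %s: %d/%d genes absent from matrix and dropped: %s",
            sig.name, len(missing), len(sig.genes), ", ".join(missing[:10]),
        )
    if not present:
        raise ValidationError(
            f"no gene of signature {sig.name!r} is present in the matrix"
        )
    return present


def module_score(
    norm: NormalizedMatrix,
    sig: GeneSignature,
    nbins: int = 30,
    ctrl: int = 100,
    seed: int = 0,
    bins: pd.Series | None = None,
) -> tuple[pd.Series, list[str]]:
    """Per-cell module score for one signature.

    For each signature gene present in the matrix, ``ctrl`` control genes are
    sampled without replacement from that gene's expression bin (the whole
    bin if it holds fewer than ``ctrl`` genes); the union of the draws is the
    control pool, drawn once per signature per run from a stream seeded by
    ``(seed, signature name)``. Returns the score Series (indexed by cell)
    and the control pool actually used, in sorted order.
    """
    present = _present_genes(norm, sig)
    if bins is None:
        bins = bin_genes_by_mean(norm, nbins)
    rng = np.random.default_rng(derive_seed(seed, f"module_score:{sig.name}"))

    bin_members: dict[int, list[str]] = {}
    for b in sorted(bins.unique()):
        bin_members[int(b)] = sorted(bins.index[bins == b])

    control_pool: set[str] = set()
    for g in present:
        b = int(bins.loc[g])
        members = bin_members[b]
        size = min(ctrl, len(members))
        draw = rng.choice(members, size=size, replace=False)
        control_pool.update(draw.tolist())
    controls = sorted(control_pool)

    frame = norm.to_frame()
    sig_mean = frame.loc[present].mean(axis=0)
    ctrl_mean = frame.loc[controls].mean(axis=0)
    score = (sig_mean - ctrl_mean).rename(sig.name)
    score.index.name = "cell_id"
    return score, controls


def score_signatures(
    norm: NormalizedMatrix,
    signatures: list[GeneSignature],
    nbins: int = 30,
    ctrl: int = 100,
    seed: int = 0,
) -> ModuleScores:
    """Score several signatures against one matrix, sharing the bin partition."""
    if not signatures:
        raise ValidationError("no signatures given")
    bins = bin_genes_by_mean(norm, nbins)
    cols: dict[str, pd.Series] = {}
    controls: dict[str, list[str]] = {}
    for sig in signatures:
        score, ctrl_genes = module_score(norm, sig, nbins=nbins, ctrl=ctrl, seed=seed, bins=bins)
        cols[sig.name] = score
        controls[sig.name] = ctrl_genes
    scores = pd.DataFrame(cols)
    scores.index.name = "cell_id"
    return ModuleScores(
        scores=scores,
        params={"nbins": nbins, "ctrl": ctrl, "seed": seed},
        control_genes=controls,
    )


_PAIRS = {"MES": ("MES1", "MES2"), "NPC": ("NPC1", "NPC2")}
_PASSTHROUGH = ("AC", "OPC")


def average_paired_scores(scores: ModuleScores) -> ModuleScores:
    """Consolidate the six raw state scores into four: MES = mean(MES1, MES2),
    NPC = mean(NPC1, NPC2); AC and OPC pass through unchanged. Any additional
    columns (e.g. an ITL score) also pass through."""
    df = scores.scores
    needed = [c for pair in _PAIRS.values() for c in pair] + list(_PASSTHROUGH)
    for col in needed:
        if col not in df.columns:
            raise ValidationError(f"missing module-score column {col!r}")
    out = pd.DataFrame(index=df.index)
    for name, (a, b) in _PAIRS.items():
        out[name] = (df[a] + df[b]) / 2.0
    for col in _PASSTHROUGH:
        out[col] = df[col]
    extra = [c for c in df.columns if c not in needed]
    for col in extra:
        out[col] = df[col]
    out = out[["MES", "AC", "OPC", "NPC"] + extra]
    return ModuleScores(scores=out, params=dict(scores.params), control_genes=dict(scores.control_genes))


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def ssgsea_score(expr: pd.Series, sig: GeneSignature, alpha: float = 0.75) -> float:
    """Single-sample enrichment score of ``sig`` in one expression vector.

    Genes are ordered by descending expression (ties broken by gene
    identifier); the gene at descending position i (1-based) carries rank
    value N - i + 1. The score is the sum over positions of the difference
    between the in-set ECDF weighted by rank value ** alpha and the uniform
    out-of-set ECDF.
    """
    if expr.index.has_duplicates:
        raise ValidationError("expression vector has duplicate gene identifiers")
    genes = list(expr.index)
    in_set = set(sig.genes) & set(genes)
    if not in_set:
        raise ValidationError(f"signature {sig.name!r} has no overlap with the vector")
    if len(in_set) == len(genes):
        raise ValidationError(
            f"signature {sig.name!r} covers every gene: out-of-set ECDF undefined"
        )
    order = sorted(genes, key=lambda g: (-float(expr[g]), g))
    n = len(order)
    rank_value = np.arange(n, 0, -1, dtype=float)
    hit = np.array([g in in_set for g in order])
    weights = np.where(hit, rank_value**alpha, 0.0)
    p_in = np.cumsum(weights) / weights.sum()
    p_out = np.cumsum(~hit) / (n - len(in_set))
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    expr: pd.DataFrame,
    signatures: list[GeneSignature],
    alpha: float = 0.75,
    normalize_range: bool = False,
) -> pd.DataFrame:
    """ssGSEA scores for a genes x samples table; rows samples, columns
    signatures. With ``normalize_range`` each signature column is divided by
    its score range across the cohort (a common reporting variant)."""
    out = pd.DataFrame(
        {
            sig.name: [ssgsea_score(expr[s], sig, alpha=alpha) for s in expr.columns]
            for sig in signatures
        },
        index=pd.Index(expr.columns, name="sample_id"),
    )
    if normalize_range:
        rng_ = out.max(axis=0) - out.min(axis=0)
        if (rng_ == 0).any():
            raise ValidationError("zero score range; cannot range-normalize")
        out = out / rng_
    return out


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def _rank_order(metric: pd.Series) -> pd.Series:
    if metric.index.has_duplicates:
        raise ValidationError("ranking metric has duplicate gene identifiers")
    if not np.all(np.isfinite(metric.to_numpy(dtype=float))):
        raise ValidationError("ranking metric must be finite")
    order = sorted(metric.index, key=lambda g: (-float(metric[g]), g))
    return metric.reindex(order)


def enrichment_score(metric: pd.Series, sig: GeneSignature) -> tuple[float, np.ndarray]:
    """Observed ES and the full running sum for a ranked list.

    The list is ordered by descending metric (ties by gene identifier); hits
    advance the sum by |metric| / sum of hit |metric|, misses retreat it by
    1 / (N - n_hits). ES is the running-sum value of largest magnitude
    (earliest position on ties).
    """
    ranked = _rank_order(metric)
    hit = np.array([g in set(sig.genes) for g in ranked.index])
    if not hit.any():
        raise ValidationError(f"signature {sig.name!r} has no overlap with the ranking")
    if hit.all():
        raise ValidationError(f"signature {sig.name!r} covers the whole ranking")
    running = _running_sum(np.abs(ranked.to_numpy(dtype=float)), hit)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), running


def _running_sum(absmetric: np.ndarray, hit: np.ndarray) -> np.ndarray:
    n = absmetric.size
    nh = int(hit.sum())
    nr = absmetric[hit].sum()
    if nr == 0:
        # All hit metrics are exactly zero; fall back to uniform increments.
        inc = np.where(hit, 1.0 / nh, 0.0)
    else:
        inc = np.where(hit, absmetric / nr, 0.0)
    dec = np.where(hit, 0.0, 1.0 / (n - nh))
    return np.cumsum(inc - dec)


def _es_for_hit_matrix(absmetric: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """Vectorized ES for a (n_perm, N) boolean hit matrix."""
    n = absmetric.size
    nh = hits.sum(axis=1)
    nr = hits @ absmetric
    nr = np.where(nr == 0, 1.0, nr)  # degenerate rows handled as uniform below
    inc = np.where(hits, absmetric[np.newaxis, :] / nr[:, np.newaxis], 0.0)
    zero_rows = (hits @ absmetric) == 0
    if zero_rows.any():
        inc[zero_rows] = np.where(hits[zero_rows], 1.0 / nh[zero_rows, np.newaxis], 0.0)
    dec = np.where(hits, 0.0, 1.0 / (n - nh)[:, np.newaxis])
    running = np.cumsum(inc - dec, axis=1)
    peaks = np.argmax(np.abs(running), axis=1)
    return running[np.arange(running.shape[0]), peaks]


def preranked_gsea(
    metric: pd.Series,
    sig: GeneSignature,
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> EnrichmentResult:
    """Preranked GSEA with gene-label permutation NES and p-value.

    The null re-draws which ranked positions are signature hits (all
    ``C(N, n_hits)`` subsets when ``exhaustive`` and the count is feasible,
    otherwise ``n_perm`` uniform draws). NES = ES / mean(|ES*|) over
    same-sign permutation scores; p = same-sign tail frequency with a +1
    correction, so its resolution is 1 / (n_null + 1).
    """
    warnings: list[str] = []
    if n_perm < 10:
        warnings.append(f"n_perm={n_perm} is very small; p-value resolution is poor")
    ranked = _rank_order(metric)
    absmetric = np.abs(ranked.to_numpy(dtype=float))
    hit = np.array([g in set(sig.genes) for g in ranked.index])
    es, _ = enrichment_score(metric, sig)
    n, nh = hit.size, int(hit.sum())

    if exhaustive and comb(n, nh) <= 200_000:
        null_es = np.empty(comb(n, nh))
        base = np.zeros(n, dtype=bool)
        for i, idx in enumerate(combinations(range(n), nh)):
            h = base.copy()
            h[list(idx)] = True
            null_es[i] = _es_for_hit_matrix(absmetric, h[np.newaxis, :])[0]
        n_used = null_es.size
    else:
        if exhaustive:
            warnings.append("exhaustive enumeration infeasible; falling back to sampling")
        rng = np.random.default_rng(derive_seed(seed, f"gsea:{sig.name}"))
        hits = np.zeros((n_perm, n), dtype=bool)
        for i in range(n_perm):
            hits[i, rng.choice(n, size=nh, replace=False)] = True
        null_es = _es_for_hit_matrix(absmetric, hits)
        n_used = n_perm

    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    if n_same == 0 or np.abs(null_es[same_sign]).mean() == 0:
        nes = float("nan")
        warnings.append("no same-sign permutation scores; NES undefined")
        p = 1.0
    else:
        nes = es / np.abs(null_es[same_sign]).mean()
        p = (1 + int((np.abs(null_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)
    return EnrichmentResult(
        es=es,
        nes=float(nes),
        p_value=float(p),
        n_permutations=n_used,
        seed=seed,
        n_genes=n,
        n_hits=nh,
        warnings=warnings,
    )
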