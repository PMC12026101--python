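"""Signature derivation and the statistical battery around it.

Covers the derivation chain (strict-threshold selection of significant
up-regulated genes, ordered multi-list intersection), median high/low cohort
splits, transcript detection calls, scoring of the six-gene immunosuppressive
Treg-like (ITL) signature in bulk samples and single cells, Pearson
correlation panels with Benjamini-Hochberg adjustment, and named
group-comparison tests (Student's t, one-way ANOVA with Tukey HSD,
Mann-Whitney U, Kruskal-Wallis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .containers import GeneSignature, NormalizedMatrix
from .exceptions import ValidationError
from .scoring import module_score, ssgsea_score

#: The six-gene TGFBR2-induced immunosuppressive Treg-like signature:
#: PD-L1, CD73, CD39, galectin-1, PD-L2 and TGFB1.
ITL_SIGNATURE = GeneSignature(
    name="TGFBR2_ITL",
    genes=["CD274", "NT5E", "ENTPD1", "LGALS1", "PDCD1LG2", "TGFB1"],
    description="TGFBR2-induced immunosuppressive Treg-like effector genes",
)

DEG_COLUMNS = ("gene", "log2FC", "pvalue", "padj")


def validate_deg_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a differential-expression table against the expected schema."""
    for col in DEG_COLUMNS:
        if col not in table.columns:
            raise ValidationError(f"DEG table missing required column {col!r}")
    if table["gene"].duplicated().any():
        dup = table.loc[table["gene"].duplicated(), "gene"].iloc[0]
        raise ValidationError(f"DEG table has duplicate gene {dup!r}")
    lfc = table["log2FC"].to_numpy(dtype=float)
    if not np.all(np.isfinite(lfc)):
        raise ValidationError("DEG table log2FC must be finite")
    for col in ("pvalue", "padj"):
        v = table[col].to_numpy(dtype=float)
        if np.any((v < 0) | (v > 1) | ~np.isfinite(v)):
            raise ValidationError(f"DEG table column {col!r} must lie in [0, 1]")
    return table


def significant_up(
    table: pd.DataFrame, padj_max: float = 0.05, lfc_min: float = 0.0
) -> list[str]:
    """Genes with ``padj < padj_max`` and ``log2FC > lfc_min`` (both strict),
    ordered by ascending padj then gene identifier."""
    if not 0 < padj_max <= 1:
        raise ValidationError("padj_max must be in (0, 1]")
    validate_deg_table(table)
    hits = table[(table["padj"] < padj_max) & (table["log2FC"] > lfc_min)]
    hits = hits.sort_values(["padj", "gene"], kind="mergesort")
    return hits["gene"].tolist()


@dataclass
class IntersectionResult:
    """Ordered record of a staged gene-list intersection."""

    stages: list[tuple[str, list[str]]]
    intersection: list[str]
    params: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "stages": {name: genes for name, genes in self.stages},
            "intersection": self.intersection,
            "params": self.params,
        }


def intersect_stages(
    lists: list[list[str]],
    names: list[str] | None = None,
    params: dict[str, Any] | None = None,
) -> IntersectionResult:
    """Set intersection of ordered gene lists, preserving the first list's
    order; all stage lists are retained for audit."""
    if len(lists) < 2:
        raise ValidationError("need at least two gene lists to intersect")
    if names is None:
        names = [f"stage{i + 1}" for i in range(len(lists))]
    if len(names) != len(lists):
        raise ValidationError("one name per stage list is required")
    common = set(lists[0])
    for other in lists[1:]:
        common &= set(other)
    final = [g for g in lists[0] if g in common]
    return IntersectionResult(
        stages=[(n, list(l)) for n, l in zip(names, lists)],
        intersection=final,
        params=params or {},
    )


def median_split(values: pd.Series, gene_label: str = "") -> pd.Series:
    """Dichotomize samples at the median of ``values``.

    Samples strictly above the median are "high"; samples at or below it are
    "low" (deterministic tie rule). Raises if fewer than two samples, all
    values are identical, or either group would be empty.
    """
    if len(values) < 2:
        raise ValidationError("median split needs at least 2 samples")
    v = values.to_numpy(dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValidationError("median split requires finite values")
    if np.all(v == v[0]):
        raise ValidationError(
            f"all values identical{f' for {gene_label}' if gene_label else ''}; no split exists"
        )
    med = float(np.median(v))
    labels = pd.Series(np.where(v > med, "high", "low"), index=values.index, name="group")
    if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
        raise ValidationError("median split produced an empty group")
    return labels


def detect_expressed(
    norm: NormalizedMatrix, genes: list[str], min_frac: float = 0.01
) -> pd.Series:
    """Detection call per gene: nonzero in at least ``min_frac`` of cells
    (inclusive). Genes absent from the matrix are undetected."""
    if not genes:
        raise ValidationError("empty gene list")
    if not 0 < min_frac <= 1:
        raise ValidationError("min_frac must be in (0, 1]")
    idx = {g: i for i, g in enumerate(norm.gene_ids)}
    out = {}
    for g in genes:
        if g not in idx:
            out[g] = False
        else:
            frac = float((norm.values[idx[g]] > 0).mean())
            out[g] = frac >= min_frac
    return pd.Series(out, name="detected")


def itl_score_bulk(
    expr: pd.DataFrame, sig: GeneSignature = ITL_SIGNATURE, alpha: float = 0.75
) -> pd.Series:
    """Per-sample ITL activity: ssGSEA score of the signature in each sample
    of a genes x samples expression table."""
    scores = pd.Series(
        {s: ssgsea_score(expr[s], sig, alpha=alpha) for s in expr.columns},
        name=sig.name,
    )
    scores.index.name = "sample_id"
    return scores


def itl_score_cells(
    norm: NormalizedMatrix,
    sig: GeneSignature = ITL_SIGNATURE,
    nbins: int = 30,
    ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-cell ITL activity: expression-matched module score of the
    signature in a normalized single-cell matrix."""
    score, _ = module_score(norm, sig, nbins=nbins, ctrl=ctrl, seed=seed)
    return score


@dataclass
class CorrelationPanel:
    """All-pairs Pearson panel over a samples x variables table."""

    r: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    n: pd.DataFrame
    params: dict[str, Any] = field(default_factory=dict)


def correlation_panel(table: pd.DataFrame) -> CorrelationPanel:
    """Pairwise Pearson r with two-sided p and BH adjustment.

    Observations are rows (samples), variables are columns. Pairs are handled
    pairwise-complete (rows with a missing value in either variable are
    dropped for that pair; each pair needs >= 3 complete observations).
    Zero-variance pairs get NaN entries. BH is applied over the upper
    triangle and mirrored; the diagonal is r = 1 with p left NaN.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValidationError("correlation panel needs at least two variables")
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    np.fill_diagonal(r, 1.0)
    for i in range(k):
        n[i, i] = int(table[cols[i]].notna().sum())
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            sub = table[[cols[i], cols[j]]].dropna()
            n[i, j] = n[j, i] = len(sub)
            if len(sub) < 3:
                raise ValidationError(
                    f"pair ({cols[i]}, {cols[j]}) has fewer than 3 complete observations"
                )
            x = sub[cols[i]].to_numpy(dtype=float)
            y = sub[cols[j]].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                pairs.append((i, j, np.nan))
                continue
            rr, pp = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = float(rr)
            p[i, j] = p[j, i] = float(pp)
            pairs.append((i, j, float(pp)))

    p_adj = np.full((k, k), np.nan)
    defined = [(i, j) for i, j, pp in pairs if np.isfinite(pp)]
    if defined:
        raw = [p[i, j] for i, j in defined]
        adj = multipletests(raw, method="fdr_bh")[1]
        for (i, j), a in zip(defined, adj):
            p_adj[i, j] = p_adj[j, i] = float(a)

    idx = pd.Index(cols)
    return CorrelationPanel(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        p_adj=pd.DataFrame(p_adj, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        params={"method": "pearson", "adjust": "benjamini-hochberg"},
    )


@dataclass
class GroupComparison:
    """Result of a named group-comparison test."""

    test: str
    statistic: float
    p_value: float
    group_sizes: dict[str, int]
    posthoc: pd.DataFrame | None = None

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_sizes": self.group_sizes,
        }
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        return d


VALID_TESTS = ("t", "anova", "mannwhitney", "kruskal")


def _mannwhitney_asymptotic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U, tie-corrected normal approximation without
    continuity correction (identical distributions give p = 1 exactly)."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    nt = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (nt * (nt - 1))
    sigma2 = n1 * n2 / 12.0 * (nt + 1 - tie_term)
    if sigma2 <= 0:
        return float(u1), 1.0
    z = (u1 - mu) / np.sqrt(sigma2)
    return float(u1), float(2.0 * stats.norm.sf(abs(z)))


def compare_groups(values: pd.Series, groups: pd.Series, test: str) -> GroupComparison:
    """Run the named test (never auto-selected) on ``values`` split by
    ``groups``; "t" and "mannwhitney" require exactly two groups, "anova"
    adds a Tukey HSD pairwise table."""
    if test not in VALID_TESTS:
        raise ValidationError(f"unknown test {test!r}; valid: {VALID_TESTS}")
    groups = groups.reindex(values.index)
    if groups.isna().any():
        raise ValidationError("group labels do not cover every observation")
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValidationError("need at least two groups")
    arrays = [values[groups == g].to_numpy(dtype=float) for g in levels]
    sizes = {str(g): len(a) for g, a in zip(levels, arrays)}
    if test in ("t", "anova") and any(len(a) < 2 for a in arrays):
        raise ValidationError(f"test {test!r} requires n >= 2 in every group")

    posthoc = None
    if test == "t":
        if len(levels) != 2:
            raise ValidationError("t-test requires exactly two groups")
        stat, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
    elif test == "mannwhitney":
        if len(levels) != 2:
            raise ValidationError("Mann-Whitney requires exactly two groups")
        stat, p = _mannwhitney_asymptotic(arrays[0], arrays[1])
    elif test == "kruskal":
        stat, p = stats.kruskal(*arrays)
    else:  # anova
        stat, p = stats.f_oneway(*arrays)
        tk = pairwise_tukeyhsd(
            values.to_numpy(dtype=float), groups.astype(str).to_numpy()
        )
        posthoc = pd.DataFrame(
            tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
        )
    return GroupComparison(
        test=test,
        statistic=float(stat),
        p_value=float(p),
        group_sizes=sizes,
        posthoc=posthoc,
    )
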