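"""Synthetic inputs with recorded ground truth.

Three generators emulate the data families the analysis consumes:

* droplet-style scRNA-seq counts with six planted GBM state programs
  (MES1, MES2, AC, OPC, NPC1, NPC2), a mitochondrial gene block and an
  optional fraction of deliberately low-quality cells;
* bulk expression cohorts with planted gene-vs-signature Pearson
  correlations;
* triplets of differential-expression tables whose significant-up sets have
  a known intersection.

Counts follow a negative binomial with mean/dispersion parameterization
(variance = mu + mu^2/theta), the standard desk-scale surrogate for droplet
unique-molecule counts. Every generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .exceptions import ConfigurationError
from .utils import check_unique

STATES: tuple[str, ...] = ("MES1", "MES2", "AC", "OPC", "NPC1", "NPC2")

#: Human mitochondrially encoded protein-coding genes; gives the QC stage's
#: "MT-" prefix convention something real to flag.
MITO_GENES: tuple[str, ...] = (
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
)

#: Detected-feature count below which a cell is (by construction) low quality.
LOW_QUALITY_FEATURES = 500


@dataclass
class SimConfig:
    """Configuration of the single-cell count simulator.

    Parameters
    ----------
    n_cells_per_state
        Cells generated for each of the six state programs.
    n_background_genes
        Genes with no state association.
    markers_per_state
        Marker genes uplifted in cells of their own state.
    uplift
        Multiplicative mean shift of a state's markers within that state;
        ``uplift = 1`` is the no-signal null.
    nb_mean, nb_dispersion
        Baseline negative-binomial mean and dispersion (theta).
    mito_fraction_low, mito_fraction_high
        Per-cell mitochondrial read proportion is drawn uniformly from this
        interval.
    frac_low_quality
        Fraction (of the normal cell count) of additional cells downsampled
        below the detected-feature QC threshold.
    planted_programs
        Optional extra programs: name -> (gene list, state list); the genes
        are added to the universe and uplifted in cells of the listed states.
        Keeps per-state marker lists disjoint while letting a gene set (e.g.
        the six ITL genes) ride on both MES programs.
    """

    n_cells_per_state: int = 200
    n_background_genes: int = 2000
    markers_per_state: int = 50
    uplift: float = 4.0
    nb_mean: float = 2.0
    nb_dispersion: float = 2.0
    mito_fraction_low: float = 0.01
    mito_fraction_high: float = 0.10
    frac_low_quality: float = 0.0
    seed: int = 0
    planted_programs: dict[str, tuple[list[str], list[str]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.n_cells_per_state < 1:
            raise ConfigurationError("n_cells_per_state must be >= 1")
        if self.n_background_genes < 1:
            raise ConfigurationError("n_background_genes must be >= 1")
        if self.markers_per_state < 1:
            raise ConfigurationError("markers_per_state must be >= 1")
        if self.uplift < 1.0:
            raise ConfigurationError("uplift must be >= 1 (1 = no signal)")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ConfigurationError("nb_mean and nb_dispersion must be positive")
        if not 0.0 <= self.mito_fraction_low <= self.mito_fraction_high <= 1.0:
            raise ConfigurationError(
                "need 0 <= mito_fraction_low <= mito_fraction_high <= 1"
            )
        if not 0.0 <= self.frac_low_quality < 1.0:
            raise ConfigurationError("frac_low_quality must be in [0, 1)")
        for name, (genes, states) in self.planted_programs.items():
            if not genes or not states:
                raise ConfigurationError(f"program {name!r} needs genes and states")
            for s in states:
                if s not in STATES:
                    raise ConfigurationError(f"program {name!r}: unknown state {s!r}")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["planted_programs"] = {
            k: [list(v[0]), list(v[1])] for k, v in self.planted_programs.items()
        }
        return d


@dataclass
class GroundTruth:
    """Machine-readable truth emitted alongside every synthetic artifact."""

    cell_state_labels: dict[str, str] = field(default_factory=dict)
    marker_assignment: dict[str, list[str]] = field(default_factory=dict)
    low_quality_cells: list[str] = field(default_factory=list)
    planted_programs: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    planted_correlations: dict[str, tuple[str, float]] = field(default_factory=dict)
    expected_intersection: list[str] = field(default_factory=list)
    boundary_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["planted_correlations"] = {
            g: [s, r] for g, (s, r) in self.planted_correlations.items()
        }
        return d


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Negative-binomial draw with mean mu and dispersion theta."""
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p)


def simulate_sc_counts(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Generate a gene x cell count matrix with planted state programs.

    Marker genes of state *k* have negative-binomial mean
    ``uplift * nb_mean`` in cells labeled *k* and ``nb_mean`` elsewhere.
    A mitochondrial block ("MT-" genes) is appended whose per-cell share of
    total counts is drawn uniformly from the configured interval. If
    ``frac_low_quality > 0``, that fraction (of the normal cell count) of
    extra cells is generated normally and then binomially downsampled until
    fewer than 500 features are detected, giving QC filtering an unambiguous
    target.
    """
    rng = np.random.default_rng(config.seed)

    marker_assignment = {
        s: [f"{s}-M{i:03d}" for i in range(config.markers_per_state)] for s in STATES
    }
    marker_genes = [g for s in STATES for g in marker_assignment[s]]
    program_genes: list[str] = []
    for name, (genes, _states) in config.planted_programs.items():
        program_genes.extend(genes)
    background = [f"BG{i:05d}" for i in range(config.n_background_genes)]
    nonmito_genes = marker_genes + program_genes + background
    check_unique(nonmito_genes, "gene")
    gene_ids = nonmito_genes + list(MITO_GENES)

    n_normal = len(STATES) * config.n_cells_per_state
    n_lowq = int(round(config.frac_low_quality * n_normal))
    labels = [s for s in STATES for _ in range(config.n_cells_per_state)]
    labels += [STATES[i % len(STATES)] for i in range(n_lowq)]
    n_cells = n_normal + n_lowq
    cell_ids = [f"C{i:05d}" for i in range(n_cells)]

    # Mean matrix for non-mitochondrial genes.
    mu = np.full((len(nonmito_genes), n_cells), config.nb_mean, dtype=float)
    gene_pos = {g: i for i, g in enumerate(nonmito_genes)}
    state_cols = {s: np.array([j for j, l in enumerate(labels) if l == s]) for s in STATES}
    for s in STATES:
        rows = [gene_pos[g] for g in marker_assignment[s]]
        mu[np.ix_(rows, state_cols[s])] *= config.uplift
    for name, (genes, prog_states) in config.planted_programs.items():
        rows = [gene_pos[g] for g in genes]
        for s in prog_states:
            mu[np.ix_(rows, state_cols[s])] *= config.uplift

    counts = _nb_draw(rng, mu, config.nb_dispersion)

    # Mitochondrial block: per-cell target read share f, so the mito total is
    # f/(1-f) times the nuclear total, split multinomially across MT genes.
    frac = rng.uniform(config.mito_fraction_low, config.mito_fraction_high, n_cells)
    nuclear_tot = counts.sum(axis=0)
    mito_tot = np.round(frac / (1.0 - np.clip(frac, None, 0.999)) * nuclear_tot)
    mito_counts = np.zeros((len(MITO_GENES), n_cells), dtype=np.int64)
    p_equal = np.full(len(MITO_GENES), 1.0 / len(MITO_GENES))
    for j in range(n_cells):
        mito_counts[:, j] = rng.multinomial(int(mito_tot[j]), p_equal)
    values = np.vstack([counts, mito_counts]).astype(np.int64)

    # Force the designated low-quality cells below the feature threshold by
    # repeated binomial thinning (keeps composition unbiased in expectation).
    target = min(LOW_QUALITY_FEATURES, max(1, len(gene_ids)))
    lowq_ids = cell_ids[n_normal:]
    for j in range(n_normal, n_cells):
        for _ in range(40):
            if (values[:, j] > 0).sum() < target:
                break
            values[:, j] = rng.binomial(values[:, j], 0.5)

    mito_flags = np.array([g.startswith("MT-") for g in gene_ids])
    matrix = CountMatrix(values, gene_ids, cell_ids, mito_flags)
    truth = GroundTruth(
        cell_state_labels=dict(zip(cell_ids, labels)),
        marker_assignment=marker_assignment,
        low_quality_cells=lowq_ids,
        planted_programs={
            name: {"genes": list(genes), "states": list(states)}
            for name, (genes, states) in config.planted_programs.items()
        },
    )
    return matrix, truth


def simulate_bulk_cohort(
    n_samples: int,
    planted: dict[str, tuple[str, float]],
    seed: int,
    *,
    genes_per_signature: int = 10,
    n_noise_genes: int = 50,
    baseline: float = 8.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a bulk expression table with planted gene-signature correlations.

    Each referenced signature gets a latent activity ``z ~ N(0, 1)`` shared by
    its member genes (member = baseline + z + 0.05 * noise, so a mean-based
    signature score is essentially z). A planted gene with target correlation
    r is ``baseline + r * z + sqrt(1 - r^2) * noise``, making its population
    Pearson correlation with the latent activity exactly r.

    Returns a genes x samples DataFrame (log-scale units, arbitrary baseline)
    plus ground truth recording membership and planted correlations.
    """
    if n_samples < 3:
        raise ConfigurationError("need at least 3 samples")
    for gene, (sig, r) in planted.items():
        if not abs(r) < 1.0:
            raise ConfigurationError(
                f"planted correlation for {gene!r} must satisfy |r| < 1, got {r}"
            )
    rng = np.random.default_rng(seed)
    signatures = sorted({sig for sig, _ in planted.values()})

    members = {
        sig: [f"{sig}-G{i:02d}" for i in range(genes_per_signature)]
        for sig in signatures
    }
    rows: list[str] = []
    data: list[np.ndarray] = []
    latent = {sig: rng.standard_normal(n_samples) for sig in signatures}
    for sig in signatures:
        for g in members[sig]:
            rows.append(g)
            data.append(latent[sig] + 0.05 * rng.standard_normal(n_samples))
    for gene in planted:
        sig, r = planted[gene]
        rows.append(gene)
        data.append(
            r * latent[sig] + np.sqrt(1.0 - r**2) * rng.standard_normal(n_samples)
        )
    for i in range(n_noise_genes):
        rows.append(f"NOISE{i:04d}")
        data.append(rng.standard_normal(n_samples))
    check_unique(rows, "gene")

    table = pd.DataFrame(
        baseline + np.vstack(data),
        index=pd.Index(rows, name="gene"),
        columns=[f"S{i:03d}" for i in range(n_samples)],
    )
    truth = GroundTruth(
        marker_assignment=members,
        planted_correlations={g: (s, r) for g, (s, r) in planted.items()},
    )
    return table, truth


_DEG_CONTRASTS = ("GBM_vs_NT", "OS_vs_parental", "MES_vs_other")


def simulate_deg_tables(
    universe: list[str],
    planted_sets: tuple[list[str], list[str], list[str]],
    seed: int,
    *,
    padj_threshold: float = 0.05,
    n_boundary: int = 0,
) -> tuple[list[pd.DataFrame], GroundTruth]:
    """Generate three DE tables whose significant-up sets are the planted sets.

    Planted genes get ``padj`` well below the threshold and positive log2
    fold change; all other genes are clearly non-significant. ``n_boundary``
    extra genes per table sit at exactly ``padj == padj_threshold`` with
    positive fold change; the strict-inequality selection contract must
    exclude them. The triple intersection of the planted sets is recorded
    (sorted by gene identifier) in ``expected_intersection``.
    """
    if len(planted_sets) != 3:
        raise ConfigurationError("exactly three planted sets are required")
    check_unique(universe, "gene")
    uni = set(universe)
    for i, s in enumerate(planted_sets):
        missing = [g for g in s if g not in uni]
        if missing:
            raise ConfigurationError(
                f"planted set {i} contains genes outside the universe: {missing[:5]}"
            )
    rng = np.random.default_rng(seed)
    tables: list[pd.DataFrame] = []
    boundary_all: list[str] = []
    for i, planted in enumerate(planted_sets):
        planted_set = set(planted)
        candidates = [g for g in universe if g not in planted_set]
        n_b = min(n_boundary, len(candidates))
        boundary = list(rng.choice(candidates, size=n_b, replace=False)) if n_b else []
        boundary_set = set(boundary)
        boundary_all.extend(boundary)

        recs = []
        for g in universe:
            if g in planted_set:
                padj = rng.uniform(1e-8, 0.8 * padj_threshold)
                lfc = rng.uniform(0.5, 4.0)
            elif g in boundary_set:
                padj = padj_threshold
                lfc = rng.uniform(0.5, 4.0)
            else:
                padj = rng.uniform(1.2 * padj_threshold, 1.0)
                lfc = rng.normal(0.0, 0.5)
            pvalue = padj * rng.uniform(0.1, 1.0)
            recs.append((g, lfc, pvalue, padj))
        df = pd.DataFrame(recs, columns=["gene", "log2FC", "pvalue", "padj"])
        df = df.sample(frac=1.0, random_state=int(rng.integers(2**31)))
        df = df.reset_index(drop=True)
        df.attrs["contrast"] = _DEG_CONTRASTS[i]
        tables.append(df)

    expected = sorted(set(planted_sets[0]) & set(planted_sets[1]) & set(planted_sets[2]))
    truth = GroundTruth(
        expected_intersection=expected,
        boundary_genes=sorted(set(boundary_all)),
    )
    return tables, truth
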