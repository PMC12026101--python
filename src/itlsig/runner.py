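"""End-to-end pipeline orchestration.

Runs QC -> normalization -> module scoring -> cell-state mapping -> ITL
scoring (and, when differential-expression tables are available, the staged
intersection that nominates signature genes), writing every stage output
plus a manifest with per-file SHA-256 hashes and the full parameter
snapshot. A run is a pure function of (inputs, config, seed): identical
configuration yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .cell_state import state_coordinates, state_signature_correlation
from .config import RunConfig
from .containers import CountMatrix, GeneSignature
from .exceptions import ItlsigError, StageError
from .io import (
    read_deg_table,
    read_dense_counts,
    read_gmt,
    read_mtx_triplet,
    write_json,
    write_mtx_triplet,
    write_tsv,
)
from .pipeline import (
    ITL_SIGNATURE,
    compare_groups,
    intersect_stages,
    itl_score_cells,
    significant_up,
)
from .preprocess import QCThresholds, compute_qc, filter_cells, log_normalize, top_principal_components
from .scoring import average_paired_scores, score_signatures
from .synthetic import STATES, GroundTruth, SimConfig, simulate_deg_tables, simulate_sc_counts
from .utils import derive_seed


@dataclass
class RunManifest:
    config: dict[str, Any]
    stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = __version__

    def to_dict(self) -> dict[str, Any]:
        return {
            "config": self.config,
            "stages": self.stages,
            "outputs": self.outputs,
            "version": self.version,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    """Decorator-ish wrapper: re-raise stage failures with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> RunManifest:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    # metadata snapshot embedded in outputs: parameters only, not the output
    # location, so identical runs yield byte-identical payloads anywhere
    snapshot = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    meta = {"config": snapshot, "version": __version__}

    def register(name: str) -> None:
        manifest.outputs[name] = _sha256(out_dir / name)

    # ------------------------------------------------------------------ input
    truth: GroundTruth | None = None
    deg_tables: list[pd.DataFrame] = []
    with _stage("input"):
        if config.mode == "synthetic":
            counts, truth, deg_tables = _synthetic_inputs(config)
            write_json(truth.to_dict(), out_dir / "ground_truth.json", metadata=meta)
            register("ground_truth.json")
            if config.write_matrices:
                write_mtx_triplet(counts, out_dir / "counts")
        else:
            if config.counts_format == "mtx":
                counts = read_mtx_triplet(config.counts_path)
            else:
                counts = read_dense_counts(config.counts_path)
            deg_tables = [read_deg_table(p) for p in config.deg_paths]
        signatures = _state_signatures(config, truth)
    manifest.stages.append("input")

    # --------------------------------------------------------------------- qc
    with _stage("qc"):
        thresholds = QCThresholds(
            min_features=config.min_features,
            min_counts=config.min_counts,
            max_pct_mito=config.max_pct_mito,
        )
        qc = compute_qc(counts, thresholds)
        write_tsv(qc, out_dir / "qc_report.tsv", metadata=meta, index_label="cell_id")
        register("qc_report.tsv")
    manifest.stages.append("qc")

    with _stage("filter"):
        filtered = filter_cells(counts, qc)
    manifest.stages.append("filter")

    with _stage("normalize"):
        norm = log_normalize(filtered, scale=config.scale)
        if config.write_matrices:
            write_tsv(norm.to_frame(), out_dir / "normalized.tsv", metadata=meta,
                      index_label="gene")
            register("normalized.tsv")
    manifest.stages.append("normalize")

    if config.compute_pca:
        with _stage("pca"):
            pcs = top_principal_components(norm, k=min(config.n_pcs, min(norm.n_genes, norm.n_cells)))
            write_tsv(pcs, out_dir / "pca.tsv", metadata=meta, index_label="cell_id")
            register("pca.tsv")
        manifest.stages.append("pca")

    # ------------------------------------------------------------------ score
    with _stage("score"):
        raw_scores = score_signatures(
            norm, signatures, nbins=config.nbins, ctrl=config.ctrl,
            seed=derive_seed(config.seed, "score"),
        )
        consolidated = average_paired_scores(raw_scores)
        write_tsv(raw_scores.scores, out_dir / "module_scores.tsv", metadata=meta,
                  index_label="cell_id")
        register("module_scores.tsv")
    manifest.stages.append("score")

    with _stage("cellstate"):
        states = state_coordinates(consolidated, x_sign=config.x_sign)
        write_tsv(states, out_dir / "cell_state.tsv", metadata=meta, index_label="cell_id")
        register("cell_state.tsv")
    manifest.stages.append("cellstate")

    # -------------------------------------------------------------------- itl
    with _stage("itl"):
        itl = itl_score_cells(
            norm, ITL_SIGNATURE, nbins=config.nbins, ctrl=config.ctrl,
            seed=derive_seed(config.seed, "itl"),
        )
        frame = itl.to_frame()
        frame["state"] = states["state"]
        write_tsv(frame, out_dir / "itl_scores.tsv", metadata=meta, index_label="cell_id")
        register("itl_scores.tsv")

        corr = state_signature_correlation(consolidated, itl)
        write_tsv(corr, out_dir / "itl_state_correlation.tsv", metadata=meta,
                  index_label="state")
        register("itl_state_correlation.tsv")

        is_mes = (states["state"] == "MES").map({True: "MES", False: "non-MES"})
        if is_mes.nunique() == 2:
            cmp_res = compare_groups(itl, is_mes, test="mannwhitney")
            write_json(cmp_res.to_dict(), out_dir / "itl_comparison.json", metadata=meta)
            register("itl_comparison.json")
    manifest.stages.append("itl")

    # ----------------------------------------------------------------- derive
    if deg_tables:
        with _stage("derive"):
            names = [t.attrs.get("contrast", f"stage{i + 1}") for i, t in enumerate(deg_tables)]
            stage_lists = [
                significant_up(t, padj_max=config.padj_max, lfc_min=config.lfc_min)
                for t in deg_tables
            ]
            result = intersect_stages(
                stage_lists, names=names,
                params={"padj_max": config.padj_max, "lfc_min": config.lfc_min},
            )
            write_json(result.to_dict(), out_dir / "intersection.json", metadata=meta)
            register("intersection.json")
        manifest.stages.append("derive")

    with _stage("manifest"):
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    manifest.stages.append("manifest")
    return manifest


def _synthetic_inputs(
    config: RunConfig,
) -> tuple[CountMatrix, GroundTruth, list[pd.DataFrame]]:
    sim_kwargs = dict(config.sim)
    programs = dict(sim_kwargs.pop("planted_programs", {}))
    if config.plant_itl_in_mes:
        programs["ITL"] = (list(ITL_SIGNATURE.genes), ["MES1", "MES2"])
    sim = SimConfig(
        **sim_kwargs,
        planted_programs=programs,
        seed=derive_seed(config.seed, "sim"),
    )
    counts, truth = simulate_sc_counts(sim)

    # DEG triplet over the simulated gene universe: the three contrasts share
    # a planted core (the ITL genes plus a slice of MES markers) so the
    # expected triple intersection is non-trivial and known.
    import numpy as np

    rng = np.random.default_rng(derive_seed(config.seed, "deg"))
    universe = list(counts.gene_ids)
    core = list(ITL_SIGNATURE.genes) + truth.marker_assignment["MES1"][:10]
    pool = [g for g in universe if g not in set(core)]
    sets = []
    for _ in range(3):
        extra = rng.choice(pool, size=30, replace=False).tolist()
        sets.append(core + extra)
    deg_tables, deg_truth = simulate_deg_tables(
        universe, (sets[0], sets[1], sets[2]),
        seed=derive_seed(config.seed, "deg_tables"),
        padj_threshold=config.padj_max,
        n_boundary=config.deg_n_boundary,
    )
    truth.expected_intersection = deg_truth.expected_intersection
    truth.boundary_genes = deg_truth.boundary_genes
    return counts, truth, deg_tables


def _state_signatures(config: RunConfig, truth: GroundTruth | None) -> list[GeneSignature]:
    if config.mode == "files":
        if not config.signatures_gmt:
            raise ItlsigError("files mode requires signatures_gmt")
        sigs = read_gmt(config.signatures_gmt)
        missing = [s for s in STATES if s not in {x.name for x in sigs}]
        if missing:
            raise ItlsigError(f"signature GMT missing state sets: {missing}")
        by_name = {s.name: s for s in sigs}
        return [by_name[s] for s in STATES]
    assert truth is not None
    return [GeneSignature(name=s, genes=truth.marker_assignment[s]) for s in STATES]
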