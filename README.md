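# itlsig

Analysis pipeline for mapping glioblastoma (GBM) cellular states in
single-cell RNA-seq and deriving/scoring the TGFBR2-driven
**immunosuppressive Treg-like (ITL)** gene signature — the six-gene set
*CD274* (PD-L1), *NT5E* (CD73), *ENTPD1* (CD39), *LGALS1* (galectin-1),
*PDCD1LG2* (PD-L2) and *TGFB1* expressed by mesenchymal glioma stem-like
cells that mimic regulatory T cell (Treg) effector programs.

The package is aimed at computational biologists who want the full chain —
from raw count matrices to signature scores and statistics — as tested,
reusable library functions plus a thin `itl` command-line interface, with a
synthetic-data generator so every stage can be validated against known
ground truth without downloading any cohort data.

## What it computes

**Cell QC and normalization.** Cells with detected features < 500, total
counts < 500, or > 20% mitochondrial reads are excluded (strict
inequalities; boundary cells pass). Counts are library-size normalized and
log-transformed: `x_gc = ln(1 + 10^4 · n_gc / N_c)`.

**Per-cell module scores.** For a signature *S*, genes are partitioned into
30 bins by mean expression and, per signature gene, 100 control genes are
drawn from its bin; the score is

```
SC(cell) = mean_{g in S} x_gc − mean_{g in controls} x_gc
```

so a score near zero means "no different from expression-matched
background". Six GBM state signatures (MES1, MES2, AC, OPC, NPC1, NPC2) are
scored per cell and consolidated as `SC_mes = (SC_mes1 + SC_mes2)/2`,
`SC_npc = (SC_npc1 + SC_npc2)/2`.

**Two-axis cell-state geometry.** Each cell is placed at

```
y = max(SC_opc, SC_npc) − max(SC_ac, SC_mes)
x = log2(|SC_opc − SC_npc| + 1)   if y > 0   (OPC/NPC lineage)
x = log2(|SC_ac  − SC_mes| + 1)   otherwise  (AC/MES lineage)
```

with x signed by the within-pair winner (Neftel-style quadrants), and the
discrete state is the argmax of the four scores.

**Enrichment.** Single-sample GSEA (rank-weighted ECDF difference,
exponent α = 0.75) scores signatures in bulk samples; preranked GSEA
computes the classic running-sum enrichment score ES with a gene-label
permutation null, `NES = ES / mean(|ES*|)` over same-sign permutations and
a +1-corrected permutation p-value.

**Derivation and statistics.** Strict-threshold selection of significant
up-regulated genes (`padj < 0.05`, `log2FC > 0` by default) intersected
across contrasts; median high/low cohort splits; transcript detection
calls; Pearson correlation panels with Benjamini–Hochberg adjustment; and
named group comparisons (Student's t, one-way ANOVA + Tukey HSD,
Mann–Whitney U, Kruskal–Wallis).

**Synthetic data.** Negative-binomial scRNA-seq counts with planted state
programs, mitochondrial content and forced low-quality cells; bulk cohorts
with planted gene–signature Pearson correlations; and DE-table triplets
with a known intersection — each emitting a machine-readable ground-truth
sidecar.

## Worked example

```python
import itlsig as il

cfg = il.SimConfig(
    n_cells_per_state=100, n_background_genes=1000, frac_low_quality=0.1,
    seed=7,
    planted_programs={"ITL": (list(il.ITL_SIGNATURE.genes), ["MES1", "MES2"])},
)
counts, truth = il.simulate_sc_counts(cfg)          # 1319 genes x 660 cells
qc = il.compute_qc(counts)                          # 600 cells pass QC
norm = il.log_normalize(il.filter_cells(counts, qc))

sigs = [il.GeneSignature(name=s, genes=truth.marker_assignment[s])
        for s in ("MES1", "MES2", "AC", "OPC", "NPC1", "NPC2")]
scores = il.average_paired_scores(il.score_signatures(norm, sigs, seed=7))
states = il.state_coordinates(scores)
print(states["state"].value_counts())
# MES 200, NPC 200, AC 100, OPC 100  (exactly the planted composition)

itl = il.itl_score_cells(norm, seed=7)
groups = states["state"].eq("MES").map({True: "MES", False: "non-MES"})
res = il.compare_groups(itl, groups, test="mannwhitney")
print(res.statistic, res.p_value)
# U = 77074, p = 1.38e-76 — the planted ITL program is far higher in MES cells
```

The first rows of `states` look like

```
         MES     AC    OPC    NPC      x      y lineage state
C00000 0.525 -0.547 -0.219 -0.223  1.051 -0.744  AC/MES   MES
C00001 0.252 -0.280 -0.222 -0.136  0.615 -0.388  AC/MES   MES
```

The same flow is available from the shell:

```sh
itl sim sc --seed 7 --out-dir demo --frac-low-quality 0.1
itl preprocess --counts demo/counts --format mtx --out-dir demo/pp
itl run --config run.yaml        # full QC -> score -> state -> ITL -> derive
```

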