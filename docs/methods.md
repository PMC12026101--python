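# Methods

This note records the statistical models behind `itlsig`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
validation does and does not demonstrate.

## Quality control and normalization

A cell is excluded when detected features < 500, total counts < 500, or the
mitochondrial read percentage exceeds 20%. All three comparisons are
strict, so a cell at exactly 500 features/counts or exactly 20% passes;
this matches the inequality directions as conventionally printed
("<500", ">20%"). The "features and/or counts" clause is read as a
fail-if-either rule. Mitochondrial genes are flagged by identifier prefix
(default `MT-`, configurable). Percentages use raw totals, the standard
practice. An all-zero cell gets `n_features = 0`, `pct_mito = 0` by
convention and fails.

Normalization is library-size scaling to 10,000 counts per cell followed by
`ln(1 + ·)`. Downstream scoring only requires a normalized log-scale
matrix, so a regularized-regression normalization (e.g. variance-
stabilizing NB regression) was deliberately not used: the simple closed
form is dependency-free and can be verified element-wise by an independent
oracle. Batch correction is out of scope. A 20-component PCA of the
gene-centered matrix is provided for completeness (sign fixed so each
component's largest-magnitude loading is positive) but no downstream stage
consumes it.

## Module scores

Genes are partitioned into `nbins = 30` near-equal bins by mean expression
(ties broken by gene identifier; remainder genes go to the low-expression
bins). For each signature gene, `ctrl = 100` control genes are sampled
without replacement from its bin — the whole bin when it is smaller than
`ctrl` — and the union of the draws forms one control pool per signature
per run. The score is the signature-mean minus control-pool-mean
expression, per cell. Control draws are seeded per `(run seed, signature
name)`, so scores are deterministic and independent of signature order,
and the pool is recorded in the result so a test can replay the
computation step by step. Signature genes absent from the matrix are
dropped with a logged warning provided at least one remains; curated
signatures routinely overlap a matrix only partially, so this is not an
error. A signature gene may be drawn into its own control pool (matching
the referenced implementation's behavior); with `ctrl` large this biases
the score toward zero by a factor `(1 − k/|pool|)`, which the tests account
for explicitly.

Under exchangeable gene labels the expected score is zero; the test suite
checks this by Monte Carlo (500 random signatures, grand mean within 3
standard errors of zero).

## Cell-state geometry

The six per-cell state scores are consolidated by pair averaging
(`MES = (MES1 + MES2)/2`, `NPC = (NPC1 + NPC2)/2`; AC and OPC pass
through). Coordinates:

* `y = max(SC_opc, SC_npc) − max(SC_ac, SC_mes)`; `y > 0` is OPC/NPC
  lineage, and the measure-zero `y = 0` case resolves to AC/MES (consistent
  with "positive means OPC/NPC").
* `x = log2(|within-pair difference| + 1)` for the assigned lineage. Only
  the magnitude formula is defined upstream; the sign convention (negative
  when the pair's first member, OPC or AC, dominates) reproduces the
  familiar four-quadrant layout and is exposed as a flag
  (`neftel`/`magnitude`).
* The discrete state is the argmax of the four consolidated scores with
  fixed tie priority MES > AC > OPC > NPC. Consolidated (not raw six)
  scores are used because the plot axes are defined on them.

No clipping or winsorizing of extreme coordinates is applied.

## ssGSEA

For one sample, genes are ordered by descending expression (ties by
identifier); the gene at descending position *i* of *N* carries rank value
`N − i + 1`. The score is `Σ_i [P_in(i) − P_out(i)]` where `P_in` is the
ECDF weighted by `rank value^alpha` over signature genes and `P_out` the
uniform ECDF over the complement. `alpha = 0.75` follows the original
single-sample formulation. The raw score is reported by default; an
optional cohort range-normalization (divide by max − min across samples) is
available as a flag since reporting conventions differ. A signature
covering every gene leaves the out-of-set ECDF undefined and is rejected.
Being rank-based, the score is invariant under strictly monotone transforms
of the expression vector, which the tests assert.

## Preranked GSEA

The ranked list is ordered by descending metric (ties by identifier). Hits
advance the running sum by `|metric| / Σ_hits |metric|`, misses retreat it
by `1/(N − n_hits)`; ES is the extreme deviation (earliest position on
magnitude ties). If every hit metric is exactly zero the hit increments
fall back to uniform `1/n_hits`. The null permutes gene labels — which
ranked positions are hits — because the input is a derived ranking, not
replicate-level data; sample permutation is therefore unavailable by
construction. `NES = ES / mean(|ES*|)` over same-sign null scores;
`p = (1 + #{|ES*| ≥ |ES|, same sign}) / (1 + #{same sign})`, so the
resolution is `1/(n_null + 1)`. When `C(N, n_hits)` is feasible
(≤ 200,000) an exhaustive enumeration mode replaces sampling and is exact.
`n_perm < 10` is accepted but recorded as a warning in the result. Default
`n_perm = 1000` keeps the smallest attainable p near 1e-3, sufficient for
the screening use here.

## Derivation battery

* `significant_up`: `padj < padj_max` and `log2FC > lfc_min`, both strict;
  defaults 0.05 and 0 are exposed and recorded in the result because the
  upstream analysis does not print its cutoffs. Output is ordered by
  ascending `padj`, then gene.
* `intersect_stages`: set intersection preserving the first list's order;
  stage lists are retained for audit.
* `median_split`: strictly-above-median samples are "high", at-or-below are
  "low" — a deterministic tie rule chosen because the upstream description
  is silent; all-identical input has no split and is an error.
* `detect_expressed`: a gene is detected when nonzero in ≥ `min_frac`
  (default 1%, inclusive) of cells; genes absent from the matrix are
  undetected.
* `correlation_panel`: pairwise-complete Pearson with two-sided p;
  Benjamini–Hochberg over the upper triangle, mirrored. Zero-variance
  pairs are reported as NaN (undefined), never silently zero. BH was
  chosen because the upstream reporting names no correction for
  correlation panels; the choice is recorded in the output metadata.
* `compare_groups` runs only the named test. Mann–Whitney uses the
  tie-corrected normal approximation without continuity correction so that
  identical group distributions give p = 1 exactly and the k = 2
  Kruskal–Wallis equivalence holds to numerical tolerance. "Student's t"
  is the independent two-sample equal-variance test. ANOVA attaches a
  Tukey HSD pairwise table.

The six-gene ITL signature ships as a constant
(`CD274, NT5E, ENTPD1, LGALS1, PDCD1LG2, TGFB1`) and is user-overridable;
bulk scoring delegates to ssGSEA, per-cell scoring to the module score. A
curated Treg direct-effector candidate pool is included as an editable GMT
(`data/treg_effectors.gmt`); the pool reflects standard Treg effector
literature because the upstream curation is described narratively, not
algorithmically.

## Synthetic data: what it emulates, and what it does not

Counts follow a negative binomial with mean/dispersion parameterization
(variance `μ + μ²/θ`), the standard desk-scale surrogate for droplet UMI
counts. Defaults — 200 cells per state, 2,000 background genes, 50 markers
per state, baseline mean 2, dispersion 2, uplift 4 — give per-cell depths
(~4,000–5,000 counts, ~1,700 detected features) and a marker separation
(8 vs 2 mean counts) typical of a well-powered droplet experiment with
clearly defined programs. Mitochondrial content is a named `MT-` block
whose per-cell share is drawn uniformly from [1%, 10%]. Low-quality cells
are extra cells binomially downsampled until < 500 detected features, so QC
has unambiguous ground truth. Programs shared across states (e.g. the ITL
genes riding on MES1 + MES2) are planted through a separate mechanism so
per-state marker lists stay disjoint. Library size is controlled through
the baseline NB mean rather than matched to any real depth profile.

Bulk cohorts plant a gene-vs-signature correlation exactly: signature
members are `z + 0.05·ε` around a latent activity `z ~ N(0,1)` and a
planted gene is `r·z + √(1−r²)·ε`, so the population correlation with the
latent activity is `r` (attenuation through the member noise is < 0.1%).
DE tables place planted genes well below the significance threshold with
positive fold change, everything else clearly above it, and optionally
plant rows at exactly `padj = threshold` to exercise the strict-inequality
contract.

Not simulated: doublets, ambient RNA, batch structure, gene–gene
correlation beyond the planted programs, zero inflation beyond NB, or
realistic mean–variance trends across genes. Passing the recovery tests
therefore shows the pipeline's operations are correct and well-calibrated
under their stated models — not that the biological conclusions transfer
to any particular real cohort.

One structural consequence worth knowing: with no signal (uplift 1) the
state-assignment accuracy sits somewhat above 1/6 chance (~0.27), because
the consolidated MES/NPC scores are means of two independent scores and
have lower variance than AC/OPC, making AC/OPC more often the argmax while
AC/OPC cells are also less frequent in the balanced design. This is a
property of the consolidation itself, not a defect of the scoring.

## Determinism and seeds

Every stochastic operation takes a seed; a run expands one top-level seed
per consumer through SHA-256 of `"{seed}:{label}"` (kept below 2^31), so
stages are reproducible in isolation and results are independent of
execution order. Identical configuration yields byte-identical outputs;
output files embed a parameter snapshot (excluding the output location) in
a `#` header or JSON metadata block. TSV round-trips are bit-exact (floats
are written at full precision and parsed in round-trip mode).

## Problem sizes used in validation

The recovery experiments run five seed batteries of 1,200 cells
(200 per state, ~2,300 genes) at uplift 4; correlation recovery uses
r ∈ {−0.8, 0, 0.6, 0.9} at n ∈ {200, 500} over 10 seeds each; null
calibration uses 500 module-score draws and 200 GSEA repetitions at 500
permutations. These sizes make the Monte-Carlo error small relative to
every acceptance margin while keeping a full validation run in seconds on
one CPU.

## Known limitations

* No batch correction, doublet handling, highly-variable-gene selection, or
  embedding; the pipeline begins at a count matrix and ends at scores,
  states and statistics.
* DE tables are consumed, not fitted; no DESeq2/edgeR re-implementation.
* GSEA reports ES/NES/p only — no leading-edge genes, no FDR machinery
  beyond BH over a result list.
* The ssGSEA normalization variant and the GSEA ranking metric are
  analysis choices the user must make; defaults (raw ES; log2FC) are
  documented, not claimed as the only valid ones.
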