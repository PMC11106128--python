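# Methods

This note documents the models behind each analysis stage, the synthetic
data they are validated on, and the numerical conventions that make runs
reproducible. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Data model and preprocessing

All stages operate on an observation-major `ExpressionMatrix` (rows = spots,
metacells or bulk samples; columns = genes) tagged with one of three layers.
`counts` holds raw non-negative integers. `normalize_log` produces the
`lognorm` layer, `log(1 + c_ig * s / d_i)` with `d_i` the spot's total count
and `s` a target depth (default 10,000, a CPM-like convention); spots with
zero depth stay as zero rows and are flagged in the log. `scale_genes`
produces the `scaled` layer by per-gene z-scoring with the **population**
standard deviation (divisor *n*) — a fixed, documented convention the test
values depend on; zero-variance genes map to all-zero columns rather than
NaN. The composition lognorm∘scale is invariant to rescaling any spot's
depth, which is asserted as a property test.

Gene identifiers are matched verbatim across all tables (no case folding or
symbol mapping), so a mismatch surfaces as a missing gene rather than a
silent mis-join.

## Co-expression stage

**Metacells.** Within each (cluster, condition, day) group, a spot is pooled
with its `k_neighbors` nearest neighbours (Euclidean distance in the top-10
PC space of the group's centred lognorm matrix); a candidate metacell is
greedily rejected when it shares more than `max_overlap` of its members with
an accepted one. Groups smaller than `k_neighbors + 1` are emitted unpooled
with a warning. Pooling reduces count sparsity before correlation
estimation; `k_neighbors = 0` disables it exactly.

**Soft power.** For each candidate exponent `beta` in 1..30 the signed
adjacency `a_ij = ((1 + r_ij)/2)^beta` (unsigned `|r_ij|^beta` by flag) is
formed and the connectivities `k_i = sum_{j != i} a_ij` are binned into 10
equal-width bins; the fit regresses `log10(frequency)` on `log10(mean k)`
and the R² is signed so a decreasing degree law scores positively. The
chosen power is the smallest with signed R² ≥ 0.8, else the argmax with a
warning. Degenerate inputs (constant connectivity, fewer than three usable
bins) record NaN instead of crashing. An exactly power-law degree vector
scores signed R² = 1 to machine precision, which doubles as the correctness
oracle for the fit.

**TOM and modules.** Topological overlap is
`TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`
with unit diagonal and pairs with zero denominator defined as 0; the matrix
implementation is tested against a brute-force triple loop at 1e-10.
Modules are average-linkage clusters of `1 - TOM` under a **static cut at
dissimilarity 0.95**: in TOM dissimilarity, genes without co-expression
partners sit near height 1, so a fixed cut close to — but below — 1 isolates
any co-expressed subtree while leaving unstructured genes in fragments
smaller than `min_size` (default 30), which become grey. A merge-height
quantile rule (cut at the 0.99 quantile) is retained behind
`cut_height=None` but is not the default: on sparse networks the top
percentile of merge heights lies inside the unassigned-gene regime and
yields a single giant cluster. After cutting, modules whose eigengenes
correlate above `merge_corr = 0.75` are merged iteratively (highest pair
first). Surviving modules are renamed by a fixed colour sequence in order of
decreasing size (ties broken by first gene id), so labels are reproducible
across runs; colour identities carry no meaning beyond ordering.

**Eigengenes, kME, hubs.** A module eigengene is the first-PC score vector
of the module's scaled submatrix (via SVD), sign-oriented so the mean
correlation with member genes is positive, then standardized to unit
variance; a single-gene module's eigengene is that gene's scaled vector.
`kME_gm` is the Pearson correlation of gene *g* with eigengene *m*, computed
for all genes against all modules. Hub lists take the top 100 genes per
module by own-module kME (ties broken lexicographically); the CLI exports a
top-25 hub network whose edges connect hubs with absolute correlation above
a flagged threshold (default 0.5) — an explicit stand-in convention, since
hub-network edge definitions vary between tools.

**Traits.** Module–trait correlations use one-hot day, condition and
cluster indicators with two-sided Pearson tests. The violin/heat-map style
claims (e.g. early-day vs late-day complementarity) reduce to the sign
pattern of these correlations, which is what the tests assert.

## Differential expression and enrichment

A vs N comparisons run per (cluster, day) stratum on the lognorm layer with
a two-sided Wilcoxon rank-sum test: exact when both groups have ≤ 10 spots,
otherwise the tie-corrected normal approximation. Strata missing a
condition (fewer than 3 spots per group) are skipped with a warning.
`log2FC = log2((mean expm1 A + 1) / (mean expm1 N + 1))` back-transforms the
lognorm values; the pseudocount of 1 keeps fold changes bounded when a
group is all zero. Genes are *selected* when `|log2FC| >= 0.58` (fold
change 1.5) **and raw** `P < 0.05`; the BH FDR is reported alongside but
deliberately not used for selection, matching the screening convention the
pipeline implements. UpSet summaries report exclusive intersection-region
sizes, which partition the union of selected genes.

Over-representation uses the same hypergeometric upper-tail engine as the
ceRNA screen, with the universe supplied by the caller (typically all tested
genes) and BH correction across sets. The GSEA statistic is the weighted
Kolmogorov–Smirnov running sum (hit steps proportional to `|stat|^p`,
default p = 1, normalised; miss steps `1/(N - n_hits)`), with the enrichment
score the signed maximum deviation. Significance is by **gene-label
permutation** (resampling set membership) — feasible at any sample count,
unlike phenotype permutation with three-spot groups — with
`NES = ES / mean |ES_perm|` and a two-sided p on `|ES|`. The ES
implementation is cross-checked against Bioconductor's fgsea on shared
inputs, and the tail engine against R's `phyper`.

## Pathway activity and NNMF

Spot scores are `S = Z W` over the genes shared between the scaled matrix
and the weight table; a warning fires when fewer than half the model's genes
are present, and pathways with no usable gene are dropped. Scaled scores
are per-pathway z-scores across spots, so cluster means are directly
comparable between pathways. The weight table is an input (the synthetic
generator's planted weights, or any exported responsive-gene model); no
weights are trained or shipped.

NNMF minimises the Frobenius loss with Lee–Seung multiplicative updates.
The input is the scaled layer shifted per gene to minimum 0 (the documented
non-negativity transform); negative input is a fatal error pointing to the
shift step. Initialisation is seeded uniform noise scaled to
`sqrt(mean(X)/k)`; a small epsilon (1e-12) guards denominators; iteration
stops at relative loss change < 1e-4 or 500 updates, and the loss trace —
recorded at init and after every update — is non-increasing by
construction, which the tests assert across seeds. The all-zero matrix
short-circuits to zero factors with loss 0. Factorisation runs per
(condition, day) section by default (k = 20 factors each), with a pooled
mode behind a flag; factor–pathway Pearson matrices are emitted with
hierarchically clustered row/column order for heat-map display.

## ceRNA screening

Every (lncRNA or circRNA, mRNA) pair is scored by the shared-target count
`k` against the hypergeometric upper tail with universe `N` = the union of
all miRNAs appearing in the target map — the least-assumption choice, and
overridable. BH correction runs **within each ceRNA class** because the
circRNA and lncRNA networks are assembled separately; a pooled flag exists.
Pairs survive at `p < 0.01`, `FDR < 0.01` and strictly positive Pearson
correlation across the matched bulk samples (pairs with a missing member or
a constant expression vector are dropped and counted). Retained pairs whose
mRNA is DE-selected expand into ceRNA–miRNA and miRNA–mRNA edges, one per
shared miRNA, with mRNA nodes annotated by DE direction. Betweenness uses
Brandes' algorithm, unnormalised, counting each unordered endpoint pair
once (verified against all-pairs path enumeration); degree ranking flags
the top node per RNA class. Centrality is also exposed for arbitrary
user-supplied edge lists, since protein–protein networks are a common
second input for the same ranking.

## Synthetic data generator

The generator is the package's study-conditions definition, not a tuning
knob. `simulate_spatial` lays six sections ({N, A} × GD {14, 15, 16}), each
an 8-cluster hexagonal grid (42 spots per cluster by default, ≈ 2,000 spots
total) with cluster blobs from Voronoi seeds; coordinates are cosmetic — no
stage reads them. Counts are negative binomial with mean `exp(mu)` and
variance `m + m^2/theta` (dispersion `theta = 10`), where

    mu_ig = log(2) + b_g f_m(i) + 0.6 * sum_p W_gp a_p(i) + DE shift

* **Modules**: 10 modules of 40 genes with loadings `b_g` uniform in
  `1.2 × [0.5, 1]`. Module activity `f_m` combines a day profile (±0.4,
  alternating "early" [high GD14/15, low GD16] and "late" parity, flipped
  for modules that reuse a home cluster), a home-cluster boost (+1.5), and a
  dominant module-specific spot term (SD 1.0). The spot term keeps
  cross-module correlation low enough for modules to be separable, while
  day and cluster terms plant the module–trait sign structure.
* **Pathways**: 14 pathways × 30 genes with signed weights (magnitude
  0.5–1.5) and activities = cluster-level means (SD 1) plus spot noise
  (SD 0.5), injected through the same weight table the scoring stage uses.
* **DE genes**: 100 genes in a fixed index block receive a ±1 log2-unit
  log-mean shift in condition A (alternating sign), so true fold changes
  are exact by construction.

`simulate_ncrna` builds a 300-miRNA universe; 40 planted triples (half
circRNA, half lncRNA) share 80% of their 25–35 targets with their partner
mRNA, background RNAs draw targets uniformly, and planted pairs co-vary
across 24 bulk samples through a latent factor with loading 0.7. Planted
mRNA identifiers reuse the spatial DE-gene names so the joint
spatial-DE-plus-bulk workflow links end to end. `simulate_two_condition` is
a minimal one-stratum variant used for DE calibration and power studies.

Everything is driven by one integer seed (stage seeds derive from it), and
outputs are byte-identical across reruns — asserted through the CLI.

**What the generator does not emulate**: real Visium noise spectra, spatial
autocorrelation beyond cluster blobs, doublets or segmentation error,
mean–variance trends beyond a single global dispersion, and gene–gene
correlation that is not module- or pathway-driven. Passing recovery tests
therefore demonstrates the pipeline's correctness and calibration under the
planted model, not performance on tissue data; effect sizes were chosen for
testability at desk scale (the full default pipeline runs in well under a
minute on one CPU).

## Evaluation conventions

Module recovery is scored as the adjusted Rand index between recovered
labels (grey included as its own label) and true module ids **over the
planted-module genes**; background genes carry no true module, so including
them would score the arbitrary fragmentation of unstructured genes rather
than recovery. ceRNA recovery reports precision and recall of retained
pairs against planted triples. DE calibration checks uniformity of null raw
p-values (KS test) and the selection rate of planted log2FC = 1 effects at
50 + 50 spots. Problem sizes for these checks are the generator defaults
above; the exactness oracles (hypergeometric enumeration at N ≤ 12,
triple-loop TOM at 20 genes, path-enumeration betweenness at ≤ 12 nodes)
run at sizes where exhaustive computation is cheap.

## Known limitations

* The static-cut module detector has no dynamic tree-cut refinement; deeply
  nested module structure (modules within modules) merges or splits
  according to the single cut height.
* The Wilcoxon exact path follows the standard no-ties null; heavily tied
  small-sample strata are handled by the tie-corrected approximation only
  above n = 10 per group.
* GSEA permutes gene labels, not phenotypes, so its null ignores
  inter-gene correlation.
* NNMF multiplicative updates converge to a local optimum; different seeds
  give different (equally valid) factorisations, which is why factors are
  interpreted only through their correlation with pathway scores.
* The hypergeometric universe and the per-class FDR pooling of the ceRNA
  screen are documented conventions, configurable where a different
  convention is preferred.
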