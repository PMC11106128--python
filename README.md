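# spotweave

Network and pathway analysis for Visium-style spatial transcriptomics of
embryonic development, built around a concrete study design: sagittal
sections of normal (N) and malformation-model (A) rat embryos at gestational
days (GD) 14–16, each annotated into eight anatomical clusters (urethra,
hindgut, bladder, urorectal septum, genital tubercle, vertebral bodies,
neural tube, small intestine). The package takes a spot × gene count matrix
plus that annotation and runs four analysis stages, each usable on its own:

1. **Co-expression modules** (`spotweave.coexpression`) — metacell pooling,
   soft-threshold selection by scale-free fit, signed adjacency, topological
   overlap (TOM), colour-named modules, module eigengenes (ME), kME hub
   ranking, and module–module / module–trait correlation.
2. **Differential expression and enrichment** (`spotweave.diffexpr`) —
   per-(cluster, day) Wilcoxon rank-sum tests of A vs N, UpSet-style
   intersection counts, hypergeometric over-representation, and a GSEA
   running-sum statistic with permutation p-values.
3. **Pathway activity** (`spotweave.pathways`) — responsive-gene weight-matrix
   scoring of spots, per-cluster summaries, per-section non-negative matrix
   factorisation (NNMF), and factor–pathway correlation.
4. **ceRNA networks** (`spotweave.cerna`) — hypergeometric shared-miRNA-target
   screening of lncRNA/circRNA–mRNA pairs, FDR and positive-co-expression
   filters, triad assembly, and degree / betweenness-centrality hub ranking.

A synthetic-data generator (`spotweave.simulate`) emulates the six-section
study design with planted modules, pathway activities, condition effects and
ceRNA triples, so every stage is testable against known ground truth without
any external download.

## The statistics in brief

With `r_ij` the Pearson correlation of genes *i*, *j* across observations,
the signed adjacency is `a_ij = ((1 + r_ij)/2)^beta`, with `beta` the
smallest power whose connectivity distribution fits scale-free topology at
signed `R^2 >= 0.8`. Topological overlap is

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

and modules are average-linkage clusters of `1 - TOM`. A module's eigengene
is the first principal component of its (scaled) expression; `kME_gm` is the
correlation of gene *g* with eigengene *m* and ranks hub genes.

Pathway scores are the linear projection `S = Z W` of z-scored expression
through a signed gene × pathway weight table; NNMF factorises the
non-negative-shifted matrix as `X ≈ W_f H_f` by Lee–Seung multiplicative
updates with a monotone Frobenius loss.

A candidate ceRNA pair with target sets of sizes `K` and `n` sharing `k`
miRNAs in a universe of `N` is scored by the hypergeometric upper tail
`P(X >= k)`; pairs are kept at `p < 0.01`, Benjamini–Hochberg `FDR < 0.01`
(per ceRNA class) and expression correlation `r > 0`, then expanded into
ceRNA–miRNA–mRNA triads whose nodes are ranked by unnormalised betweenness
centrality (Brandes' algorithm).

## Worked example

```python
import numpy as np
import spotweave as sw

cfg = sw.SimConfig(seed=1)                       # the default study design
expr, meta, truth = sw.simulate_spatial(cfg)
print(f"{expr.n_obs} spots x {expr.n_genes} genes across 6 sections")

res = sw.run_wgcna(sw.normalize_log(expr), meta)
sp = res["soft_power"]
print(f"soft power beta = {sp.chosen} (scale-free R^2 = "
      f"{sp.table.set_index('power').loc[sp.chosen, 'r2_signed']:.3f})")
sizes = res["labels"][res["labels"] != "grey"].value_counts()
print(f"modules: {len(res['mes'].columns)} (largest: {sizes.index[0]} with "
      f"{sizes.iloc[0]} genes; grey: {int((res['labels'] == 'grey').sum())} genes)")
r = res["module_trait_r"]
m = r["day_14"].idxmax()
print(f"module '{m}' vs day: r(14)={r.loc[m, 'day_14']:+.2f} "
      f"r(15)={r.loc[m, 'day_15']:+.2f} r(16)={r.loc[m, 'day_16']:+.2f}")

t = sw.differential_expression(sw.normalize_log(expr), meta, cluster=1, day=15)
print(f"cluster 1, GD15: {int(t['selected'].sum())} DE genes "
      f"(|log2FC| >= 0.58, P < 0.05)")

sc = sw.scale_genes(sw.normalize_log(expr))
act = sw.score_pathways(sc, truth.pathway_weights)
rs = [np.corrcoef(act.scaled[p], truth.pathway_activity[p])[0, 1]
      for p in act.scaled.columns]
print(f"pathway activity recovery: min r = {min(rs):.3f} over {len(rs)} pathways")

tmap_dict, bulk, ntruth = sw.simulate_ncrna(cfg)
tmap = sw.TargetMap.from_dict(tmap_dict)
pairs = sw.coexpression_filter(sw.candidate_pairs(tmap), bulk)
net = sw.assemble_triads(pairs, tmap, t)
bc = sw.betweenness_ranking(net.graph)
print(f"ceRNA screen: {len(pairs)} retained pairs -> network with "
      f"{net.graph.number_of_nodes()} nodes, {net.graph.number_of_edges()} edges")
print("top betweenness:", ", ".join(
    f"{row.node} ({row.betweenness:.0f})" for row in bc.head(3).itertuples()))
```

prints:

```
2016 spots x 1500 genes across 6 sections
soft power beta = 19 (scale-free R^2 = 0.811)
modules: 10 (largest: turquoise with 40 genes; grey: 1100 genes)
module 'turquoise' vs day: r(14)=+0.25 r(15)=+0.24 r(16)=-0.49
cluster 1, GD15: 107 DE genes (|log2FC| >= 0.58, P < 0.05)
pathway activity recovery: min r = 0.944 over 14 pathways
ceRNA screen: 40 retained pairs -> network with 360 nodes, 1716 edges
top betweenness: circ_0006 (1892), gene_0826 (1892), circ_0015 (1885)
```

Reading the output: the soft power 19 is the smallest exponent giving an
approximately scale-free network; the ten recovered modules are exactly the
ten planted ones (the 1,100 grey genes are the unstructured background plus
pathway-responsive genes); the `turquoise` module correlates positively with
GD14/15 and negatively with GD16 — the early/late complementarity the
generator plants; and all 40 planted ceRNA triples survive the
three-filter screen.

The same pipeline is available from the shell:

```sh
spotweave simulate --seed 1 --outdir data/
spotweave wgcna   --matrix data/matrix.mtx --genes data/genes.tsv \
                  --barcodes data/barcodes.tsv --metadata data/metadata.tsv \
                  --outdir results/wgcna
spotweave de      --matrix data/matrix.mtx --genes data/genes.tsv \
                  --barcodes data/barcodes.tsv --metadata data/metadata.tsv \
                  --outdir results/de
spotweave cerna   --targets data/target_map.tsv --expr data/bulk_expression.tsv \
                  --deg results/de/deg_1_15.tsv --outdir results/cerna
```

## Documentation

`docs/methods.md` describes the models, the synthetic-data generator and the
numerical conventions (scaling, tie-breaking, degenerate-input guards) in
detail.
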