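"""Per-cluster differential expression between conditions, UpSet-style
intersection summaries, over-representation analysis and a GSEA-style
running-sum statistic.

Selection follows the relaxed screening criterion common in spot-level
work: |log2FC| >= 0.58 (fold change 1.5) together with raw Wilcoxon
rank-sum P < 0.05; the Benjamini-Hochberg FDR is reported alongside but is
not part of the selection rule.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cerna import hypergeom_tail
from .datatypes import ExpressionMatrix, GeneSetCollection, SpotMetadata

log = logging.getLogger(__name__)

FC_MIN_DEFAULT = 0.58  # |log2FC| of a 1.5-fold change
ALPHA_DEFAULT = 0.05


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    expr: ExpressionMatrix,
    meta: SpotMetadata,
    cluster: int,
    day: int,
    fc_min: float = FC_MIN_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
    min_per_group: int = 3,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum A-vs-N per gene within one (cluster, day)
    stratum of the lognorm layer.

    The test is exact when both groups have <= 10 spots, otherwise the
    normal approximation with tie correction. log2FC compares back-transformed
    group means with a pseudocount of 1 so zero groups stay bounded.
    """
    if expr.layer != "lognorm":
        raise ValueError("differential_expression expects the lognorm layer")
    mtab = meta.aligned_to(expr)
    sel = (mtab["cluster"] == cluster) & (mtab["day"] == day)
    sub = expr.values[sel.to_numpy()]
    cond = mtab.loc[sel, "condition"].to_numpy()
    n_a, n_n = int((cond == "A").sum()), int((cond == "N").sum())
    if n_a < min_per_group or n_n < min_per_group:
        log.warning(
            "stratum cluster=%s day=%s lacks both conditions "
            "(A=%d, N=%d, need >= %d each); skipped", cluster, day, n_a, n_n, min_per_group,
        )
        return pd.DataFrame(
            columns=["gene", "cluster", "day", "log2fc", "p", "fdr", "direction", "selected"]
        )
    A = sub[cond == "A"]
    N = sub[cond == "N"]
    method = "exact" if max(n_a, n_n) <= 10 else "asymptotic"
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(A, N, alternative="two-sided", method=method, axis=0)
    pvals = np.asarray(res.pvalue, dtype=float)
    # all-tied columns have zero rank variance; the test is uninformative there
    degenerate = np.ptp(np.vstack([A, N]), axis=0) == 0
    pvals[degenerate | ~np.isfinite(pvals)] = 1.0
    pvals = np.clip(pvals, 0.0, 1.0)
    mean_a = np.expm1(A).mean(axis=0)
    mean_n = np.expm1(N).mean(axis=0)
    log2fc = np.log2((mean_a + 1.0) / (mean_n + 1.0))
    fdr = bh_fdr(pvals)
    out = pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "cluster": cluster,
            "day": day,
            "log2fc": log2fc,
            "p": pvals,
            "fdr": fdr,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "selected": (np.abs(log2fc) >= fc_min) & (pvals < alpha),
        }
    )
    return out


def upset_counts(deg_tables: dict) -> pd.DataFrame:
    """Exclusive intersection-region sizes of the selected-gene sets.

    ``deg_tables`` maps a label (e.g. cluster id) to its DE table. Each row
    of the result is one non-empty combination of labels with the number of
    genes selected in exactly those labels, so region counts partition the
    union of selected genes.
    """
    sets = {
        str(k): set(t.loc[t["selected"], "gene"]) for k, t in deg_tables.items()
    }
    union = set().union(*sets.values()) if sets else set()
    membership: dict[tuple, int] = {}
    for g in union:
        key = tuple(sorted(k for k, s in sets.items() if g in s))
        membership[key] = membership.get(key, 0) + 1
    rows = [
        {"clusters": "+".join(key), "degree": len(key), "count": c}
        for key, c in membership.items()
    ]
    rows.sort(key=lambda r: (-r["degree"], r["clusters"]))
    return pd.DataFrame(rows, columns=["clusters", "degree", "count"])


def ora(
    query: list[str],
    universe: list[str],
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """Over-representation of the query in each gene set: hypergeometric
    upper-tail p of the overlap within the universe, BH-adjusted across sets.

    Set members outside the universe are ignored; the query must be a subset
    of the universe.
    """
    uni = set(universe)
    q = set(query)
    stray = q - uni
    if stray:
        raise ValueError(f"query genes outside universe, e.g. {sorted(stray)[:3]}")
    rows = []
    for name, members in sets.items():
        mem = set(members) & uni
        if not mem:
            continue
        k = len(q & mem)
        p = hypergeom_tail(k, len(uni), len(mem), len(q))
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": len(mem),
                "query_size": len(q),
                "universe_size": len(uni),
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["set_name", "overlap", "set_size", "query_size", "universe_size", "p"]
    )
    if len(out):
        out["fdr"] = bh_fdr(out["p"].to_numpy())
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


def gsea_es(ranked: pd.Series, members: set, weight_p: float = 1.0) -> float:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score.

    ``ranked`` maps gene -> signed statistic, assumed sorted descending.
    Hits step up proportionally to |stat|^weight_p (normalised); misses step
    down by 1/(N - n_hits). ES is the maximum deviation from zero, signed.
    """
    genes = ranked.index.to_numpy()
    statv = np.abs(ranked.to_numpy()) ** weight_p
    is_hit = np.fromiter((g in members for g in genes), bool, len(genes))
    n_hit = int(is_hit.sum())
    if n_hit == 0:
        return float("nan")
    hit_total = statv[is_hit].sum()
    if hit_total == 0:  # all-zero statistics: equal hit weights
        steps_hit = is_hit / n_hit
    else:
        steps_hit = np.where(is_hit, statv, 0.0) / hit_total
    n_miss = len(genes) - n_hit
    steps_miss = np.where(~is_hit, 1.0 / n_miss, 0.0) if n_miss else np.zeros(len(genes))
    running = np.cumsum(steps_hit - steps_miss)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea(
    ranked: pd.Series,
    gene_set: list[str],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Enrichment score with gene-label permutation NES and p-value.

    Returns a dict with es, nes, p, n_hits. Genes of the set absent from the
    ranking are ignored; an empty intersection yields NaN statistics.
    """
    ranked = ranked.sort_values(ascending=False, kind="stable")
    members = set(gene_set) & set(ranked.index)
    if not members:
        log.warning("gsea: gene set does not intersect the ranking")
        return {"es": float("nan"), "nes": float("nan"), "p": float("nan"), "n_hits": 0}
    es = gsea_es(ranked, members, weight_p)
    rng = np.random.default_rng(seed)
    genes = ranked.index.to_numpy()
    perm_es = np.empty(n_perm)
    for b in range(n_perm):
        perm_members = set(rng.choice(genes, size=len(members), replace=False))
        perm_es[b] = gsea_es(ranked, perm_members, weight_p)
    scale = np.abs(perm_es).mean()
    nes = es / scale if scale > 0 else float("nan")
    p = (1.0 + np.sum(np.abs(perm_es) >= abs(es))) / (n_perm + 1.0)
    return {"es": es, "nes": nes, "p": float(p), "n_hits": len(members)}
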