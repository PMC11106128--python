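"""Weighted gene co-expression network analysis on spots or metacells.

The stage follows the classic recipe: pool similar spots into metacells,
sweep soft-threshold powers for approximate scale-free topology, raise the
(signed) correlation matrix to the chosen power, convert adjacency to
topological-overlap similarity, cluster genes on TOM dissimilarity into
colour-named modules, summarise each module by its eigengene (first
principal component), and score genes by kME (correlation with the
eigengene) to rank hubs and correlate modules with traits.

All randomness-free; results are fully determined by the input matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import ExpressionMatrix, SpotMetadata

log = logging.getLogger(__name__)

GREY = "grey"

# colour sequence for module naming, assigned by descending module size
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]


# ---------------------------------------------------------------------------
# metacells


def build_metacells(
    expr: ExpressionMatrix,
    meta: SpotMetadata,
    k_neighbors: int = 5,
    max_overlap: float = 0.5,
    n_pcs: int = 10,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Pool each spot with its k nearest neighbours (top-PC space) within a
    (cluster, condition, day) group; greedily reject metacells sharing more
    than ``max_overlap`` of members with an already accepted one.

    Returns the metacell expression (lognorm layer) and a metadata frame
    carrying the group labels of each metacell.
    """
    if expr.layer != "lognorm":
        raise ValueError("build_metacells expects the lognorm layer")
    mtab = meta.aligned_to(expr)
    groups = mtab.groupby(["cluster", "condition", "day"], sort=True).indices
    rows, ids, recs = [], [], []
    for (cluster, cond, day), idx in sorted(groups.items(), key=lambda kv: str(kv[0])):
        idx = np.sort(np.asarray(idx))
        X = expr.values[idx]
        gname = f"c{cluster}_{cond}{day}"
        if k_neighbors == 0 or len(idx) < k_neighbors + 1:
            if 0 < len(idx) < k_neighbors + 1 and k_neighbors > 0:
                log.warning(
                    "group %s has %d spots (< k+1=%d); emitted unpooled",
                    gname, len(idx), k_neighbors + 1,
                )
            for j, i in enumerate(idx):
                rows.append(expr.values[i])
                ids.append(f"{gname}_mc{j:04d}")
                recs.append({"cluster": cluster, "condition": cond, "day": day,
                             "x": 0.0, "y": 0.0})
            continue
        # neighbour search in top-PC space of the centred group matrix
        Xc = X - X.mean(axis=0)
        n_comp = min(n_pcs, *Xc.shape)
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        pcs = U[:, :n_comp] * s[:n_comp]
        d2 = ((pcs[:, None, :] - pcs[None, :, :]) ** 2).sum(axis=2)
        order = np.argsort(d2, axis=1, kind="stable")
        accepted: list[set] = []
        j = 0
        limit = max_overlap * (k_neighbors + 1)
        for i in range(len(idx)):
            members = set(order[i, : k_neighbors + 1].tolist())
            if any(len(members & a) > limit for a in accepted):
                continue
            accepted.append(members)
            rows.append(X[sorted(members)].mean(axis=0))
            ids.append(f"{gname}_mc{j:04d}")
            recs.append({"cluster": cluster, "condition": cond, "day": day,
                         "x": 0.0, "y": 0.0})
            j += 1
    out = ExpressionMatrix(np.asarray(rows), ids, list(expr.gene_ids), layer="lognorm")
    mc_meta = pd.DataFrame(recs, index=ids)
    return out, mc_meta


# ---------------------------------------------------------------------------
# soft power and adjacency


@dataclass
class SoftPowerResult:
    table: pd.DataFrame          # power, r2_signed, slope, mean_k
    chosen: int
    reached_threshold: bool


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit of a connectivity vector.

    Bins k into ``n_bins`` equal-width bins, regresses log10(frequency) on
    log10(mean k per bin) and returns (signed R^2, slope); the sign flips so
    a decreasing degree law scores positively. Degenerate inputs (constant k,
    fewer than 3 usable bins) return (nan, nan).
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size == 0 or np.isclose(k.max(), k.min()):
        return float("nan"), float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k, freq = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            mean_k.append(k[sel].mean())
            freq.append(sel.mean())
    if len(mean_k) < 3:
        return float("nan"), float("nan")
    lx, ly = np.log10(mean_k), np.log10(freq)
    fit = stats.linregress(lx, ly)
    signed = -np.sign(fit.slope) * fit.rvalue**2
    return float(signed), float(fit.slope)


def _correlation(expr: ExpressionMatrix) -> np.ndarray:
    """Gene-gene Pearson correlation; zero-variance genes get correlation 0."""
    X = expr.values
    sd = X.std(axis=0)
    n_const = int((sd == 0).sum())
    if n_const:
        log.warning("%d zero-variance genes; their correlations set to 0", n_const)
    Xz = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    Xz[:, sd == 0] = 0.0
    c = (Xz.T @ Xz) / X.shape[0]
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def adjacency(expr: ExpressionMatrix, beta: int, mode: str = "signed") -> np.ndarray:
    """Soft-thresholded adjacency: signed ((1+r)/2)^beta or unsigned |r|^beta."""
    if beta < 1:
        raise ValueError("soft power beta must be >= 1")
    c = _correlation(expr)
    if mode == "signed":
        a = ((1.0 + c) / 2.0) ** beta
    elif mode == "unsigned":
        a = np.abs(c) ** beta
    else:
        raise ValueError(f"unknown adjacency mode {mode!r}")
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


def connectivity(adj: np.ndarray) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} a_ij (diagonal excluded)."""
    return adj.sum(axis=1) - np.diag(adj)


def pick_soft_power(
    expr: ExpressionMatrix,
    powers=range(1, 31),
    r2_threshold: float = 0.8,
    n_bins: int = 10,
    mode: str = "signed",
) -> SoftPowerResult:
    """Sweep candidate powers and pick the smallest whose scale-free fit
    reaches the threshold (default 0.8); otherwise the argmax with a warning."""
    if expr.n_obs < 30:
        log.warning("pick_soft_power: only %d observations (<30)", expr.n_obs)
    c = _correlation(expr)
    base = (1.0 + c) / 2.0 if mode == "signed" else np.abs(c)
    rows = []
    for beta in powers:
        a = base**beta
        np.fill_diagonal(a, 1.0)
        k = connectivity(a)
        r2, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append({"power": int(beta), "r2_signed": r2, "slope": slope,
                     "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table[table["r2_signed"] >= r2_threshold]
    if len(ok):
        chosen = int(ok.iloc[0]["power"])
        reached = True
    else:
        if table["r2_signed"].notna().any():
            chosen = int(table.loc[table["r2_signed"].idxmax(), "power"])
        else:
            chosen = int(table["power"].iloc[0])
        reached = False
        log.warning(
            "no candidate power reached signed R^2 >= %.2f; using argmax beta=%d",
            r2_threshold, chosen,
        )
    return SoftPowerResult(table=table, chosen=chosen, reached_threshold=reached)


# ---------------------------------------------------------------------------
# topological overlap


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    TOM_ii = 1; pairs with a zero denominator get TOM 0.
    """
    a = np.asarray(adj, dtype=float)
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    shared = a0 @ a0                      # u=i and u=j terms vanish (zero diag)
    k = a0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a0
    num = shared + a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def tom_dissimilarity(adj: np.ndarray) -> np.ndarray:
    d = 1.0 - tom_similarity(adj)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class AdjacencyTOM:
    """Bundle of adjacency, connectivity and TOM for one network."""

    adjacency: np.ndarray
    connectivity: np.ndarray = field(default=None)
    tom: np.ndarray = field(default=None)
    dissimilarity: np.ndarray = field(default=None)

    @classmethod
    def from_expression(cls, expr: ExpressionMatrix, beta: int, mode: str = "signed"):
        a = adjacency(expr, beta, mode)
        t = tom_similarity(a)
        d = 1.0 - t
        np.fill_diagonal(d, 0.0)
        return cls(adjacency=a, connectivity=connectivity(a), tom=t, dissimilarity=d)


# ---------------------------------------------------------------------------
# module detection


def _first_pc(X: np.ndarray) -> np.ndarray:
    """Scores along the first principal component of an obs x genes block."""
    if X.shape[1] == 1:
        return X[:, 0].copy()
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    return U[:, 0] * s[0]


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def _eigengene(X: np.ndarray) -> np.ndarray:
    """Sign-oriented, unit-variance first PC of a module submatrix."""
    me = _first_pc(X)
    cors = []
    for j in range(X.shape[1]):
        sd = X[:, j].std()
        if sd > 0 and me.std() > 0:
            cors.append(np.corrcoef(me, X[:, j])[0, 1])
    if cors and np.mean(cors) < 0:
        me = -me
    return _standardize(me)


DEFAULT_CUT_HEIGHT = 0.95


def detect_modules(
    dissim: np.ndarray,
    expr: ExpressionMatrix,
    min_size: int = 30,
    cut_height: float | None = DEFAULT_CUT_HEIGHT,
    merge_corr: float = 0.75,
) -> pd.Series:
    """Average-linkage clustering of TOM dissimilarity into colour modules.

    A static cut defines the initial clusters; clusters below ``min_size``
    become grey; modules whose eigengenes correlate above ``merge_corr`` are
    merged iteratively. Surviving modules are named by a fixed colour
    sequence in order of decreasing size, so labels are reproducible.

    The default cut is a fixed dissimilarity height of 0.95: genes with no
    topological overlap sit near height 1, so the cut isolates any
    co-expressed subtree while leaving unassigned genes in sub-``min_size``
    fragments (grey). Passing ``cut_height=None`` instead cuts at the 0.99
    quantile of merge heights, which on sparse networks tends to land inside
    the unassigned-gene regime and is kept only as an explicit opt-in.
    """
    n = dissim.shape[0]
    if n != expr.n_genes:
        raise ValueError("dissimilarity size does not match gene count")
    condensed = squareform(dissim, checks=False)
    Z = linkage(condensed, method="average")
    if cut_height is None:
        cut_height = float(np.quantile(Z[:, 2], 0.99))
    raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=expr.gene_ids, dtype=object)
    sizes = labels.value_counts()
    small = sizes[sizes < min_size].index
    labels[labels.isin(small)] = GREY
    if (labels == GREY).all():
        log.warning("all genes grey: no cluster reached min_size=%d", min_size)
        return labels.astype(str)

    # iterative eigengene merge
    gidx = {g: i for i, g in enumerate(expr.gene_ids)}
    while True:
        mods = sorted(m for m in labels.unique() if m != GREY)
        if len(mods) < 2:
            break
        mes = {m: _eigengene(expr.values[:, [gidx[g] for g in labels.index[labels == m]]])
               for m in mods}
        best, best_r = None, merge_corr
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                r = np.corrcoef(mes[mods[i]], mes[mods[j]])[0, 1]
                if r > best_r:
                    best, best_r = (mods[i], mods[j]), r
        if best is None:
            break
        labels[labels == best[1]] = best[0]

    # deterministic colour naming by descending size (ties by first gene id)
    mods = [m for m in labels.unique() if m != GREY]
    keyed = sorted(
        mods,
        key=lambda m: (-int((labels == m).sum()), labels.index[labels == m][0]),
    )
    rename = {}
    for i, m in enumerate(keyed):
        rename[m] = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
    return labels.map(lambda m: GREY if m == GREY else rename[m]).astype(str)


# ---------------------------------------------------------------------------
# eigengenes, kME, hubs, correlations


def module_eigengenes(expr: ExpressionMatrix, labels: pd.Series) -> pd.DataFrame:
    """Per-module eigengene scores (observations x modules), sign-oriented so
    mean member correlation is positive, standardized to unit variance."""
    if expr.layer != "scaled":
        raise ValueError("module_eigengenes expects the scaled layer")
    gidx = {g: i for i, g in enumerate(expr.gene_ids)}
    mods = sorted(m for m in labels.unique() if m != GREY)
    cols = {}
    for m in mods:
        genes = [g for g in labels.index[labels == m] if g in gidx]
        if not genes:
            continue
        cols[m] = _eigengene(expr.values[:, [gidx[g] for g in genes]])
    return pd.DataFrame(cols, index=expr.obs_ids)


def compute_kme(expr: ExpressionMatrix, mes: pd.DataFrame) -> pd.DataFrame:
    """kME[g, m] = Pearson correlation of gene g with module eigengene m."""
    X = expr.values
    sd = X.std(axis=0)
    Xz = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    Xz[:, sd == 0] = 0.0
    out = {}
    for m in mes.columns:
        me = mes[m].to_numpy()
        mez = (me - me.mean()) / (me.std() if me.std() > 0 else 1.0)
        out[m] = np.clip(Xz.T @ mez / X.shape[0], -1.0, 1.0)
    return pd.DataFrame(out, index=expr.gene_ids)


def select_hub_genes(
    kme: pd.DataFrame, labels: pd.Series, top_n: int = 100
) -> pd.DataFrame:
    """Top-``top_n`` genes per module by own-module kME (ties: lexicographic)."""
    rows = []
    for m in kme.columns:
        genes = [g for g in labels.index[labels == m] if g in kme.index]
        ranked = sorted(genes, key=lambda g: (-kme.loc[g, m], g))[:top_n]
        for rank, g in enumerate(ranked, start=1):
            rows.append({"module": m, "gene": g, "kme": float(kme.loc[g, m]), "rank": rank})
    return pd.DataFrame(rows, columns=["module", "gene", "kme", "rank"])


def module_correlations(mes: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation among module eigengenes (unit diagonal)."""
    return mes.corr(method="pearson")


def make_trait_matrix(meta: pd.DataFrame) -> pd.DataFrame:
    """One-hot day / condition / cluster indicator traits aligned to rows."""
    out = {}
    for d in sorted(meta["day"].unique()):
        out[f"day_{d}"] = (meta["day"] == d).astype(float)
    out["condition_A"] = (meta["condition"] == "A").astype(float)
    for c in sorted(meta["cluster"].unique()):
        out[f"cluster_{c}"] = (meta["cluster"] == c).astype(float)
    return pd.DataFrame(out, index=meta.index)


def module_trait_correlation(
    mes: pd.DataFrame, traits: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided test p for every (module eigengene, trait)."""
    if len(mes) != len(traits):
        raise ValueError("eigengene and trait matrices have different row counts")
    r = pd.DataFrame(index=mes.columns, columns=traits.columns, dtype=float)
    p = pd.DataFrame(index=mes.columns, columns=traits.columns, dtype=float)
    for m in mes.columns:
        for t in traits.columns:
            tv = traits[t].to_numpy()
            if tv.std() == 0 or mes[m].std() == 0:
                r.loc[m, t], p.loc[m, t] = np.nan, np.nan
                continue
            res = stats.pearsonr(mes[m].to_numpy(), tv)
            r.loc[m, t], p.loc[m, t] = res.statistic, res.pvalue
    return r, p


# ---------------------------------------------------------------------------
# convenience pipeline


def run_wgcna(
    expr_lognorm: ExpressionMatrix,
    meta: SpotMetadata,
    use_metacells: bool = True,
    k_neighbors: int = 5,
    max_overlap: float = 0.5,
    powers=range(1, 31),
    r2_threshold: float = 0.8,
    mode: str = "signed",
    min_size: int = 30,
    cut_height: float | None = DEFAULT_CUT_HEIGHT,
    merge_corr: float = 0.75,
    top_n_hubs: int = 100,
) -> dict:
    """End-to-end co-expression stage; returns a dict of all result tables."""
    from .preprocess import scale_genes

    if use_metacells:
        pooled, pooled_meta = build_metacells(expr_lognorm, meta, k_neighbors, max_overlap)
    else:
        pooled, pooled_meta = expr_lognorm, meta.aligned_to(expr_lognorm)
    scaled = scale_genes(pooled)
    sp = pick_soft_power(scaled, powers=powers, r2_threshold=r2_threshold, mode=mode)
    net = AdjacencyTOM.from_expression(scaled, sp.chosen, mode=mode)
    labels = detect_modules(net.dissimilarity, scaled, min_size=min_size,
                            cut_height=cut_height, merge_corr=merge_corr)
    mes = module_eigengenes(scaled, labels)
    kme = compute_kme(scaled, mes)
    hubs = select_hub_genes(kme, labels, top_n=top_n_hubs)
    traits = make_trait_matrix(pooled_meta)
    mt_r, mt_p = module_trait_correlation(mes, traits)
    return {
        "metacells": pooled,
        "metacell_meta": pooled_meta,
        "soft_power": sp,
        "network": net,
        "labels": labels,
        "mes": mes,
        "kme": kme,
        "hubs": hubs,
        "module_corr": module_correlations(mes),
        "module_trait_r": mt_r,
        "module_trait_p": mt_p,
    }
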