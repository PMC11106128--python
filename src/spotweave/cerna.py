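"""Competing-endogenous-RNA inference from a miRNA target map.

A lncRNA or circRNA is proposed as a ceRNA of an mRNA when the two share
more miRNA targets than expected by chance. For target sets A (|A| = K) and
B (|B| = n) drawn from a universe of N miRNAs, the shared count k is tested
against the hypergeometric upper tail P(X >= k); pairs are kept at
p < 0.01 and BH FDR < 0.01 and must additionally show positive expression
correlation (r > 0) across matched bulk samples. Retained pairs are expanded
into ceRNA-miRNA-mRNA triads and ranked by degree and betweenness
centrality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix

log = logging.getLogger(__name__)

RNA_CLASSES = ("mRNA", "lncRNA", "circRNA")
CERNA_CLASSES = ("lncRNA", "circRNA")

P_MAX_DEFAULT = 0.01
FDR_MAX_DEFAULT = 0.01


# ---------------------------------------------------------------------------
# target map


@dataclass
class TargetMap:
    """rna_id -> miRNA target set, typed by RNA class."""

    targets: dict[str, frozenset] = field(default_factory=dict)
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, t in self.targets.items():
            if not t:
                raise ValueError(f"empty target set for {rid}")
            cls = self.classes.get(rid)
            if cls not in RNA_CLASSES:
                raise ValueError(f"{rid}: unknown RNA class {cls!r}")

    @property
    def universe(self) -> frozenset:
        out: set = set()
        for t in self.targets.values():
            out |= t
        return frozenset(out)

    def ids_of_class(self, cls: str) -> list[str]:
        return sorted(r for r, c in self.classes.items() if c == cls)

    @classmethod
    def from_dict(cls, d: dict) -> "TargetMap":
        """Build from {rna_id: (rna_class, iterable-of-miRNAs)}."""
        return cls(
            targets={r: frozenset(t) for r, (c, t) in d.items()},
            classes={r: c for r, (c, t) in d.items()},
        )

    @classmethod
    def read_tsv(cls, path) -> "TargetMap":
        """Columns: rna_id, rna_class, mirnas (comma-separated)."""
        df = pd.read_csv(path, sep="\t")
        return cls(
            targets={
                str(r.rna_id): frozenset(str(r.mirnas).split(","))
                for r in df.itertuples(index=False)
            },
            classes={str(r.rna_id): str(r.rna_class) for r in df.itertuples(index=False)},
        )

    def to_tsv(self, path) -> None:
        rows = [
            {"rna_id": r, "rna_class": self.classes[r], "mirnas": ",".join(sorted(t))}
            for r, t in sorted(self.targets.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# hypergeometric engine (shared with over-representation analysis)


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n); exact 1 at k <= 0."""
    if k <= 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, K, n)))


def shared_target_test(targets_a, targets_b, universe) -> tuple[int, float]:
    """Shared-target count and hypergeometric tail p for two target sets.

    ``universe`` may be the miRNA universe itself (membership is validated)
    or its size as an integer. Symmetric in the two sets.
    """
    a, b = frozenset(targets_a), frozenset(targets_b)
    if isinstance(universe, (int, np.integer)):
        N = int(universe)
    else:
        uni = frozenset(universe)
        stray = (a | b) - uni
        if stray:
            raise ValueError(f"target ids outside the universe: {sorted(stray)[:5]}")
        N = len(uni)
    if max(len(a), len(b)) > N:
        raise ValueError("target set larger than the universe")
    k = len(a & b)
    return k, hypergeom_tail(k, N, len(a), len(b))


# ---------------------------------------------------------------------------
# pair screening


def candidate_pairs(
    tmap: TargetMap,
    p_max: float = P_MAX_DEFAULT,
    fdr_max: float = FDR_MAX_DEFAULT,
    universe_size: int | None = None,
    pool_fdr: bool = False,
) -> pd.DataFrame:
    """Test every (lncRNA|circRNA, mRNA) pair for shared-target enrichment.

    BH correction runs within each ceRNA class (the circRNA and lncRNA
    networks are built separately) unless ``pool_fdr``. Rows are the pairs
    surviving p < p_max and FDR < fdr_max, ordered by (cerna_id, mrna_id).
    """
    mrnas = tmap.ids_of_class("mRNA")
    cernas = [r for c in CERNA_CLASSES for r in tmap.ids_of_class(c)]
    if not mrnas or not cernas:
        log.warning("candidate_pairs: nothing to test (need >=1 ceRNA and >=1 mRNA)")
        return pd.DataFrame(
            columns=["cerna_id", "cerna_class", "mrna_id", "k_shared", "K", "n", "p", "fdr"]
        )
    N = universe_size if universe_size is not None else len(tmap.universe)
    rows = []
    for cid in sorted(cernas):
        A = tmap.targets[cid]
        for mid in mrnas:
            k, p = shared_target_test(A, tmap.targets[mid], N)
            rows.append(
                {
                    "cerna_id": cid,
                    "cerna_class": tmap.classes[cid],
                    "mrna_id": mid,
                    "k_shared": k,
                    "K": len(A),
                    "n": len(tmap.targets[mid]),
                    "p": p,
                }
            )
    df = pd.DataFrame(rows)
    df["fdr"] = np.nan
    groups = [df.index] if pool_fdr else [
        df.index[df["cerna_class"] == c] for c in CERNA_CLASSES
    ]
    for idx in groups:
        if len(idx):
            df.loc[idx, "fdr"] = multipletests(df.loc[idx, "p"], method="fdr_bh")[1]
    kept = df[(df["p"] < p_max) & (df["fdr"] < fdr_max)]
    return kept.sort_values(["cerna_id", "mrna_id"], kind="stable").reset_index(drop=True)


def coexpression_filter(pairs: pd.DataFrame, expr: ExpressionMatrix) -> pd.DataFrame:
    """Attach sample-level Pearson r per pair and keep strictly positive r.

    Pairs with a member absent from the expression table, or with a constant
    expression vector (undefined r), are dropped and counted in the log.
    """
    if expr.n_obs < 3:
        raise ValueError("co-expression filter needs >= 3 samples")
    gidx = expr.gene_index()
    rs, keep = [], []
    n_missing = n_constant = 0
    for row in pairs.itertuples(index=False):
        if row.cerna_id not in gidx or row.mrna_id not in gidx:
            n_missing += 1
            rs.append(np.nan)
            keep.append(False)
            continue
        x = expr.values[:, gidx[row.cerna_id]]
        y = expr.values[:, gidx[row.mrna_id]]
        if x.std() == 0 or y.std() == 0:
            n_constant += 1
            rs.append(np.nan)
            keep.append(False)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rs.append(r)
        keep.append(r > 0)
    if n_missing:
        log.warning("coexpression_filter: %d pairs missing from expression", n_missing)
    if n_constant:
        log.warning("coexpression_filter: %d pairs with constant expression dropped", n_constant)
    out = pairs.copy()
    out["r"] = rs
    return out[np.asarray(keep, dtype=bool)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# triad networks


@dataclass
class CeRNANetwork:
    """Typed ceRNA-miRNA-mRNA graph with per-class node counts."""

    graph: nx.Graph
    class_counts: pd.DataFrame

    def node_table(self) -> pd.DataFrame:
        rows = [
            {"node": n, "node_type": d.get("node_type", "")}
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows, columns=["node", "node_type"])


def assemble_triads(
    pairs: pd.DataFrame, tmap: TargetMap, de_table: pd.DataFrame
) -> CeRNANetwork:
    """Expand retained pairs whose mRNA is DE-selected into a typed network.

    For each kept pair, one edge ceRNA-miRNA and one edge miRNA-mRNA is added
    per shared miRNA. mRNA nodes carry the DE direction (up/down) for the
    usual red/blue display convention.
    """
    if "selected" in de_table.columns:
        de_sel = de_table[de_table["selected"].astype(bool)]
    else:
        de_sel = de_table
    de_genes = set(de_sel["gene"])
    direction = dict(zip(de_sel["gene"], de_sel.get("direction", ""), strict=False))
    g = nx.Graph()
    for row in pairs.itertuples(index=False):
        if row.mrna_id not in de_genes:
            continue
        shared = sorted(tmap.targets[row.cerna_id] & tmap.targets[row.mrna_id])
        if not shared:
            continue
        g.add_node(row.cerna_id, node_type=tmap.classes[row.cerna_id])
        g.add_node(row.mrna_id, node_type="mRNA", direction=str(direction.get(row.mrna_id, "")))
        for m in shared:
            g.add_node(m, node_type="miRNA")
            g.add_edge(row.cerna_id, m, interaction="ceRNA-miRNA")
            g.add_edge(m, row.mrna_id, interaction="miRNA-mRNA")
    counts = (
        pd.Series([d["node_type"] for _, d in g.nodes(data=True)], dtype=str)
        .value_counts()
        .rename_axis("node_type")
        .reset_index(name="count")
        .sort_values("node_type", kind="stable")
        .reset_index(drop=True)
    )
    return CeRNANetwork(graph=g, class_counts=counts)


# ---------------------------------------------------------------------------
# centrality rankings


def betweenness_ranking(graph: nx.Graph) -> pd.DataFrame:
    """Nodes sorted by unnormalised betweenness centrality (each unordered
    pair of endpoints counted once; Brandes' algorithm), ties by node id."""
    bc = nx.betweenness_centrality(graph, normalized=False)
    rows = [
        {
            "node": n,
            "node_type": graph.nodes[n].get("node_type", ""),
            "betweenness": float(bc[n]),
        }
        for n in graph.nodes
    ]
    rows.sort(key=lambda r: (-r["betweenness"], r["node"]))
    df = pd.DataFrame(rows, columns=["node", "node_type", "betweenness"])
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def connectivity_ranking(graph: nx.Graph) -> pd.DataFrame:
    """Nodes sorted by degree (ties by id); the top node per RNA class is
    flagged as the class's highest-connectivity hub."""
    rows = [
        {
            "node": n,
            "node_type": graph.nodes[n].get("node_type", ""),
            "degree": int(graph.degree[n]),
        }
        for n in graph.nodes
    ]
    rows.sort(key=lambda r: (-r["degree"], r["node"]))
    df = pd.DataFrame(rows, columns=["node", "node_type", "degree"])
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    tops = set()
    for cls in df["node_type"].unique():
        sub = df[df["node_type"] == cls]
        if len(sub):
            tops.add(sub.iloc[0]["node"])
    df["top_in_class"] = df["node"].isin(tops)
    return df
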