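"""Pathway-activity scoring from a responsive-gene weight matrix, cluster
summaries, non-negative matrix factorisation and factor-pathway correlation.

A pathway's spot score is the weight-matrix projection of the scaled
expression, S[i, p] = sum_g Z[i, g] * W[g, p]; scaled scores are per-pathway
z-scores across spots. The weight table (gene x pathway, signed reals, e.g.
an exported published responsive-gene model or the synthetic generator's
planted weights) is an input, never trained here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .datatypes import ExpressionMatrix

log = logging.getLogger(__name__)


def read_pathway_weights(path) -> pd.DataFrame:
    """Gene x pathway TSV of signed weights (first column = gene id)."""
    w = pd.read_csv(path, sep="\t", index_col=0)
    if w.shape[1] == 0:
        raise ValueError("pathway weight table has no pathway columns")
    return w


@dataclass
class PathwayActivity:
    """Raw and per-pathway-scaled spot scores."""

    raw: pd.DataFrame      # spots x pathways
    scaled: pd.DataFrame   # per-pathway z-scores


def score_pathways(expr: ExpressionMatrix, weights: pd.DataFrame) -> PathwayActivity:
    """Project scaled expression through the pathway weight matrix.

    Genes are intersected with the weight table's rows (warning when fewer
    than half the model genes are present); pathways with no nonzero weight
    on any present gene are dropped with a warning.
    """
    if expr.layer != "scaled":
        raise ValueError("score_pathways expects the scaled layer")
    present = [g for g in weights.index if g in set(expr.gene_ids)]
    if len(present) < 0.5 * len(weights.index):
        log.warning(
            "only %d/%d weight-model genes present in the expression matrix",
            len(present), len(weights.index),
        )
    if not present:
        raise ValueError("no weight-model genes present in the expression matrix")
    W = weights.loc[present]
    dead = [p for p in W.columns if not (W[p] != 0).any()]
    if dead:
        log.warning("pathways with no usable genes dropped: %s", dead)
        W = W.drop(columns=dead)
    Z = expr.subset_genes(present).values
    raw = pd.DataFrame(Z @ W.to_numpy(), index=expr.obs_ids, columns=W.columns)
    sd = raw.std(axis=0, ddof=0)
    scaled = (raw - raw.mean(axis=0)) / sd.where(sd > 0, 1.0)
    scaled.loc[:, sd == 0] = 0.0
    return PathwayActivity(raw=raw, scaled=scaled)


def cluster_mean_scores(
    activity: PathwayActivity, meta: pd.DataFrame, by=("cluster",)
) -> pd.DataFrame:
    """Mean scaled score per group (default: anatomical cluster) x pathway."""
    scores = activity.scaled
    if len(scores) != len(meta):
        raise ValueError("activity and metadata have different row counts")
    grouped = scores.groupby([meta[b].to_numpy() for b in by]).mean()
    grouped.index.set_names(list(by), inplace=True)
    return grouped


# ---------------------------------------------------------------------------
# non-negative matrix factorisation


def shift_nonnegative(expr: ExpressionMatrix) -> pd.DataFrame:
    """Scaled expression shifted per gene so each column's minimum is 0 -
    the documented transform feeding NNMF."""
    vals = expr.values
    return pd.DataFrame(
        vals - vals.min(axis=0), index=expr.obs_ids, columns=expr.gene_ids
    )


def nnmf(
    matrix,
    k: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiplicative-update NNMF (Frobenius loss): X ~ W @ H, W >= 0, H >= 0.

    Deterministic given ``seed`` (uniform random init scaled to the data
    magnitude); iteration stops when the relative loss change drops below
    ``tol`` or after ``max_iter`` updates. Returns (W, H, loss_trace) with
    the loss recorded at init and after every update.
    """
    X = np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError(
            "NNMF input has negative entries; shift the scaled layer first "
            "(see shift_nonnegative)"
        )
    n, m = X.shape
    if not 1 <= k < min(n, m):
        raise ValueError(f"k={k} must satisfy 1 <= k < min{X.shape}")
    if not X.any():
        return np.zeros((n, k)), np.zeros((k, m)), np.array([0.0])
    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / k)
    W = rng.uniform(1e-4, 1.0, size=(n, k)) * scale
    H = rng.uniform(1e-4, 1.0, size=(k, m)) * scale
    eps = 1e-12
    losses = [float(np.linalg.norm(X - W @ H, "fro") ** 2)]
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + eps)
        W *= (X @ H.T) / (W @ H @ H.T + eps)
        loss = float(np.linalg.norm(X - W @ H, "fro") ** 2)
        losses.append(loss)
        prev = losses[-2]
        if prev > 0 and (prev - loss) / prev < tol:
            break
    return W, H, np.asarray(losses)


def nnmf_per_sample(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    k: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    pooled: bool = False,
) -> dict:
    """One factorisation per (condition, day) section, mirroring per-sample
    unsupervised decomposition; ``pooled`` factorises all spots at once.

    Returns {section_label: (W_df, H_df, loss_trace)}.
    """
    X = shift_nonnegative(expr)
    out = {}
    if pooled:
        groups = {"pooled": np.arange(len(X))}
    else:
        keys = meta["condition"].astype(str) + meta["day"].astype(str)
        groups = {lab: np.flatnonzero(keys.to_numpy() == lab) for lab in sorted(keys.unique())}
    for i, (lab, idx) in enumerate(sorted(groups.items())):
        W, H, losses = nnmf(X.to_numpy()[idx], k=k, seed=seed + i, max_iter=max_iter, tol=tol)
        W_df = pd.DataFrame(
            W, index=[X.index[j] for j in idx],
            columns=[f"factor_{f:02d}" for f in range(k)],
        )
        H_df = pd.DataFrame(H, index=W_df.columns, columns=X.columns)
        out[lab] = (W_df, H_df, losses)
    return out


def factor_pathway_correlation(
    factors: pd.DataFrame, activity: PathwayActivity, cluster_order: bool = True
) -> pd.DataFrame:
    """Pearson correlation of each spot-factor column with each scaled
    pathway-score column, rows/columns ordered by hierarchical clustering
    for heat-map display (set ``cluster_order=False`` to keep input order)."""
    scores = activity.scaled.loc[factors.index]
    out = pd.DataFrame(index=factors.columns, columns=scores.columns, dtype=float)
    for f in factors.columns:
        fv = factors[f].to_numpy()
        for p in scores.columns:
            pv = scores[p].to_numpy()
            if fv.std() == 0 or pv.std() == 0:
                out.loc[f, p] = np.nan
            else:
                out.loc[f, p] = float(np.corrcoef(fv, pv)[0, 1])
    if cluster_order and out.notna().all().all() and min(out.shape) > 2:
        row_order = leaves_list(linkage(out.to_numpy(), method="average"))
        col_order = leaves_list(linkage(out.to_numpy().T, method="average"))
        out = out.iloc[row_order, col_order]
    return out
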