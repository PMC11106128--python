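"""Depth normalisation and per-gene scaling.

``normalize_log`` rescales each spot to a common library size before a log1p
transform, so downstream correlations are not driven by sequencing depth;
``scale_genes`` z-scores each gene across observations (population SD), the
form expected by the co-expression and pathway-scoring stages.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import ExpressionMatrix

log = logging.getLogger(__name__)

DEFAULT_SCALE = 10_000.0  # CPM-like per-spot target depth


def normalize_log(expr: ExpressionMatrix, scale: float = DEFAULT_SCALE) -> ExpressionMatrix:
    """log(1 + counts * scale / depth) per spot; zero-depth spots stay all-zero."""
    if expr.layer != "counts":
        raise ValueError(f"normalize_log expects a counts layer, got {expr.layer!r}")
    counts = expr.values
    depth = counts.sum(axis=1)
    n_empty = int((depth == 0).sum())
    if n_empty:
        log.warning("normalize_log: %d observations with zero depth left as zero rows", n_empty)
    safe_depth = np.where(depth > 0, depth, 1.0)
    vals = np.log1p(counts * (scale / safe_depth[:, None]))
    return ExpressionMatrix(vals, list(expr.obs_ids), list(expr.gene_ids), layer="lognorm")


def scale_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-score (population SD, divisor n); constant genes become 0."""
    if expr.layer != "lognorm":
        raise ValueError(f"scale_genes expects a lognorm layer, got {expr.layer!r}")
    vals = expr.values
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0)  # population SD
    safe_sd = np.where(sd > 0, sd, 1.0)
    scaled = (vals - mean) / safe_sd
    scaled[:, sd == 0] = 0.0
    return ExpressionMatrix(scaled, list(expr.obs_ids), list(expr.gene_ids), layer="scaled")
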