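"""Core in-memory containers shared across the pipeline.

The central object is :class:`ExpressionMatrix`, an observation-major
(rows = spots / metacells / samples, columns = genes) dense numeric matrix
with a ``layer`` tag recording which transform produced it:

* ``counts``  — raw non-negative integers,
* ``lognorm`` — depth-normalised log1p values,
* ``scaled``  — per-gene z-scores (population SD; constant genes set to 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_LAYERS = ("counts", "lognorm", "scaled")


@dataclass
class ExpressionMatrix:
    """Dense observations x genes matrix with named axes and a layer tag."""

    values: np.ndarray
    obs_ids: list[str]
    gene_ids: list[str]
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.obs_ids = [str(o) for o in self.obs_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_obs, n_genes = self.values.shape
        if n_obs != len(self.obs_ids):
            raise ValueError(
                f"matrix has {n_obs} rows but {len(self.obs_ids)} observation ids"
            )
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"matrix has {n_genes} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.obs_ids)) != n_obs:
            raise ValueError("observation ids are not unique")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene ids are not unique")
        if self.layer not in VALID_LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {VALID_LAYERS}")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values contain NaN/Inf")
        if self.layer == "counts" and (self.values < 0).any():
            raise ValueError("counts layer contains negative entries")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.obs_ids, columns=self.gene_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        cols = [idx[g] for g in genes]
        return ExpressionMatrix(self.values[:, cols], list(self.obs_ids), list(genes), self.layer)

    def subset_obs(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            rows = np.flatnonzero(mask)
        else:
            rows = mask
        return ExpressionMatrix(
            self.values[rows], [self.obs_ids[i] for i in rows], list(self.gene_ids), self.layer
        )


@dataclass
class SpotMetadata:
    """Per-spot annotations: anatomical cluster, condition, gestational day, position.

    ``cluster`` is the 0-7 anatomical annotation, ``condition`` is N (normal)
    or A (affected/malformation), ``day`` the gestational day (14-16), and
    x/y the hexagonal grid coordinates in arbitrary units.
    """

    table: pd.DataFrame  # index = obs_id; columns cluster, condition, day, x, y

    REQUIRED = ("cluster", "condition", "day", "x", "y")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate obs_id in metadata")
        cl = self.table["cluster"].to_numpy()
        if ((cl < 0) | (cl > 7)).any():
            raise ValueError("cluster annotation outside 0-7")
        bad = set(self.table["condition"].unique()) - {"N", "A"}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    def aligned_to(self, expr: ExpressionMatrix) -> pd.DataFrame:
        """Rows of the metadata in the matrix's observation order (all must exist)."""
        missing = [o for o in expr.obs_ids if o not in self.table.index]
        if missing:
            raise ValueError(f"{len(missing)} observations missing from metadata, e.g. {missing[:3]}")
        return self.table.loc[expr.obs_ids]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), e.g. GO terms or pathway signatures."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()
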