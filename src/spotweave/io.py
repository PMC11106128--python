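"""Readers and writers: MatrixMarket expression, TSV metadata, GMT gene sets,
and network export (SIF / GraphML / edge-list TSV)."""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datatypes import ExpressionMatrix, GeneSetCollection, SpotMetadata

log = logging.getLogger(__name__)


def _read_annotation(path) -> list[str]:
    """One identifier per line; if tab-separated, the first column is the id."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ids.append(line.split("\t")[0])
    return ids


def load_expression(matrix_path, genes_path, barcodes_path) -> ExpressionMatrix:
    """Load a spots x genes counts matrix from MatrixMarket + annotation files.

    The matrix file stores observations as rows and genes as columns; entries
    omitted from the sparse coordinate file are zeros.
    """
    mat = spio.mmread(matrix_path)
    if sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    obs_ids = _read_annotation(barcodes_path)
    gene_ids = _read_annotation(genes_path)
    n_obs, n_genes = mat.shape
    if len(obs_ids) != n_obs:
        raise ValueError(
            f"barcode file has {len(obs_ids)} entries but matrix has {n_obs} rows"
        )
    if len(gene_ids) != n_genes:
        raise ValueError(
            f"gene file has {len(gene_ids)} entries but matrix has {n_genes} columns"
        )
    if (mat < 0).any():
        raise ValueError("count matrix contains negative entries")
    return ExpressionMatrix(mat, obs_ids, gene_ids, layer="counts")


def save_expression(expr: ExpressionMatrix, matrix_path, genes_path, barcodes_path) -> None:
    """Write an ExpressionMatrix as MatrixMarket + annotation files (round-trips
    losslessly with :func:`load_expression` for integer counts)."""
    vals = expr.values
    if expr.layer == "counts" and np.allclose(vals, np.round(vals)):
        mat = sparse.coo_matrix(vals.astype(np.int64))
        spio.mmwrite(str(matrix_path), mat, field="integer")
    else:
        spio.mmwrite(str(matrix_path), sparse.coo_matrix(vals), precision=17)
    Path(genes_path).write_text("".join(g + "\n" for g in expr.gene_ids))
    Path(barcodes_path).write_text("".join(o + "\n" for o in expr.obs_ids))


def load_metadata(path) -> SpotMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SpotMetadata(df)


def save_metadata(meta: SpotMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="obs_id")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member1<TAB>member2...``.

    Lines with fewer than three fields are skipped with a warning.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    n_skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                n_skipped += 1
                continue
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            seen: list[str] = []
            for g in genes:
                if g not in seen:
                    seen.append(g)
            sets[name] = seen
            descriptions[name] = desc
    if n_skipped:
        log.warning("read_gmt: skipped %d malformed lines (<3 fields)", n_skipped)
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_network(graph: nx.Graph, path, format: str = "graphml") -> None:
    """Export a (typed, attributed) network as SIF, GraphML or edge-list TSV.

    SIF lines are ``source<TAB>interaction<TAB>target`` using each edge's
    ``interaction`` attribute (default ``"pp"``). GraphML round-trips node and
    edge attribute dictionaries.
    """
    path = Path(path)
    if format == "sif":
        with open(path, "w") as fh:
            for u, v, data in sorted(graph.edges(data=True)):
                fh.write(f"{u}\t{data.get('interaction', 'pp')}\t{v}\n")
    elif format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "tsv":
        rows = []
        for u, v, data in sorted(graph.edges(data=True)):
            rows.append({"source": u, "target": v, **data})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}; use sif, graphml or tsv")


def read_network(path, format: str = "graphml") -> nx.Graph:
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "sif":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 3:
                    g.add_edge(parts[0], parts[2], interaction=parts[1])
        return g
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        attr_cols = [c for c in df.columns if c not in ("source", "target")]
        for row in df.itertuples(index=False):
            d = row._asdict()
            g.add_edge(str(d["source"]), str(d["target"]), **{c: d[c] for c in attr_cols})
        return g
    raise ValueError(f"unknown network format {format!r}")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Uniform TSV emitter for result tables; floats at full precision."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
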