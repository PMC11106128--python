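"""Synthetic Visium-like sections and whole-transcriptome ncRNA tables with
planted ground truth.

The spatial generator emulates the study design every downstream stage
expects: six sections (normal and affected embryos at gestational days
14-16), each an 8-cluster hexagonal-grid section, with negative-binomial
counts whose log-means carry

* planted gene modules whose activities depend on (cluster, day), alternating
  between an "early" profile (high on days 14/15, low on day 16) and the
  complementary "late" profile, so module-trait correlations exist by
  construction;
* planted pathway activities injected through a signed gene x pathway weight
  matrix (the same matrix the scoring stage consumes);
* condition-shifted genes with exactly known log2 fold changes.

The ncRNA generator emulates a matched bulk whole-transcriptome dataset:
a miRNA target map in which planted ceRNA/mRNA pairs share an above-chance
fraction of targets, plus a sample-level expression table in which planted
pairs co-vary through a latent factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, SpotMetadata

# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic generators.

    Defaults give ~2,000 spots x 1,500 genes over six sections and 40 planted
    ceRNA triples among several thousand background pairs; the whole pipeline
    runs in a few minutes on one CPU at these sizes.
    """

    n_clusters: int = 8
    spots_per_cluster: int = 42          # per section
    conditions: tuple = ("N", "A")
    days: tuple = (14, 15, 16)
    n_genes: int = 1500
    n_modules: int = 10
    genes_per_module: int = 40
    module_effect: float = 1.2           # loading scale b on log-mean
    nb_dispersion: float = 10.0          # theta; var = m + m^2/theta
    base_mean: float = 2.0               # baseline expected count per gene
    pathway_count: int = 14
    pathway_genes_per_pathway: int = 30
    pathway_effect: float = 0.6          # scale of activity injected via weights
    n_de_genes: int = 100
    de_log2fc: float = 1.0               # magnitude of planted condition effect
    n_mirnas: int = 300
    n_cerna_triples: int = 40
    n_background_cerna: int = 20
    n_background_mrna: int = 20
    target_set_size: tuple = (25, 35)    # inclusive range
    shared_target_overlap: float = 0.8
    n_samples: int = 24                  # bulk samples for co-expression
    latent_loading: float = 0.7          # planted-pair expression loading
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_clusters", "spots_per_cluster", "n_genes", "n_modules",
            "genes_per_module", "pathway_count", "pathway_genes_per_pathway",
            "n_de_genes", "n_mirnas", "n_cerna_triples", "n_samples",
        ):
            if getattr(self, name) < 0 or (
                name not in ("n_de_genes",) and getattr(self, name) == 0
            ):
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 < self.shared_target_overlap <= 1.0:
            raise ValueError("shared_target_overlap must be in (0, 1]")
        reserved = (
            self.n_modules * self.genes_per_module
            + self.pathway_count * self.pathway_genes_per_pathway
            + self.n_de_genes
        )
        if self.n_genes < reserved:
            raise ValueError(
                f"n_genes={self.n_genes} cannot host {reserved} planted genes "
                "(modules + pathway genes + condition-shifted genes)"
            )
        if self.shared_target_overlap * self.target_set_size[0] < 1:
            raise ValueError("overlap x target_set_size < 1: no shareable targets")

    # deterministic gene-index blocks: modules, then pathway genes, then
    # condition-shifted genes, then unstructured background
    @property
    def module_gene_slice(self) -> slice:
        return slice(0, self.n_modules * self.genes_per_module)

    @property
    def pathway_gene_slice(self) -> slice:
        a = self.n_modules * self.genes_per_module
        return slice(a, a + self.pathway_count * self.pathway_genes_per_pathway)

    @property
    def de_gene_slice(self) -> slice:
        a = self.pathway_gene_slice.stop
        return slice(a, a + self.n_de_genes)


@dataclass
class GroundTruth:
    """Planted structure used as the recovery oracle by the test-suite."""

    module_labels: pd.Series = None          # gene -> "M<k>" ("" = background)
    module_activity: pd.DataFrame = None     # spots x modules (f_m)
    module_day_profile: pd.DataFrame = None  # modules x days (+1/-1 pattern)
    pathway_activity: pd.DataFrame = None    # spots x pathways (a_p)
    pathway_weights: pd.DataFrame = None     # genes x pathways (W)
    de_genes: pd.DataFrame = None            # gene, true_log2fc
    triples: pd.DataFrame = None             # cerna_id, cerna_class, mrna_id, shared_mirnas
    target_map: dict = field(default_factory=dict)


def _gene_names(n: int) -> list[str]:
    return [f"gene_{i:04d}" for i in range(n)]


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative binomial with mean m and variance m + m^2/theta."""
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p).astype(float)


def _hex_section(rng: np.random.Generator, n_clusters: int, spots_per_cluster: int):
    """Axial hexagonal grid partitioned into contiguous cluster blobs.

    Returns (x, y, cluster) arrays of length n_clusters * spots_per_cluster.
    Geometry is cosmetic (no analysis stage reads x/y) but mirrors the
    110-um-pitch hexagonal spot layout of the platform.
    """
    side = int(np.ceil(np.sqrt(n_clusters * spots_per_cluster * 2)))
    rows, cols = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    gx = cols + 0.5 * (rows % 2)
    gy = rows * (np.sqrt(3.0) / 2.0)
    gx, gy = gx.ravel(), gy.ravel()
    seed_idx = rng.choice(gx.size, size=n_clusters, replace=False)
    sx, sy = gx[seed_idx], gy[seed_idx]
    d2 = (gx[:, None] - sx) ** 2 + (gy[:, None] - sy) ** 2
    nearest = d2.argmin(axis=1)
    xs, ys, cl = [], [], []
    taken = np.zeros(gx.size, dtype=bool)
    for c in range(n_clusters):
        own = np.flatnonzero((nearest == c) & ~taken)
        own = own[np.argsort(d2[own, c], kind="stable")]
        if own.size < spots_per_cluster:  # borrow nearest unclaimed points
            extra = np.flatnonzero(~taken)
            extra = extra[np.argsort(d2[extra, c], kind="stable")]
            own = np.concatenate([own, extra[~np.isin(extra, own)]])
        pick = own[:spots_per_cluster]
        taken[pick] = True
        xs.append(gx[pick])
        ys.append(gy[pick])
        cl.append(np.full(spots_per_cluster, c))
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(cl)


def simulate_spatial(cfg: SimConfig) -> tuple[ExpressionMatrix, SpotMetadata, GroundTruth]:
    """Generate the six-section spatial dataset with planted ground truth."""
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    n_sections = len(cfg.conditions) * len(cfg.days)
    spots_per_section = cfg.n_clusters * cfg.spots_per_cluster
    n_spots = n_sections * spots_per_section

    # --- planted module structure ------------------------------------------
    module_names = [f"M{m}" for m in range(cfg.n_modules)]
    labels = pd.Series("", index=genes, name="module")
    loadings = np.zeros(cfg.n_genes)
    gene_module = np.full(cfg.n_genes, -1)
    for m in range(cfg.n_modules):
        lo = m * cfg.genes_per_module
        hi = lo + cfg.genes_per_module
        gene_module[lo:hi] = m
        labels.iloc[lo:hi] = module_names[m]
        loadings[lo:hi] = cfg.module_effect * rng.uniform(0.5, 1.0, hi - lo)
    # alternating early/late day profiles and a home cluster per module;
    # modules that reuse a home cluster get the opposite day parity so no two
    # modules share both components (keeps planted modules separable)
    parity = [(m + m // cfg.n_clusters) % 2 for m in range(cfg.n_modules)]
    day_profile = np.array(
        [[1.0, 1.0, -1.0] if p == 0 else [-1.0, -1.0, 1.0] for p in parity]
    )
    home_cluster = np.array([m % cfg.n_clusters for m in range(cfg.n_modules)])

    # --- planted pathway weights -------------------------------------------
    pathway_names = [f"PW{p:02d}" for p in range(cfg.pathway_count)]
    W = np.zeros((cfg.n_genes, cfg.pathway_count))
    pw_start = cfg.pathway_gene_slice.start
    for p in range(cfg.pathway_count):
        lo = pw_start + p * cfg.pathway_genes_per_pathway
        hi = lo + cfg.pathway_genes_per_pathway
        mag = rng.uniform(0.5, 1.5, hi - lo)
        sign = rng.choice([-1.0, 1.0], hi - lo)
        W[lo:hi, p] = mag * sign
    cluster_pathway_mean = rng.normal(0.0, 1.0, size=(cfg.n_clusters, cfg.pathway_count))

    # --- condition-shifted (DE) genes --------------------------------------
    de_idx = np.arange(cfg.de_gene_slice.start, cfg.de_gene_slice.stop)
    de_sign = np.where(np.arange(de_idx.size) % 2 == 0, 1.0, -1.0)
    de_shift = de_sign * cfg.de_log2fc * np.log(2.0)  # natural-log shift in A
    de_table = pd.DataFrame(
        {"gene": [genes[i] for i in de_idx], "true_log2fc": de_sign * cfg.de_log2fc}
    )

    # --- assemble spots section by section ---------------------------------
    obs_ids, metas = [], []
    counts = np.empty((n_spots, cfg.n_genes))
    f_all = np.empty((n_spots, cfg.n_modules))
    a_all = np.empty((n_spots, cfg.pathway_count))
    row = 0
    for cond in cfg.conditions:
        for di, day in enumerate(cfg.days):
            x, y, cluster = _hex_section(rng, cfg.n_clusters, cfg.spots_per_cluster)
            sl = slice(row, row + spots_per_section)
            # module activities: day profile + home-cluster boost + a dominant
            # module-specific spot component (keeps cross-module correlation low)
            f = (
                0.4 * day_profile[:, di][None, :]
                + 1.5 * (cluster[:, None] == home_cluster[None, :])
                + rng.normal(0.0, 1.0, size=(spots_per_section, cfg.n_modules))
            )
            # pathway activities: cluster-level mean + spot noise
            a = cluster_pathway_mean[cluster] + rng.normal(
                0.0, 0.5, size=(spots_per_section, cfg.pathway_count)
            )
            log_mu = (
                np.log(cfg.base_mean)
                + f @ (loadings[None, :] * (gene_module[None, :] == np.arange(cfg.n_modules)[:, None]))
                + cfg.pathway_effect * (a @ W.T)
            )
            if cond == "A":
                log_mu[:, de_idx] += de_shift[None, :]
            counts[sl] = _nb_sample(rng, np.exp(log_mu), cfg.nb_dispersion)
            f_all[sl], a_all[sl] = f, a
            ids = [f"{cond}{day}_s{j:04d}" for j in range(spots_per_section)]
            obs_ids.extend(ids)
            metas.append(
                pd.DataFrame(
                    {"cluster": cluster, "condition": cond, "day": day, "x": x, "y": y},
                    index=ids,
                )
            )
            row += spots_per_section

    expr = ExpressionMatrix(counts, obs_ids, genes, layer="counts")
    meta = SpotMetadata(pd.concat(metas))
    truth = GroundTruth(
        module_labels=labels,
        module_activity=pd.DataFrame(f_all, index=obs_ids, columns=module_names),
        module_day_profile=pd.DataFrame(
            day_profile, index=module_names, columns=[str(d) for d in cfg.days]
        ),
        pathway_activity=pd.DataFrame(a_all, index=obs_ids, columns=pathway_names),
        pathway_weights=pd.DataFrame(W, index=genes, columns=pathway_names),
        de_genes=de_table,
    )
    return expr, meta, truth


def simulate_two_condition(
    n_per_group: int,
    n_genes: int,
    n_de: int = 0,
    log2fc: float = 1.0,
    base_mean: float = 5.0,
    nb_dispersion: float = 10.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SpotMetadata, pd.DataFrame]:
    """Minimal two-condition stratum (one cluster, one day) for calibration
    and power studies of the differential-expression test.

    The first ``n_de`` genes receive a log-mean shift of ``log2fc * ln 2`` in
    condition A (alternating sign); the rest are null.
    """
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    base = np.full(n_genes, np.log(base_mean))
    shift = np.zeros(n_genes)
    sign = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    shift[:n_de] = sign * log2fc * np.log(2.0)
    mu_n = np.tile(np.exp(base), (n_per_group, 1))
    mu_a = np.tile(np.exp(base + shift), (n_per_group, 1))
    counts = np.vstack([_nb_sample(rng, mu_n, nb_dispersion), _nb_sample(rng, mu_a, nb_dispersion)])
    ids = [f"N_s{i:04d}" for i in range(n_per_group)] + [f"A_s{i:04d}" for i in range(n_per_group)]
    meta = SpotMetadata(
        pd.DataFrame(
            {
                "cluster": 0,
                "condition": ["N"] * n_per_group + ["A"] * n_per_group,
                "day": 15,
                "x": 0.0,
                "y": 0.0,
            },
            index=ids,
        )
    )
    truth = pd.DataFrame({"gene": genes[:n_de], "true_log2fc": sign * log2fc})
    return ExpressionMatrix(counts, ids, genes, layer="counts"), meta, truth


# ---------------------------------------------------------------------------
# whole-transcriptome ncRNA generator


def simulate_ncrna(cfg: SimConfig) -> tuple[dict, ExpressionMatrix, GroundTruth]:
    """Generate a miRNA target map and bulk expression with planted ceRNA triples.

    Returns ``(target_map, expression, truth)`` where ``target_map`` maps
    rna_id -> (rna_class, frozenset of miRNA ids). Planted ceRNA/mRNA pairs
    share ``shared_target_overlap`` of their targets and co-vary across
    samples through a latent factor; background RNAs get uniformly random
    target sets and independent expression. Planted mRNA identifiers reuse the
    condition-shifted spatial gene names so the joint (spatial DE + bulk
    ceRNA) workflow links up end to end.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    universe = [f"miR_{i:04d}" for i in range(cfg.n_mirnas)]
    uni = np.array(universe)

    n_tri = cfg.n_cerna_triples
    n_circ = n_tri // 2
    cerna_ids = [f"circ_{i:04d}" if i < n_circ else f"lnc_{i:04d}" for i in range(n_tri)]
    cerna_cls = ["circRNA" if i < n_circ else "lncRNA" for i in range(n_tri)]
    de_genes = _gene_names(cfg.n_genes)[cfg.de_gene_slice]
    if len(de_genes) < n_tri:
        raise ValueError("not enough condition-shifted spatial genes to host planted triples")
    mrna_ids = list(de_genes[:n_tri])

    bg_cerna = [
        f"bgcirc_{i:04d}" if i % 2 == 0 else f"bglnc_{i:04d}"
        for i in range(cfg.n_background_cerna)
    ]
    bg_cerna_cls = ["circRNA" if i % 2 == 0 else "lncRNA" for i in range(cfg.n_background_cerna)]
    bg_mrna = [f"bgm_{i:04d}" for i in range(cfg.n_background_mrna)]

    lo, hi = cfg.target_set_size
    tmap: dict[str, tuple[str, frozenset]] = {}
    rows = []
    for cid, ccls, mid in zip(cerna_ids, cerna_cls, mrna_ids):
        size = int(rng.integers(lo, hi + 1))
        k_shared = max(1, int(round(cfg.shared_target_overlap * size)))
        shared = rng.choice(uni, size=k_shared, replace=False)
        rest = np.setdiff1d(uni, shared)
        own_a = rng.choice(rest, size=size - k_shared, replace=False)
        own_b = rng.choice(rest, size=size - k_shared, replace=False)
        tmap[cid] = (ccls, frozenset(shared) | frozenset(own_a))
        tmap[mid] = ("mRNA", frozenset(shared) | frozenset(own_b))
        rows.append(
            {
                "cerna_id": cid,
                "cerna_class": ccls,
                "mrna_id": mid,
                "shared_mirnas": ",".join(sorted(shared)),
            }
        )
    for rid, rcls in list(zip(bg_cerna, bg_cerna_cls)) + [(r, "mRNA") for r in bg_mrna]:
        size = int(rng.integers(lo, hi + 1))
        tmap[rid] = (rcls, frozenset(rng.choice(uni, size=size, replace=False)))

    # sample-level expression: planted pairs share a latent factor
    all_ids = cerna_ids + mrna_ids + bg_cerna + bg_mrna
    n = cfg.n_samples
    lam = cfg.latent_loading
    expr = np.empty((n, len(all_ids)))
    col = {r: j for j, r in enumerate(all_ids)}
    for cid, mid in zip(cerna_ids, mrna_ids):
        z = rng.normal(size=n)
        expr[:, col[cid]] = lam * z + np.sqrt(1 - lam**2) * rng.normal(size=n)
        expr[:, col[mid]] = lam * z + np.sqrt(1 - lam**2) * rng.normal(size=n)
    for rid in bg_cerna + bg_mrna:
        expr[:, col[rid]] = rng.normal(size=n)
    sample_ids = [f"sample_{i:02d}" for i in range(n)]
    emat = ExpressionMatrix(expr + 5.0, sample_ids, all_ids, layer="lognorm")

    truth = GroundTruth(triples=pd.DataFrame(rows), target_map=tmap)
    return tmap, emat, truth


# ---------------------------------------------------------------------------
# truth export / import


def export_truth(gt: GroundTruth, outdir) -> None:
    """One TSV per truth component; read-back with :func:`load_truth` is exact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if gt.module_labels is not None:
        gt.module_labels.rename_axis("gene").to_frame().to_csv(
            outdir / "truth_module_labels.tsv", sep="\t"
        )
    if gt.module_activity is not None:
        gt.module_activity.rename_axis("obs_id").to_csv(
            outdir / "truth_module_activity.tsv", sep="\t", float_format="%.17g"
        )
    if gt.module_day_profile is not None:
        gt.module_day_profile.rename_axis("module").to_csv(
            outdir / "truth_module_day_profile.tsv", sep="\t"
        )
    if gt.pathway_activity is not None:
        gt.pathway_activity.rename_axis("obs_id").to_csv(
            outdir / "truth_pathway_activity.tsv", sep="\t", float_format="%.17g"
        )
    if gt.pathway_weights is not None:
        gt.pathway_weights.rename_axis("gene").to_csv(
            outdir / "truth_pathway_weights.tsv", sep="\t", float_format="%.17g"
        )
    if gt.de_genes is not None:
        gt.de_genes.to_csv(outdir / "truth_de_genes.tsv", sep="\t", index=False)
    if gt.triples is not None:
        gt.triples.to_csv(outdir / "truth_triples.tsv", sep="\t", index=False)
    if gt.target_map:
        rows = [
            {"rna_id": rid, "rna_class": cls, "mirnas": ",".join(sorted(targets))}
            for rid, (cls, targets) in sorted(gt.target_map.items())
        ]
        pd.DataFrame(rows).to_csv(outdir / "truth_target_map.tsv", sep="\t", index=False)


def load_truth(outdir) -> GroundTruth:
    outdir = Path(outdir)
    gt = GroundTruth()

    def maybe(name):
        p = outdir / name
        return p if p.exists() else None

    if (p := maybe("truth_module_labels.tsv")) is not None:
        df = pd.read_csv(p, sep="\t", index_col=0, keep_default_na=False)
        gt.module_labels = df["module"].astype(str)
    if (p := maybe("truth_module_activity.tsv")) is not None:
        gt.module_activity = pd.read_csv(p, sep="\t", index_col=0)
    if (p := maybe("truth_module_day_profile.tsv")) is not None:
        gt.module_day_profile = pd.read_csv(p, sep="\t", index_col=0)
    if (p := maybe("truth_pathway_activity.tsv")) is not None:
        gt.pathway_activity = pd.read_csv(p, sep="\t", index_col=0)
    if (p := maybe("truth_pathway_weights.tsv")) is not None:
        gt.pathway_weights = pd.read_csv(p, sep="\t", index_col=0)
    if (p := maybe("truth_de_genes.tsv")) is not None:
        gt.de_genes = pd.read_csv(p, sep="\t")
    if (p := maybe("truth_triples.tsv")) is not None:
        gt.triples = pd.read_csv(p, sep="\t")
    if (p := maybe("truth_target_map.tsv")) is not None:
        df = pd.read_csv(p, sep="\t")
        gt.target_map = {
            r.rna_id: (r.rna_class, frozenset(str(r.mirnas).split(",")))
            for r in df.itertuples(index=False)
        }
    return gt


def config_to_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)
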