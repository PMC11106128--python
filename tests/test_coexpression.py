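"""Co-expression stage: metacells, soft power, adjacency, TOM, modules,
eigengenes, kME, hubs and trait correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import spotweave as sw
from spotweave.coexpression import _eigengene, _first_pc, GREY


def _expr(values, layer="scaled", prefix="g"):
    n, m = np.asarray(values).shape
    return sw.ExpressionMatrix(
        np.asarray(values, dtype=float),
        [f"s{i}" for i in range(n)],
        [f"{prefix}{j}" for j in range(m)],
        layer=layer,
    )


def _block_expr(n_obs, blocks, within_cor, seed=0, n_noise=0):
    """Genes in latent blocks with a chosen within-block correlation."""
    rng = np.random.default_rng(seed)
    cols = []
    a = np.sqrt(within_cor)
    b = np.sqrt(1 - within_cor)
    for size in blocks:
        z = rng.normal(size=n_obs)
        for _ in range(size):
            cols.append(a * z + b * rng.normal(size=n_obs))
    for _ in range(n_noise):
        cols.append(rng.normal(size=n_obs))
    X = np.column_stack(cols)
    X = (X - X.mean(0)) / X.std(0)
    return _expr(X)


# ---------------------------------------------------------------------------


class TestMetacells:
    def _meta(self, n, cluster=0):
        ids = [f"s{i}" for i in range(n)]
        return ids, sw.SpotMetadata(
            pd.DataFrame({"cluster": cluster, "condition": "N", "day": 14,
                          "x": 0.0, "y": 0.0}, index=ids)
        )

    def test_zero_neighbors_is_identity_pooling(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 2, size=(6, 4))
        ids, meta = self._meta(6)
        expr = sw.ExpressionMatrix(X, ids, list("abcd"), layer="lognorm")
        mc, _ = sw.build_metacells(expr, meta, k_neighbors=0)
        assert mc.n_obs == 6
        assert np.allclose(np.sort(mc.values, axis=0), np.sort(X, axis=0))

    def test_identical_spots_collapse_to_one_metacell(self):
        X = np.tile([[1.0, 2.0, 3.0]], (3, 1))
        ids, meta = self._meta(3)
        expr = sw.ExpressionMatrix(X, ids, list("abc"), layer="lognorm")
        mc, _ = sw.build_metacells(expr, meta, k_neighbors=2, max_overlap=0.5)
        assert mc.n_obs == 1
        assert np.allclose(mc.values[0], [1.0, 2.0, 3.0])

    def test_zero_overlap_gives_disjoint_members(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 5)) + 5
        ids, meta = self._meta(10)
        expr = sw.ExpressionMatrix(X, ids, list("abcde"), layer="lognorm")
        mc, _ = sw.build_metacells(expr, meta, k_neighbors=4, max_overlap=0.0)
        # 10 spots, metacells of 5 disjoint members: at most 2 accepted
        assert 1 <= mc.n_obs <= 2

    def test_small_group_emitted_unpooled(self, caplog):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(3, 4)) + 5
        ids, meta = self._meta(3)
        expr = sw.ExpressionMatrix(X, ids, list("abcd"), layer="lognorm")
        mc, _ = sw.build_metacells(expr, meta, k_neighbors=5)
        assert mc.n_obs == 3
        assert np.allclose(np.sort(mc.values, axis=0), np.sort(X, axis=0))


class TestSoftPower:
    def test_exact_power_law_fits_perfectly(self):
        """Degrees following an exact power law give signed R^2 = 1."""
        ks, counts = [1, 2, 3, 4, 6, 8, 12, 24], None
        counts = [24 // k for k in ks]  # freq proportional to k^-1
        degrees = np.repeat(ks, counts).astype(float)
        r2, slope = sw.scale_free_fit(degrees, n_bins=47)
        assert r2 == pytest.approx(1.0, abs=1e-6)
        assert slope == pytest.approx(-1.0, abs=1e-9)

    def test_increasing_law_scores_negative(self):
        degrees = np.repeat([1, 2, 3, 4, 6, 8, 12, 24], [1, 2, 3, 4, 6, 8, 12, 24]).astype(float)
        r2, _ = sw.scale_free_fit(degrees, n_bins=47)
        assert r2 == pytest.approx(-1.0, abs=1e-6)

    def test_degenerate_equal_connectivity_flagged(self):
        r2, slope = sw.scale_free_fit(np.full(50, 3.0))
        assert np.isnan(r2) and np.isnan(slope)

    def test_equal_correlations_no_crash(self):
        # two genes repeated -> all pairwise correlations equal
        rng = np.random.default_rng(0)
        z = rng.normal(size=40)
        X = np.column_stack([z, z, z, z])
        X = (X - X.mean(0)) / X.std(0)
        res = sw.pick_soft_power(_expr(X), powers=range(1, 5))
        assert res.table["r2_signed"].isna().all()

    def test_default_sim_reaches_threshold_with_smallest_power(self, wgcna_result):
        sp = wgcna_result["soft_power"]
        assert sp.reached_threshold
        ok = sp.table[sp.table["r2_signed"] >= 0.8]
        assert sp.chosen == int(ok["power"].iloc[0])


class TestAdjacency:
    def test_hand_values(self):
        # r=1 -> 1; r=-1 -> 0 (signed); r=0.5, beta=2 -> 0.75^2
        z = np.array([1.0, -1.0, 0.5, -0.5])
        X = np.column_stack([z, z, -z])
        X = (X - X.mean(0)) / X.std(0)
        a = sw.adjacency(_expr(X), beta=2, mode="signed")
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 2] == pytest.approx(0.0)
        rng = np.random.default_rng(3)
        z1 = rng.normal(size=2000)
        z2 = 0.5 * z1 + np.sqrt(0.75) * rng.normal(size=2000)
        X2 = np.column_stack([z1, z2])
        X2 = (X2 - X2.mean(0)) / X2.std(0)
        a2 = sw.adjacency(_expr(X2), beta=2, mode="signed")
        r = np.corrcoef(z1, z2)[0, 1]
        assert a2[0, 1] == pytest.approx(((1 + r) / 2) ** 2, abs=1e-12)

    def test_unsigned_mode(self):
        z = np.array([1.0, -1.0, 0.5, -0.5])
        X = np.column_stack([z, -z])
        X = (X - X.mean(0)) / X.std(0)
        a = sw.adjacency(_expr(X), beta=3, mode="unsigned")
        assert a[0, 1] == pytest.approx(1.0)

    def test_signed_exact_value(self):
        assert ((1 + 0.5) / 2) ** 2 == pytest.approx(0.5625)


def tom_oracle(a):
    """Triple-loop reference for the topological overlap matrix."""
    n = a.shape[0]
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = sum(a0[i, u] * a0[u, j] for u in range(n) if u != i and u != j)
            num += a0[i, j]
            den = min(k[i], k[j]) + 1 - a0[i, j]
            t[i, j] = num / den if den > 0 else 0.0
    return t


class TestTOM:
    def test_perfect_clique(self):
        a = np.ones((3, 3))
        assert np.allclose(sw.tom_similarity(a), 1.0)

    def test_isolated_pair_zero(self):
        a = np.eye(4)
        t = sw.tom_similarity(a)
        assert t[0, 1] == 0.0 and t[0, 0] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, size=(20, 20))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        assert np.abs(sw.tom_similarity(a) - tom_oracle(a)).max() < 1e-10

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(0, 1, size=(15, 15))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        t = sw.tom_similarity(a)
        assert (t >= 0).all() and (t <= 1).all()
        assert np.allclose(t, t.T)


class TestModuleDetection:
    def test_two_planted_blocks_recovered_exactly(self):
        expr = _block_expr(300, [50, 50], within_cor=0.9, seed=4)
        a = sw.adjacency(expr, beta=6)
        labels = sw.detect_modules(sw.tom_dissimilarity(a), expr)
        truth = np.array([0] * 50 + [1] * 50)
        got = labels.iloc[:100].to_numpy()
        assert (labels.iloc[:100] != GREY).all()
        assert adjusted_rand_score(truth, got) == pytest.approx(1.0)
        assert len(set(got)) == 2

    def test_min_size_larger_than_clusters_all_grey(self):
        expr = _block_expr(200, [10, 10], within_cor=0.9, seed=5)
        a = sw.adjacency(expr, beta=6)
        labels = sw.detect_modules(sw.tom_dissimilarity(a), expr, min_size=30)
        assert (labels == GREY).all()

    def test_duplicated_block_merges_into_one_module(self):
        # two 40-gene blocks driven by the same latent factor
        rng = np.random.default_rng(6)
        z = rng.normal(size=300)
        cols = [np.sqrt(0.9) * z + np.sqrt(0.1) * rng.normal(size=300) for _ in range(80)]
        X = np.column_stack(cols)
        X = (X - X.mean(0)) / X.std(0)
        expr = _expr(X)
        a = sw.adjacency(expr, beta=6)
        labels = sw.detect_modules(sw.tom_dissimilarity(a), expr)
        mods = set(labels) - {GREY}
        assert len(mods) == 1

    def test_colour_naming_by_size(self):
        expr = _block_expr(300, [60, 40], within_cor=0.92, seed=7)
        a = sw.adjacency(expr, beta=6)
        labels = sw.detect_modules(sw.tom_dissimilarity(a), expr)
        sizes = labels[labels != GREY].value_counts()
        assert list(sizes.index) == ["turquoise", "blue"]


class TestEigengenes:
    def test_identical_member_vectors(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std()
        X = np.column_stack([x, x, x])
        expr = _expr(X)
        labels = pd.Series(["turquoise"] * 3, index=expr.gene_ids)
        mes = sw.module_eigengenes(expr, labels)
        kme = sw.compute_kme(expr, mes)
        assert np.allclose(np.abs(np.corrcoef(mes["turquoise"], x)[0, 1]), 1.0)
        assert np.allclose(kme["turquoise"], 1.0, atol=1e-10)

    def test_orientation_mean_member_correlation_positive(self, wgcna_result):
        mes, kme, labels = wgcna_result["mes"], wgcna_result["kme"], wgcna_result["labels"]
        for m in mes.columns:
            members = labels.index[labels == m]
            assert kme.loc[members, m].mean() > 0

    def test_sign_flip_flips_eigengene(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 5))
        X = (X - X.mean(0)) / X.std(0)
        me1 = _eigengene(X)
        me2 = _eigengene(-X)
        assert np.allclose(me1, -me2)

    def test_first_pc_matches_eigendecomposition(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 10))
        Xc = X - X.mean(0)
        scores = _first_pc(X)
        w, v = np.linalg.eigh(Xc.T @ Xc)
        top = Xc @ v[:, -1]
        assert abs(np.corrcoef(scores, top)[0, 1]) == pytest.approx(1.0, abs=1e-10)
        # variance along ME >= variance along any other unit direction
        var_me = scores.var()
        for _ in range(20):
            u = rng.normal(size=10)
            u /= np.linalg.norm(u)
            assert var_me >= (Xc @ u).var() - 1e-10

    def test_single_gene_module(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 2))
        X = (X - X.mean(0)) / X.std(0)
        expr = _expr(X)
        labels = pd.Series(["blue", GREY], index=expr.gene_ids)
        mes = sw.module_eigengenes(expr, labels)
        assert abs(np.corrcoef(mes["blue"], X[:, 0])[0, 1]) == pytest.approx(1.0)

    def test_unit_variance(self, wgcna_result):
        mes = wgcna_result["mes"]
        assert np.allclose(mes.std(axis=0, ddof=0), 1.0, atol=1e-8)


class TestKMEAndHubs:
    def test_kme_bounded(self, wgcna_result):
        kme = wgcna_result["kme"]
        assert (kme.to_numpy() >= -1).all() and (kme.to_numpy() <= 1).all()

    def test_null_gene_kme_small(self):
        rng = np.random.default_rng(13)
        me = rng.normal(size=500)
        draws = np.array([
            np.corrcoef(me, rng.normal(size=500))[0, 1] for _ in range(100)
        ])
        assert (np.abs(draws) < 0.15).mean() >= 0.95

    def test_hub_truncation_and_order(self):
        kme = pd.DataFrame({"blue": [0.9, 0.99, 0.5, 0.99]},
                           index=["g3", "g1", "g4", "g0"])
        labels = pd.Series(["blue"] * 4, index=kme.index)
        hubs = sw.select_hub_genes(kme, labels, top_n=100)
        assert len(hubs) == 4                      # fewer genes than top_n
        assert list(hubs["gene"][:2]) == ["g0", "g1"]  # tie broken lexicographically
        assert hubs.iloc[0]["rank"] == 1

    def test_injected_top_gene_ranks_first(self, wgcna_result):
        hubs = wgcna_result["hubs"]
        kme, labels = wgcna_result["kme"], wgcna_result["labels"]
        m = kme.columns[0]
        members = labels.index[labels == m]
        best = kme.loc[members, m].idxmax()
        assert hubs[hubs["module"] == m].iloc[0]["gene"] == best


class TestModuleTrait:
    def test_identical_me_columns_correlate_fully(self):
        x = np.random.default_rng(14).normal(size=30)
        mes = pd.DataFrame({"a": x, "b": x, "c": -x})
        c = sw.module_correlations(mes)
        assert c.loc["a", "b"] == pytest.approx(1.0)
        assert c.loc["a", "c"] == pytest.approx(-1.0)
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)

    def test_me_equal_to_binary_trait(self):
        t = np.array([1.0, 0, 1, 0, 1, 0, 1, 0])
        mes = pd.DataFrame({"m": (t - t.mean()) / t.std()})
        traits = pd.DataFrame({"grp": t})
        r, p = sw.module_trait_correlation(mes, traits)
        assert r.loc["m", "grp"] == pytest.approx(1.0)
        assert p.loc["m", "grp"] < 1e-6

    def test_permuted_trait_p_uniform(self):
        rng = np.random.default_rng(15)
        me = rng.normal(size=200)
        trait = np.repeat([0.0, 1.0], 100)
        ps = []
        for _ in range(1000):
            ps.append(stats.pearsonr(me, rng.permutation(trait)).pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_day_complementarity(self, default_sim, wgcna_result):
        """Modules planted high on days 14/15 correlate positively with those
        days and negatively with day 16, and vice versa."""
        _, _, _, truth = default_sim
        labels, r = wgcna_result["labels"], wgcna_result["module_trait_r"]
        checked = 0
        for tm, prof in truth.module_day_profile.iterrows():
            genes = truth.module_labels[truth.module_labels == tm].index
            rec = labels.loc[genes].mode()[0]
            if rec == GREY:
                continue
            for d in (14, 15, 16):
                assert np.sign(r.loc[rec, f"day_{d}"]) == np.sign(prof[str(d)])
            checked += 1
        assert checked >= 8
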