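"""Co-expression network: soft threshold, TOM, modules, eigengenes, stats."""

import numpy as np
import pandas as pd
import pytest

import neurodiverge as nd
from neurodiverge.network import (NetworkConfig, adjacency_matrix,
                                  correlation_matrix, detect_modules,
                                  module_eigengenes, merge_modules,
                                  select_top_variance, tom_similarity)


def _block_expr(n_blocks=2, block=50, noise_genes=0, n_samples=16,
                within=0.9, seed=0):
    """Genes driven by per-block latent factors (within-r about `within`)."""
    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    lam = np.sqrt(within)
    sd = np.sqrt(1 - within)
    for b in range(n_blocks):
        z = rng.standard_normal(n_samples)
        for _ in range(block):
            rows.append(lam * z + sd * rng.standard_normal(n_samples))
            labels.append(f"B{b}")
    for _ in range(noise_genes):
        rows.append(rng.standard_normal(n_samples))
        labels.append("noise")
    genes = [f"g{i:04d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=genes), pd.Series(labels, index=genes)


class TestTopVariance:
    def test_fraction_one_identity(self):
        df, _ = _block_expr(1, 10)
        assert select_top_variance(df, 1.0).shape == df.shape

    def test_constant_genes_excluded(self):
        df, _ = _block_expr(1, 10)
        df.loc["const"] = 1.0
        top = select_top_variance(df, 0.5)
        assert "const" not in top.index

    def test_ceiling_count(self):
        # 4826 kept from 48254 at 10% (ceiling convention)
        assert int(np.ceil(0.10 * 48254)) == 4826
        df, _ = _block_expr(1, 25)  # 25 genes
        assert len(select_top_variance(df, 0.1)) == int(np.ceil(2.5))


class TestSoftThreshold:
    def test_exact_power_law_fit_one(self):
        # construct connectivities following an exact power law and check
        # the internal regression logic via an independent least-squares fit
        from neurodiverge.network import _scale_free_fit

        rng = np.random.default_rng(1)
        # p(k) ~ k^-2 discretized
        k = np.repeat(np.arange(1, 11), (1000 / np.arange(1, 11) ** 2).astype(int))
        r2, slope = _scale_free_fit(k.astype(float))
        assert slope < 0
        assert r2 > 0.97

    def test_fit_table_matches_independent_regression(self):
        df, _ = _block_expr(2, 30, noise_genes=30, seed=2)
        cfg = NetworkConfig(beta_grid=(2, 6), min_module_size=10)
        beta, table = nd.pick_soft_threshold(df, cfg)
        corr = correlation_matrix(df)
        for _, row in table.iterrows():
            a = adjacency_matrix(corr, int(row["beta"]))
            k = a.sum(axis=1)
            k = k[k > 0]
            edges = np.linspace(k.min(), k.max() * (1 + 1e-12), 11)
            which = np.clip(np.digitize(k, edges) - 1, 0, 9)
            xs, ys = [], []
            for b in range(10):
                m = which == b
                if m.sum():
                    xs.append(np.log10(k[m].mean()))
                    ys.append(np.log10(m.mean()))
            coef = np.polyfit(xs, ys, 1)
            pred = np.polyval(coef, xs)
            ss = 1 - ((np.array(ys) - pred) ** 2).sum() / \
                ((np.array(ys) - np.mean(ys)) ** 2).sum()
            assert row["r2"] == pytest.approx(ss, abs=1e-9)

    def test_selection_deterministic(self):
        df, _ = _block_expr(3, 25, noise_genes=40, seed=3)
        cfg = NetworkConfig(beta_grid=tuple(range(1, 13)))
        b1, _ = nd.pick_soft_threshold(df, cfg)
        b2, _ = nd.pick_soft_threshold(df, cfg)
        assert b1 == b2
        assert b1 in cfg.beta_grid

    def test_empty_grid_errors(self):
        df, _ = _block_expr(1, 10)
        with pytest.raises(ValueError):
            nd.pick_soft_threshold(df, NetworkConfig(beta_grid=()))


class TestTOM:
    def test_isolated_pair_full_overlap(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        omega = tom_similarity(a)
        assert omega[0, 1] == pytest.approx(1.0)

    def test_no_connection_no_overlap(self):
        a = np.zeros((3, 3))
        omega = tom_similarity(a)
        assert omega[0, 1] == 0.0
        assert np.allclose(np.diag(omega), 1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 1, size=(8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        omega = tom_similarity(a)
        k = a.sum(axis=1)
        for i in range(8):
            for j in range(8):
                if i == j:
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(8))
                expect = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert omega[i, j] == pytest.approx(expect, abs=1e-12)

    def test_monotone_in_direct_adjacency(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 0.5, size=(6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        om1 = tom_similarity(a)
        a2 = a.copy()
        a2[0, 1] = a2[1, 0] = a[0, 1] + 0.3
        om2 = tom_similarity(a2)
        assert om2[0, 1] >= om1[0, 1]

    def test_invalid_entries_error(self):
        bad = np.array([[0.0, 1.5], [1.5, 0.0]])
        with pytest.raises(ValueError):
            tom_similarity(bad)


class TestModuleDetection:
    def test_two_planted_blocks_exact(self):
        from sklearn.metrics import adjusted_rand_score

        expr, labels = _block_expr(2, 50, noise_genes=0, within=0.8, seed=6)
        corr = correlation_matrix(expr)
        tom = tom_similarity(adjacency_matrix(corr, 6))
        part = detect_modules(tom, expr.index,
                              NetworkConfig(min_module_size=40))
        assert part.n_modules() == 2
        ari = adjusted_rand_score(labels, part.labels)
        assert ari == 1.0

    def test_pure_noise_mostly_grey(self):
        grey_frac = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            expr = pd.DataFrame(rng.standard_normal((150, 16)),
                                index=[f"g{i}" for i in range(150)])
            corr = correlation_matrix(expr)
            tom = tom_similarity(adjacency_matrix(corr, 6))
            part = detect_modules(tom, expr.index,
                                  NetworkConfig(min_module_size=30))
            grey_frac.append((part.labels == "grey").mean())
        assert np.mean(grey_frac) >= 0.95

    def test_min_size_above_block_all_grey(self):
        expr, _ = _block_expr(2, 20, seed=7)
        corr = correlation_matrix(expr)
        tom = tom_similarity(adjacency_matrix(corr, 6))
        part = detect_modules(tom, expr.index,
                              NetworkConfig(min_module_size=30))
        assert part.n_modules() == 0
        assert (part.labels == "grey").all()

    def test_planted_recovery_with_noise(self):
        from sklearn.metrics import adjusted_rand_score

        # three 60-gene modules with loading 0.8 among noise, 16 samples
        aris = []
        for seed in range(3):
            expr, labels = _block_expr(3, 60, noise_genes=120,
                                       within=0.64, seed=seed)
            corr = correlation_matrix(expr)
            tom = tom_similarity(adjacency_matrix(corr, 6))
            part = detect_modules(tom, expr.index,
                                  NetworkConfig(min_module_size=40))
            planted = labels != "noise"
            aris.append(adjusted_rand_score(labels[planted],
                                            part.labels[planted.to_numpy()][planted]))
        assert np.mean(aris) >= 0.8


class TestEigengenes:
    def test_identical_genes_eigengene_proportional(self):
        profile = np.linspace(-1, 1, 12)
        expr = pd.DataFrame(np.tile(profile, (5, 1)) * np.arange(1, 6)[:, None],
                            index=[f"g{i}" for i in range(5)])
        labels = pd.Series("turquoise", index=expr.index)
        from neurodiverge.network import ModulePartition

        eg = module_eigengenes(expr, ModulePartition(labels))
        v = eg["turquoise"].to_numpy()
        zprof = (profile - profile.mean()) / profile.std()
        cos = np.dot(v, zprof) / np.linalg.norm(v) / np.linalg.norm(zprof)
        assert abs(cos) == pytest.approx(1.0, abs=1e-10)
        assert np.dot(v, zprof) > 0  # orientation toward module average

    def test_matches_svd_oracle(self):
        from neurodiverge.network import ModulePartition

        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.normal(size=(20, 10)),
                            index=[f"g{i}" for i in range(20)])
        part = ModulePartition(pd.Series("blue", index=expr.index))
        eg = module_eigengenes(expr, part)["blue"].to_numpy()
        x = expr.to_numpy()
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        _, _, vt = np.linalg.svd(z)
        ref = vt[0]
        if np.dot(ref, z.mean(0)) < 0:
            ref = -ref
        assert np.allclose(eg, ref, atol=1e-10)
        assert np.linalg.norm(eg) == pytest.approx(1.0)


class TestMerging:
    def test_duplicated_module_merged(self):
        from neurodiverge.network import ModulePartition

        expr, _ = _block_expr(1, 60, seed=9)
        labels = pd.Series(["blue"] * 30 + ["brown"] * 30, index=expr.index)
        merged, egs = merge_modules(expr, ModulePartition(labels), 0.3)
        assert merged.n_modules() == 1
        assert len(merged.merge_history) == 1

    def test_orthogonal_modules_not_merged(self):
        from neurodiverge.network import ModulePartition

        expr, labels = _block_expr(2, 40, within=0.95, seed=10)
        part = ModulePartition(labels.map({"B0": "blue", "B1": "brown"}))
        merged, _ = merge_modules(expr, part, 0.3)
        assert merged.n_modules() == 2


class TestModuleTrait:
    def test_perfect_separation(self, four_group_samples):
        from neurodiverge.network import module_trait_correlation

        meta = four_group_samples.table
        eg = pd.DataFrame(
            {"turquoise": (meta["geography"] == "sympatric").astype(float)},
            index=meta.index)
        res = module_trait_correlation(eg, four_group_samples)
        row = res.loc[("turquoise", "geography")]
        assert abs(row["r"]) == pytest.approx(1.0)
        assert row["p"] == pytest.approx(0.0, abs=1e-12)

    def test_null_calibration(self, four_group_samples):
        from neurodiverge.network import module_trait_correlation

        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            eg = pd.DataFrame(rng.normal(size=(12, 5)),
                              index=four_group_samples.table.index,
                              columns=["m1", "m2", "m3", "m4", "m5"])
            res = module_trait_correlation(eg, four_group_samples)
            hits += res["significant"].any()
        assert hits <= 2

    def test_planted_trait_module_recovered(self, default_dataset, normalized):
        kept, norm = normalized
        from neurodiverge.network import ModulePartition, module_trait_correlation

        truth = default_dataset.truth
        labels = pd.Series("grey", index=norm.log2_cpm.index, dtype=object)
        labels[truth["true_module"] == "M1"] = "blue"  # geography-tied
        labels[truth["true_module"] == "M5"] = "brown"  # untied
        eg = module_eigengenes(norm.log2_cpm, ModulePartition(labels))
        res = module_trait_correlation(eg, default_dataset.samples)
        assert res.loc[("blue", "geography"), "q"] < 0.05
        assert res.loc[("brown", "geography"), "q"] > 0.05


class TestConnectivity:
    def test_complete_graph(self):
        from neurodiverge.network import ModulePartition, connectivity_stats

        n = 6
        corr = np.ones((n, n))
        genes = [f"g{i}" for i in range(n)]
        part = ModulePartition(pd.Series("blue", index=genes))
        stats = connectivity_stats(corr, genes, part,
                                   NetworkConfig(edge_filter_r=0.05))
        assert np.allclose(stats.per_gene["degree"], n - 1)
        assert np.allclose(stats.per_gene["clustering"], 1.0)
        assert np.allclose(stats.per_gene["neighborhood_connectivity"], n - 1)

    def test_star_graph(self):
        from neurodiverge.network import ModulePartition, connectivity_stats

        n = 5
        corr = np.zeros((n, n))
        corr[0, 1:] = corr[1:, 0] = 0.9
        genes = [f"g{i}" for i in range(n)]
        part = ModulePartition(pd.Series("blue", index=genes))
        stats = connectivity_stats(corr, genes, part)
        assert stats.per_gene["degree"].iloc[0] == n - 1
        assert (stats.per_gene["clustering"].iloc[1:] == 0).all()

    def test_random_graph_matches_networkx(self):
        import networkx as nx
        from neurodiverge.network import ModulePartition, connectivity_stats

        rng = np.random.default_rng(11)
        n = 12
        corr = rng.uniform(-1, 1, size=(n, n))
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        genes = [f"g{i}" for i in range(n)]
        part = ModulePartition(pd.Series("blue", index=genes))
        cfg = NetworkConfig(edge_filter_r=0.4)
        stats = connectivity_stats(corr, genes, part, cfg)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if abs(corr[i, j]) >= 0.4:
                    g.add_edge(i, j)
        deg = dict(g.degree())
        cc = nx.clustering(g)
        anc = nx.average_neighbor_degree(g)
        for i in range(n):
            assert stats.per_gene["degree"].iloc[i] == deg[i]
            assert stats.per_gene["clustering"].iloc[i] == pytest.approx(cc[i])
            expected_nc = anc[i] if deg[i] > 0 else 0.0
            assert stats.per_gene["neighborhood_connectivity"].iloc[i] == \
                pytest.approx(expected_nc)


class TestExport:
    def test_filter_one_empty_edges(self, tmp_path):
        from neurodiverge.network import ModulePartition, export_network

        rng = np.random.default_rng(12)
        corr = rng.uniform(-0.9, 0.9, size=(5, 5))
        corr = (corr + corr.T) / 2
        genes = [f"g{i}" for i in range(5)]
        part = ModulePartition(pd.Series("blue", index=genes))
        g = export_network(corr, genes, part, NetworkConfig(edge_filter_r=1.0))
        assert g.number_of_edges() == 0

    def test_round_trip_and_edge_count(self, tmp_path):
        import networkx as nx
        from neurodiverge.network import ModulePartition, export_network

        rng = np.random.default_rng(13)
        corr = rng.uniform(-1, 1, size=(10, 10))
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        genes = [f"g{i}" for i in range(10)]
        part = ModulePartition(pd.Series("blue", index=genes))
        cfg = NetworkConfig(edge_filter_r=0.3)
        g = export_network(corr, genes, part, cfg, outdir=tmp_path)
        iu = np.triu_indices(10, 1)
        assert g.number_of_edges() == int((np.abs(corr[iu]) >= 0.3).sum())
        g2 = nx.read_graphml(tmp_path / "network.graphml")
        assert {frozenset(e) for e in g2.edges()} == \
            {frozenset(e) for e in g.edges()}
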