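"""Co-expression network construction: calibration, PMFG, modules, hubs,
module PCs."""

import itertools

import networkx as nx
import numpy as np
import pytest

import bloodbrain as bb
from bloodbrain.containers import ExpressionMatrix
from bloodbrain.network import (ModulePCSpec, Module, ModuleSet,
                                PlanarNetwork, build_pmfg, calibrate_cutoff,
                                exhaustive_best_partition,
                                fit_pca, hub_nodes, module_pcs,
                                multiscale_cluster, n_components_for,
                                pmfg_from_pairs, weighted_modularity)


def _em(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix([f"g{i}" for i in range(values.shape[0])],
                            [f"s{j}" for j in range(values.shape[1])],
                            values, bb.Stage.RESIDUALIZED)


def _block_data(rng, n_samples=40, block_sizes=(5, 5), n_noise=6,
                noise_sd=0.05):
    """Blocks of near-perfectly co-varying genes plus independent noise."""
    rows = []
    for size in block_sizes:
        f = rng.normal(size=n_samples)
        for _ in range(size):
            rows.append(f + noise_sd * rng.normal(size=n_samples))
    for _ in range(n_noise):
        rows.append(rng.normal(size=n_samples))
    return np.array(rows)


class TestCalibrateCutoff:
    def test_planted_blocks_pass_the_cutoff(self, rng):
        values = _block_data(rng)
        expr = _em(values)
        calib = calibrate_cutoff(expr, n_perm=10, fdr=0.05, seed=1)
        assert calib.achieved and calib.rho_star < 1
        r = np.corrcoef(values)
        for block in (range(0, 5), range(5, 10)):
            for i, j in itertools.combinations(block, 2):
                assert abs(r[i, j]) >= calib.rho_star

    def test_deterministic_under_seed(self, rng):
        expr = _em(rng.normal(size=(8, 20)))
        c1 = calibrate_cutoff(expr, seed=5)
        c2 = calibrate_cutoff(expr, seed=5)
        assert c1.rho_star == c2.rho_star
        np.testing.assert_array_equal(c1.permuted_mean, c2.permuted_mean)

    def test_observed_counts_match_brute_force(self, rng):
        values = rng.normal(size=(6, 15))
        calib = calibrate_cutoff(_em(values), n_perm=3, seed=2)
        r = np.corrcoef(values)
        for c, obs in zip(calib.cutoffs, calib.observed):
            expected = sum(1 for i, j in itertools.combinations(range(6), 2)
                           if abs(r[i, j]) >= c)
            assert obs == expected
        # FDR identity and cutoff choice recomputed from the stored curves
        np.testing.assert_allclose(
            calib.fdr, calib.permuted_mean / np.maximum(calib.observed, 1))
        ok = np.flatnonzero(calib.fdr <= 0.05)
        expected_rho = calib.cutoffs[ok[0]] if ok.size else calib.cutoffs[-1]
        assert calib.rho_star == expected_rho

    def test_counts_non_increasing_in_cutoff(self, rng):
        calib = calibrate_cutoff(_em(rng.normal(size=(10, 12))), seed=3)
        assert np.all(np.diff(calib.observed) <= 0)
        assert np.all(np.diff(calib.permuted_mean) <= 1e-9)

    def test_pure_noise_has_no_spurious_structure(self, rng):
        expr = _em(rng.normal(size=(30, 50)))
        calib = calibrate_cutoff(expr, n_perm=10, fdr=0.05, seed=4)
        i = int(np.searchsorted(calib.cutoffs, calib.rho_star))
        obs = calib.observed[i]
        perm = calib.permuted_mean[i]
        assert abs(obs - perm) <= 3 * np.sqrt(max(perm, 1))

    def test_constant_gene_excluded_with_warning(self, rng):
        values = rng.normal(size=(5, 10))
        values[2] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            calibrate_cutoff(_em(values), seed=1)


def brute_force_pmfg(pairs, nodes):
    """Independent oracle: insert in sorted order, keep iff the whole
    graph stays planar, stop at 3(n-2) edges."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    kept = []
    cap = 3 * (len(nodes) - 2)
    for a, b, w, s in pairs:
        if len(kept) >= cap:
            break
        g.add_edge(a, b)
        if nx.check_planarity(g)[0]:
            kept.append((a, b))
        else:
            g.remove_edge(a, b)
    return set(kept)


class TestPMFG:
    def test_k5_keeps_the_nine_heaviest_edges(self, rng):
        nodes = list("abcde")
        weights = rng.permutation(10) + 1.0
        pairs = [(a, b, float(w), 1) for (a, b), w in
                 zip(itertools.combinations(nodes, 2), weights)]
        pairs.sort(key=lambda e: (-e[2], e[0], e[1]))
        net = pmfg_from_pairs(pairs, nodes)
        assert len(net.edges) == 9 == 3 * (5 - 2)
        kept = {(a, b) for a, b, *_ in net.edges}
        heaviest = {(a, b) for a, b, *_ in pairs[:9]}
        assert kept == heaviest

    def test_tree_input_is_fully_retained(self):
        pairs = [("a", "b", 0.9, 1), ("b", "c", 0.8, 1), ("b", "d", 0.7, 1),
                 ("d", "e", 0.6, 1)]
        net = pmfg_from_pairs(pairs)
        assert len(net.edges) == 4

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_on_random_graphs(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 11))
        nodes = [f"n{i}" for i in range(n)]
        density = rng.uniform(0.4, 1.0)
        pairs = []
        for a, b in itertools.combinations(nodes, 2):
            if rng.random() < density:
                pairs.append((a, b, float(rng.random()), 1))
        pairs.sort(key=lambda e: (-e[2], e[0], e[1]))
        net = pmfg_from_pairs(pairs, nodes)
        assert {(a, b) for a, b, *_ in net.edges} == \
            brute_force_pmfg(pairs, nodes)
        assert nx.check_planarity(net.to_graph())[0]
        assert len(net.edges) <= 3 * (n - 2)

    def test_build_pmfg_respects_rho_star(self, rng):
        values = _block_data(rng)
        expr = _em(values)
        net = build_pmfg(expr, 0.5)
        assert all(w >= 0.5 for *_, w, _s in
                   [(a, b, w, s) for a, b, w, s in net.edges])

    def test_fewer_than_three_nodes_returns_trivial_graph(self):
        pairs = [("a", "b", 0.9, 1)]
        net = pmfg_from_pairs(pairs)
        assert len(net.edges) == 1


def _clique_net(*cliques, bridges=()):
    edges = []
    nodes = []
    for clique in cliques:
        nodes.extend(clique)
        for a, b in itertools.combinations(clique, 2):
            edges.append((a, b, 1.0, 1))
    for a, b in bridges:
        edges.append((a, b, 1.0, 1))
    return PlanarNetwork(sorted(nodes), edges)


def sympy_partition_oracle(g, k_max=4):
    """Independent exhaustive maximization of weighted modularity over all
    partitions with at most k_max blocks (sympy enumeration)."""
    from sympy.utilities.iterables import multiset_partitions

    nodes = sorted(g.nodes())
    best = -np.inf
    for parts in multiset_partitions(nodes):
        if not 2 <= len(parts) <= k_max:
            continue
        labels = {v: c for c, p in enumerate(parts) for v in p}
        best = max(best, weighted_modularity(g, labels))
    return best


class TestMultiscaleCluster:
    def test_bridged_six_cliques_split_into_cliques(self):
        c1 = [f"a{i}" for i in range(6)]
        c2 = [f"b{i}" for i in range(6)]
        net = _clique_net(c1, c2, bridges=[("a0", "b0")])
        modules = multiscale_cluster(net, min_size=3)
        roots = modules.roots
        assert len(roots) == 1 and len(roots[0].gene_ids) == 12
        children = [m for m in modules if m.parent_id == roots[0].module_id]
        assert sorted(sorted(c.gene_ids) for c in children) == \
            [sorted(c1), sorted(c2)]
        # split Q equals the exhaustive maximum over bipartitions
        g = net.to_graph()
        best = max(weighted_modularity(
            g, {v: int(v in set(sub)) for v in g.nodes()})
            for r in range(1, 7)
            for sub in itertools.combinations(c1 + c2, r))
        assert children[0].q == pytest.approx(best, abs=1e-12)

    def test_uniform_clique_does_not_split(self):
        net = _clique_net([f"n{i}" for i in range(8)])
        modules = multiscale_cluster(net, min_size=2)
        assert len(modules) == 1

    def test_chain_of_three_five_cliques_recovers_all_cliques(self):
        cliques = [[f"{t}{i}" for i in range(5)] for t in "abc"]
        net = _clique_net(*cliques,
                          bridges=[("a0", "b0"), ("b4", "c0")])
        modules = multiscale_cluster(net, min_size=3)
        found = {tuple(sorted(m.gene_ids)) for m in modules}
        for clique in cliques:
            assert tuple(sorted(clique)) in found

    @pytest.mark.parametrize("trial", range(8))
    def test_split_matches_exhaustive_partition_oracle(self, trial):
        rng = np.random.default_rng(300 + trial)
        n = int(rng.integers(5, 9))
        g = nx.gnp_random_graph(n, 0.6, seed=int(rng.integers(1 << 31)))
        if g.number_of_edges() == 0:
            pytest.skip("empty graph drawn")
        for u, v in g.edges():
            g[u][v]["weight"] = float(rng.random())
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)})
        labels, q = exhaustive_best_partition(g, k_max=4)
        assert q == pytest.approx(sympy_partition_oracle(g, 4), abs=1e-12)
        assert q == pytest.approx(weighted_modularity(g, labels), abs=1e-12)

    def test_accepted_split_q_is_positive_and_hierarchy_is_forest(self):
        cliques = [[f"{t}{i}" for i in range(6)] for t in "ab"]
        net = _clique_net(*cliques, bridges=[("a0", "b0")])
        modules = multiscale_cluster(net, min_size=3)
        ids = {m.module_id for m in modules}
        for m in modules:
            assert m.parent_id is None or m.parent_id in ids
            if m.parent_id is not None:
                assert m.q > 0
                parent = modules.by_id(m.parent_id)
                assert set(m.gene_ids) <= set(parent.gene_ids)


class TestHubs:
    def test_star_center_is_the_only_hub(self):
        leaves = [f"l{i}" for i in range(8)]
        edges = [("hub", leaf, 1.0, 1) for leaf in leaves]
        net = PlanarNetwork(["hub"] + leaves, edges)
        modules = ModuleSet([Module("M1", None, 1, ["hub"] + leaves,
                                    float("nan"))])
        hub_nodes(net, modules, n_perm=50, p=0.3, seed=1)
        assert modules.modules[0].hubs == ["hub"]

    def test_random_weight_clique_hub_fraction_near_p(self, rng):
        n, p = 40, 0.1
        nodes = [f"n{i}" for i in range(n)]
        edges = [(a, b, float(rng.random()), 1)
                 for a, b in itertools.combinations(nodes, 2)]
        net = PlanarNetwork(nodes, edges)
        modules = ModuleSet([Module("M1", None, 1, nodes, float("nan"))])
        hub_nodes(net, modules, n_perm=200, p=p, seed=2)
        frac = len(modules.modules[0].hubs) / n
        assert 0.0 <= frac <= 3 * p  # observed degrees are a null draw

    def test_deterministic_under_seed(self, rng):
        nodes = [f"n{i}" for i in range(10)]
        edges = [(a, b, float(rng.random()), 1)
                 for a, b in itertools.combinations(nodes, 2)
                 if rng.random() < 0.5]
        net = PlanarNetwork(nodes, edges)
        m1 = ModuleSet([Module("M1", None, 1, nodes, float("nan"))])
        m2 = ModuleSet([Module("M1", None, 1, nodes, float("nan"))])
        hub_nodes(net, m1, n_perm=30, seed=9)
        hub_nodes(net, m2, n_perm=30, seed=9)
        assert m1.modules[0].hubs == m2.modules[0].hubs
        assert m1.modules[0].hub_p == m2.modules[0].hub_p

    def test_tiny_module_has_no_hubs(self):
        net = PlanarNetwork(["a", "b"], [("a", "b", 1.0, 1)])
        modules = ModuleSet([Module("M1", None, 1, ["a", "b"],
                                    float("nan"))])
        hub_nodes(net, modules)
        assert modules.modules[0].hubs == []


class TestModulePCs:
    def _modules(self, gene_groups):
        return ModuleSet([Module(f"M{i + 1}", None, 1, list(g), float("nan"))
                          for i, g in enumerate(gene_groups)])

    def test_rank_one_module_needs_one_pc_at_70pct(self, rng):
        f = rng.normal(size=30)
        values = np.outer(rng.normal(size=5) + 2.0, f)
        expr = _em(values)
        modules = self._modules([expr.gene_ids])
        mat, names, _ = module_pcs(expr, modules,
                                   ModulePCSpec("variance", 70))
        assert mat.shape[1] == 1

    def test_projection_identity_on_training_samples(self, rng):
        expr = _em(rng.normal(size=(12, 25)))
        modules = self._modules([expr.gene_ids[:6], expr.gene_ids[6:]])
        mat, names, recipes = module_pcs(expr, modules,
                                         ModulePCSpec("count", 2))
        projected = np.hstack([rec.transform(expr) for rec, _ in recipes])
        np.testing.assert_allclose(projected, mat, atol=1e-8)

    def test_variance_mode_matches_eigenvalue_cumsum_oracle(self, rng):
        values = rng.normal(size=(9, 30))
        recipe = fit_pca(values, [f"g{i}" for i in range(9)])
        x = values.T
        xs = (x - x.mean(0)) / x.std(0, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(xs.T @ xs))[::-1]
        cum = np.cumsum(eig) / eig.sum()
        for v in (70, 75, 80, 85, 95):
            expected = int(np.searchsorted(cum, v / 100 - 1e-12) + 1)
            assert n_components_for(recipe, ModulePCSpec("variance", v)) \
                == expected

    def test_scores_are_orthogonal_within_module(self, rng):
        expr = _em(rng.normal(size=(10, 40)))
        modules = self._modules([expr.gene_ids])
        mat, *_ = module_pcs(expr, modules, ModulePCSpec("count", 5))
        gram = (mat - mat.mean(0)).T @ (mat - mat.mean(0))
        off = gram - np.diag(np.diag(gram))
        assert np.all(np.abs(off) < 1e-8 * np.max(np.diag(gram)))

    def test_single_gene_module_contributes_nothing(self, rng):
        expr = _em(rng.normal(size=(4, 10)))
        modules = self._modules([expr.gene_ids[:1], expr.gene_ids[1:]])
        mat, names, _ = module_pcs(expr, modules, ModulePCSpec("count", 1))
        assert mat.shape[1] == 1
        assert names[0].startswith("M2:")
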