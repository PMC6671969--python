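"""Network construction, interconnectedness testing, Louvain modules."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from napmap.cohort import simulate_network
from napmap.networks import (
    build_coexpression,
    interconnectedness,
    interconnectedness_test,
    louvain_partition,
    matched_random_sets,
    modularity,
)


def set_partitions(items):
    """All partitions of a list (restricted-growth strings)."""
    if len(items) == 1:
        yield [list(items)]
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def modularity_direct(g, communities):
    """Q = sum_c (e_c / m - (d_c / 2m)^2), straight from the definition."""
    m = g.size(weight="weight")
    q = 0.0
    for c in communities:
        e_c = g.subgraph(c).size(weight="weight")
        d_c = sum(d for _, d in g.degree(c, weight="weight"))
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def exhaustive_best_modularity(g):
    return max(
        modularity_direct(g, part) for part in set_partitions(list(g.nodes))
    )


class TestBuildCoexpression:
    def test_low_expression_filter(self):
        # value 0.5 in 96 of 100 samples -> excluded
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.uniform(1, 5, (4, 100)), index=["a", "b", "c", "low"],
        )
        expr.loc["low"] = 0.5
        expr.loc["low", expr.columns[:4]] = 2.0  # expressed in only 4%
        net = build_coexpression(expr, r_quantile=0.0)
        assert "low" not in net.nodes

    def test_perfect_correlation_weight_one(self):
        expr = pd.DataFrame({"s1": [1, 2], "s2": [2, 4], "s3": [3, 6]},
                            index=["g1", "g2"]).astype(float)
        net = build_coexpression(expr, r_quantile=0.0)
        assert net["g1"]["g2"]["weight"] == pytest.approx(1.0)

    def test_weights_match_pearson_oracle(self, rng):
        expr = pd.DataFrame(rng.normal(2, 1, (6, 30)) + 2,
                            index=[f"g{i}" for i in range(6)])
        net = build_coexpression(expr, r_quantile=0.0)
        for a, b in itertools.combinations(expr.index, 2):
            r = stats.pearsonr(expr.loc[a], expr.loc[b]).statistic
            assert net[a][b]["weight"] == pytest.approx(abs(r), abs=1e-12)

    def test_constant_gene_excluded(self):
        expr = pd.DataFrame({"s1": [1, 5], "s2": [1, 6], "s3": [1, 7]},
                            index=["flat", "ok"]).astype(float)
        net = build_coexpression(expr, r_quantile=0.0)
        assert "flat" not in net.nodes

    def test_too_few_samples_rejected(self):
        expr = pd.DataFrame({"s1": [1, 2], "s2": [2, 3]}, index=["a", "b"])
        with pytest.raises(ValueError):
            build_coexpression(expr)


class TestInterconnectedness:
    def test_triangle_and_independent_set(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        g.add_nodes_from(["x", "y"])
        assert interconnectedness(g, {"a", "b", "c"}) == 3.0
        assert interconnectedness(g, {"x", "y"}) == 0.0

    def test_matches_bruteforce_double_loop(self, rng):
        for trial in range(5):
            g = nx.gnp_random_graph(20, 0.3, seed=trial)
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.1, 1))
            genes = set(rng.choice(20, size=8, replace=False).tolist())
            brute = sum(
                g[u][v]["weight"]
                for u, v in itertools.combinations(sorted(genes), 2)
                if g.has_edge(u, v)
            )
            assert interconnectedness(g, genes) == pytest.approx(brute)

    def test_additive_over_disjoint_components(self, rng):
        g1 = simulate_network(10, 1, 0.8, 0.0, seed=1)
        g2 = simulate_network(10, 1, 0.8, 0.0, seed=2,
                              genes=[f"H{i}" for i in range(10)])
        g = nx.union(g1, g2)
        s1 = interconnectedness(g, set(g1.nodes))
        s2 = interconnectedness(g, set(g2.nodes))
        assert interconnectedness(g, set(g.nodes)) == pytest.approx(s1 + s2)


class TestMatchedRandomSets:
    def test_cardinality_and_determinism(self):
        net = simulate_network(60, 3, 0.4, 0.05, seed=3)
        target = set(list(net.nodes)[:12])
        a = matched_random_sets(net, target, n_perm=5, seed=9)
        b = matched_random_sets(net, target, n_perm=5, seed=9)
        assert all(len(s) == 12 for s in a)
        assert a == b

    def test_covariates_matched_on_average(self):
        net = simulate_network(300, 3, 0.15, 0.02, seed=4)
        nodes = list(net.nodes)
        # bias the target toward long-CDS genes to make matching non-trivial
        cds = np.array([net.nodes[n]["cds_length"] for n in nodes])
        target = set(np.array(nodes)[np.argsort(cds)][-30:])
        sets = matched_random_sets(net, target, n_perm=300, seed=5)
        t_cds = np.mean([np.log(net.nodes[n]["cds_length"]) for n in target])
        s_cds = np.mean(
            [np.log(net.nodes[n]["cds_length"]) for s in sets for n in s]
        )
        assert abs(s_cds - t_cds) / abs(t_cds) < 0.15

    def test_uniform_inclusion_within_stratum(self):
        # identical covariates -> one stratum -> every gene equally likely
        g = nx.Graph()
        for i in range(40):
            g.add_node(f"g{i}", cds_length=1000.0, connectivity=1.0)
        target = {f"g{i}" for i in range(8)}
        sets = matched_random_sets(g, target, n_perm=1000, seed=6)
        counts = pd.Series(
            [n for s in sets for n in s]).value_counts().reindex(
            [f"g{i}" for i in range(40)], fill_value=0)
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert stats.chi2.sf(chi2, df=39) > 0.01

    def test_missing_covariates_rejected(self):
        g = nx.Graph()
        g.add_node("a")
        g.add_node("b")
        with pytest.raises(ValueError):
            matched_random_sets(g, {"a"}, n_perm=1, seed=0)


class TestInterconnectednessTest:
    def test_planted_module_significant(self):
        net = simulate_network(200, 20, p_in=0.9, p_out=0.02, seed=7)
        module = {n for n, d in net.nodes(data=True) if d["module"] == 0}
        res = interconnectedness_test(net, module, n_perm=1000, seed=8)
        assert res.p_empirical <= 0.01

    def test_boundary_bookkeeping(self):
        # target is the only connected pair: observed beats every null draw
        g = nx.Graph()
        for i in range(20):
            g.add_node(f"g{i}", cds_length=1000.0, connectivity=0.0)
        g.add_edge("g0", "g1", weight=5.0)
        g.nodes["g0"]["connectivity"] = g.nodes["g1"]["connectivity"] = 5.0
        plain = interconnectedness_test(g, {"g0", "g1"}, n_perm=50, seed=0)
        smooth = interconnectedness_test(g, {"g0", "g1"}, n_perm=50, seed=0,
                                         smoothed=True)
        assert plain.p_empirical == 0.0
        assert smooth.p_empirical == pytest.approx(1 / 51)

    def test_null_p_uniform_on_er_network(self, rng):
        net = simulate_network(120, 1, 0.15, 0.0, seed=9)  # one module = ER
        nodes = list(net.nodes)
        ps = []
        for rep in range(200):
            genes = set(rng.choice(nodes, size=10, replace=False))
            ps.append(
                interconnectedness_test(net, genes, n_perm=99,
                                        seed=2000 + rep).p_empirical
            )
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestLouvainAndModularity:
    def two_triangles(self):
        g = nx.Graph()
        g.add_weighted_edges_from(
            [(0, 1, 1), (1, 2, 1), (0, 2, 1), (3, 4, 1), (4, 5, 1), (3, 5, 1)]
        )
        return g

    def test_two_disjoint_triangles_closed_form(self):
        g = self.two_triangles()
        assignment, q = louvain_partition(g, seed=0)
        assert q == pytest.approx(0.5)
        mods = {frozenset(n for n, m in assignment.items() if m == k)
                for k in set(assignment.values())}
        assert mods == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_single_clique_is_one_module(self):
        g = nx.complete_graph(6)
        assignment, _ = louvain_partition(g, seed=1)
        assert len(set(assignment.values())) == 1

    def test_edgeless_network_singletons(self):
        g = nx.empty_graph(4)
        assignment, q = louvain_partition(g, seed=0)
        assert len(set(assignment.values())) == 4 and q == 0.0

    def test_achieved_at_least_trivial_partition(self, rng):
        g = nx.gnp_random_graph(15, 0.3, seed=3)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.2, 1))
        _, q = louvain_partition(g, seed=4)
        trivial = modularity(g, {n: 0 for n in g.nodes})
        assert q >= trivial - 1e-12

    def test_modularity_closed_forms_and_relabeling(self):
        g = self.two_triangles()
        clique = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
        assert modularity(g, clique) == pytest.approx(0.5)
        assert modularity(g, {n: 7 for n in g.nodes}) == pytest.approx(0.0)
        relabeled = {n: 99 - m for n, m in clique.items()}
        assert modularity(g, relabeled) == pytest.approx(0.5)

    def test_louvain_matches_exhaustive_on_small_graphs(self, rng):
        checked = 0
        for trial in range(10):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(10**6)))
            if g.number_of_edges() == 0:
                continue
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.2, 1.0))
            _, q = louvain_partition(g, seed=trial)
            assert q == pytest.approx(exhaustive_best_modularity(g), abs=1e-9)
            checked += 1
        assert checked >= 7
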