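"""Co-occurrence networks: edge inference, topology vs exhaustive oracles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from agrocore import (
    build_network,
    compare_node_metrics,
    correlation_edges,
    filter_rare,
    network_metrics,
    node_metrics,
    partition_edge_counts,
    subnetwork,
)
from agrocore.community import RelAbundanceTable


def _relab(values):
    values = np.asarray(values, dtype=float)
    values = values / values.sum(axis=1, keepdims=True)
    return RelAbundanceTable(
        [f"s{i}" for i in range(values.shape[0])],
        [f"o{j}" for j in range(values.shape[1])],
        values,
    )


# ---------------------------------------------------------------------------
# brute-force oracles on the adjacency matrix
# ---------------------------------------------------------------------------

def _floyd_warshall(a):
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[a > 0] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k][None, :])
    return d


def _betweenness_oracle(a):
    """Enumerate every shortest path between every pair (tiny graphs)."""
    n = a.shape[0]
    d = _floyd_warshall(a)
    comp_sizes = {}
    comps = []
    seen = set()
    for v in range(n):
        if v in seen:
            continue
        comp = {u for u in range(n) if np.isfinite(d[v, u])}
        comps.append(comp)
        seen |= comp
    betw = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(d[s, t]) or d[s, t] == 0:
            continue
        paths = []
        stack = [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                paths.append(path)
                continue
            for u in np.nonzero(a[v])[0]:
                if d[s, u] == len(path) and d[u, t] == d[s, t] - len(path):
                    stack.append((u, path + [u]))
        sigma = len(paths)
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(v in p for p in paths)
            betw[v] += through / sigma
    for comp in comps:
        nc = len(comp)
        scale = 2.0 / ((nc - 1) * (nc - 2)) if nc > 2 else 0.0
        for v in comp:
            betw[v] *= scale
    return betw


def _closeness_oracle(a):
    n = a.shape[0]
    d = _floyd_warshall(a)
    out = np.zeros(n)
    for v in range(n):
        finite = np.isfinite(d[v]) & (d[v] > 0)
        out[v] = (1.0 / d[v][finite]).sum() / (n - 1) if n > 1 else 0.0
    return out


def _eigenvector_oracle(a):
    n = a.shape[0]
    d = _floyd_warshall(a)
    comps = []
    seen = set()
    for v in range(n):
        if v in seen:
            continue
        comp = sorted(u for u in range(n) if np.isfinite(d[v, u]))
        comps.append(comp)
        seen |= set(comp)
    comps.sort(key=lambda c: (-len(c), c[0]))
    out = np.zeros(n)
    giant = comps[0]
    if len(giant) > 1:
        sub = a[np.ix_(giant, giant)]
        w, v = np.linalg.eigh(sub)
        vec = np.abs(v[:, np.argmax(w)])
        vec = vec / vec.max()
        for i, node in enumerate(giant):
            out[node] = vec[i]
    return out


def _random_graph(rng, n_max=8):
    n = rng.integers(2, n_max + 1)
    p = rng.uniform(0.15, 0.8)
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    a = a + a.T
    return a


def _graph_from_adjacency(a):
    g = nx.Graph()
    n = a.shape[0]
    g.add_nodes_from(str(i) for i in range(n))
    for i, j in zip(*np.nonzero(np.triu(a, 1))):
        g.add_edge(str(i), str(j), rho=1.0, q=0.0)
    return g


class TestFilterRare:
    def test_boundary_rule(self):
        vals = np.ones((5, 3))
        vals[:, 1] = 4e-4   # mean RA ~1e-4 after normalization: kept (>=)
        vals[:, 2] = 4e-5   # below threshold: removed
        relab = _relab(vals)
        mean_ra = relab.mean_ra()
        kept = filter_rare(relab, min_mean_ra=1e-4)
        expected = [o for o in relab.otu_ids if mean_ra[o] >= 1e-4]
        assert kept.otu_ids == expected

    def test_all_removed_raises(self):
        relab = _relab(np.ones((5, 3)))
        with pytest.raises(ValueError):
            filter_rare(relab, min_mean_ra=0.9)


class TestCorrelationEdges:
    def test_identical_rank_profiles_give_rho_one(self):
        rng = np.random.default_rng(0)
        base = rng.random(20) + 0.1
        vals = np.column_stack([base, base * 3, rng.random(20) + 0.1])
        edges = correlation_edges(_relab(vals), rho_min=0.6, q_max=0.05)
        pair = edges[(edges["source"] == "o0") & (edges["target"] == "o1")]
        assert len(pair) == 1
        assert pair["rho"].iloc[0] == pytest.approx(1.0)

    def test_independent_noise_yields_almost_no_edges(self):
        count = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            vals = rng.random((60, 50)) + 0.05
            edges = correlation_edges(_relab(vals))
            count += len(edges)
        assert count / 10 < 1.0

    def test_symmetry_and_monotone_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.random((25, 6)) + 0.05
        e1 = correlation_edges(_relab(vals), rho_min=0.0, q_max=1.0)
        transformed = vals ** 3  # strictly monotone per-value transform
        e2 = correlation_edges(_relab(transformed), rho_min=0.0, q_max=1.0)
        m1 = {tuple(sorted((r.source, r.target))): r.rho for r in e1.itertuples()}
        m2 = {tuple(sorted((r.source, r.target))): r.rho for r in e2.itertuples()}
        # note: row-normalization differs, but ranks of each OTU are driven
        # by the same monotone profile here
        assert set(m1) == set(m2)


class TestGraphConstruction:
    def test_subnetwork_induced_oracle(self):
        rng = np.random.default_rng(2)
        a = _random_graph(rng, 8)
        g = _graph_from_adjacency(a)
        nodes = [str(i) for i in range(a.shape[0])]
        subset = nodes[: max(2, len(nodes) // 2)]
        sub = subnetwork(g, subset)
        expected = {
            (u, v) for u, v in g.edges if u in subset and v in subset
        }
        got = {tuple(sorted(e)) for e in sub.edges}
        assert got == {tuple(sorted(e)) for e in expected}

    def test_full_subset_identity_and_unknown_node(self):
        g = _graph_from_adjacency(np.array([[0, 1], [1, 0]]))
        assert subnetwork(g, list(g.nodes)).number_of_edges() == 1
        with pytest.raises(KeyError):
            subnetwork(g, ["nope"])

    def test_self_loops_dropped(self):
        edges = pd.DataFrame(
            {"source": ["a", "a"], "target": ["a", "b"],
             "rho": [0.9, 0.8], "q": [0.0, 0.0]}
        )
        g = build_network(edges)
        assert g.number_of_edges() == 1


class TestNodeMetrics:
    def test_path_graph_enumerable(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        m = node_metrics(g)
        assert list(m["degree"]) == [1, 2, 1]
        assert m.loc["B", "betweenness"] == pytest.approx(1.0)  # only (A,C) pair
        assert m.loc["B", "eigenvector"] == pytest.approx(1.0)

    def test_star_center_maximal(self):
        g = nx.star_graph(3)
        m = node_metrics(nx.relabel_nodes(g, str))
        assert m.loc["0", "eigenvector"] == pytest.approx(1.0)
        assert (m.loc[["1", "2", "3"], "eigenvector"] < 1).all()

    def test_exhaustive_small_graph_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(120):
            a = _random_graph(rng, 8)
            g = _graph_from_adjacency(a)
            m = node_metrics(g)
            n = a.shape[0]
            assert np.array_equal(
                m["degree"].to_numpy(), a.sum(axis=1)
            )
            assert np.allclose(
                m["betweenness"].to_numpy(), _betweenness_oracle(a), atol=1e-10
            )
            assert np.allclose(
                m["closeness"].to_numpy(), _closeness_oracle(a), atol=1e-10
            )
            assert np.allclose(
                m["eigenvector"].to_numpy(), _eigenvector_oracle(a), atol=1e-6
            )


class TestNetworkMetrics:
    def test_complete_graph(self):
        g = nx.relabel_nodes(nx.complete_graph(4), str)
        m = network_metrics(g)
        assert m.graph_density == pytest.approx(1.0)
        assert m.clustering_coefficient == pytest.approx(1.0)
        assert m.average_path_length == pytest.approx(1.0)
        assert m.diameter == pytest.approx(1.0)
        assert m.average_degree == pytest.approx(3.0)

    def test_five_cycle(self):
        g = nx.relabel_nodes(nx.cycle_graph(5), str)
        m = network_metrics(g)
        assert m.clustering_coefficient == pytest.approx(0.0)
        assert m.diameter == pytest.approx(2.0)
        assert m.average_degree == pytest.approx(2.0)

    def test_two_disconnected_cliques_modular(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        m = network_metrics(nx.relabel_nodes(g, str))
        assert m.modularity >= 0.45

    def test_edgeless_graph_na_flagged(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        m = network_metrics(g)
        assert np.isnan(m.average_path_length) and np.isnan(m.diameter)
        assert m.average_degree == 0.0

    def test_oracle_on_random_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(60):
            a = _random_graph(rng, 8)
            g = _graph_from_adjacency(a)
            m = network_metrics(g)
            n, e = a.shape[0], int(a.sum() // 2)
            assert m.average_degree == pytest.approx(2 * e / n)
            assert m.graph_density == pytest.approx(2 * e / (n * (n - 1)))
            # local clustering oracle (degree<2 -> 0)
            local = []
            for v in range(n):
                nb = np.nonzero(a[v])[0]
                k = len(nb)
                if k < 2:
                    local.append(0.0)
                else:
                    tri = a[np.ix_(nb, nb)].sum() / 2
                    local.append(tri / (k * (k - 1) / 2))
            assert m.clustering_coefficient == pytest.approx(np.mean(local))
            if e:
                d = _floyd_warshall(a)
                comps = []
                seen = set()
                for v in range(n):
                    if v not in seen:
                        c = sorted(u for u in range(n) if np.isfinite(d[v, u]))
                        comps.append(c)
                        seen |= set(c)
                giant = max(comps, key=lambda c: (len(c), -c[0]))
                dg = d[np.ix_(giant, giant)]
                if len(giant) > 1:
                    iu = np.triu_indices(len(giant), 1)
                    assert m.average_path_length == pytest.approx(dg[iu].mean())
                    assert m.diameter == pytest.approx(dg[iu].max())
                assert m.diameter >= m.average_path_length


class TestPartitionCounts:
    def test_identity_and_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = _random_graph(rng, 8)
            g = _graph_from_adjacency(a)
            labels = {v: rng.choice(["x", "y", "z"]) for v in g.nodes}
            inner, external = partition_edge_counts(g, labels)
            assert sum(inner.values()) + sum(external.values()) == g.number_of_edges()
            for grp, cnt in inner.items():
                oracle = sum(
                    1 for u, v in g.edges if labels[u] == labels[v] == grp
                )
                assert cnt == oracle

    def test_single_label_no_external(self):
        g = _graph_from_adjacency(np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]]))
        inner, external = partition_edge_counts(g, {v: "a" for v in g.nodes})
        assert external == {}
        assert inner["a"] == 2

    def test_unlabeled_node_rejected(self):
        g = _graph_from_adjacency(np.array([[0, 1], [1, 0]]))
        with pytest.raises(ValueError):
            partition_edge_counts(g, {"0": "a"})


class TestCompareNodeMetrics:
    def test_dense_block_vs_periphery_significant(self):
        g = nx.disjoint_union(nx.complete_graph(12), nx.path_graph(12))
        g = nx.relabel_nodes(g, str)
        m = node_metrics(g)
        groups = pd.Series(
            ["hub"] * 12 + ["periphery"] * 12, index=m.index
        )
        res = compare_node_metrics(m, groups)
        assert res.loc["degree", "p"] < 0.01

    def test_identical_groups_not_significant(self):
        g = nx.relabel_nodes(nx.disjoint_union(nx.cycle_graph(8), nx.cycle_graph(8)), str)
        m = node_metrics(g)
        groups = pd.Series(["a"] * 8 + ["b"] * 8, index=m.index)
        res = compare_node_metrics(m, groups)
        assert res.loc["degree", "p"] > 0.5 or np.isnan(res.loc["degree", "p"])

    def test_letter_display_three_groups(self):
        rng = np.random.default_rng(6)
        # three groups of nodes with very different degrees
        g = nx.Graph()
        for i in range(10):
            g.add_node(f"lo{i}")
        g.add_edges_from((f"mid{i}", f"mid{(i + 1) % 10}") for i in range(10))
        hub = nx.complete_graph(10)
        g = nx.union(g, nx.relabel_nodes(hub, lambda v: f"hi{v}"))
        m = node_metrics(g)
        groups = pd.Series(
            ["hi" if n.startswith("hi") else "mid" if n.startswith("mid") else "lo"
             for n in m.index],
            index=m.index,
        )
        res = compare_node_metrics(m, groups)
        letters = res.loc["degree", "letters"]
        assert letters["hi"] != letters["lo"]
        # every group carries at least one letter
        assert all(letters[g] for g in ("hi", "mid", "lo"))
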