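"""Core reduction algorithm: filtering, SPL, edge construction, pruning."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from gsanet.errors import UsageError
from gsanet.io_formats import Config
from gsanet.reduction import (all_pairs_spl, assemble_visualization_network,
                              build_edges, filter_significant,
                              prune_best_edges, reduce_network)


def floyd_warshall_spl(graph: nx.Graph) -> dict[frozenset, float]:
    """Independent exhaustive all-pairs shortest-path oracle (O(n^3))."""
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    dist = [[math.inf] * n for _ in range(n)]
    for i in range(n):
        dist[i][i] = 0
    for u, v in graph.edges():
        dist[idx[u]][idx[v]] = dist[idx[v]][idx[u]] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    return {frozenset((a, b)): dist[idx[a]][idx[b]]
            for a, b in itertools.combinations(nodes, 2)}


def _stats(d: dict[str, dict[str, float]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(d, orient="index")


class TestFilterSignificant:
    def test_inclusive_cutoff(self):
        stats = _stats({"A": {"p": 0.01}, "B": {"p": 0.2}, "C": {"p": 0.05}})
        assert filter_significant(stats, 0.05) == {"A": 0.01, "C": 0.05}

    def test_best_is_min_over_classes(self):
        stats = _stats({"A": {"up": 0.9, "down": 0.01}})
        assert filter_significant(stats, 0.05) == {"A": 0.01}

    def test_cutoff_one_keeps_everything_with_a_p(self):
        stats = _stats({"A": {"p": 0.99}, "B": {"p": math.nan}})
        assert filter_significant(stats, 1.0) == {"A": 0.99}

    def test_column_selection_and_errors(self):
        stats = _stats({"A": {"up": 0.9, "down": 0.01}})
        assert filter_significant(stats, 0.05, columns=["up"]) == {}
        with pytest.raises(UsageError):
            filter_significant(stats, 0.05, columns=["sideways"])
        with pytest.raises(UsageError):
            filter_significant(stats, 1.5)

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(0)
        stats = _stats({f"S{i}": {"p": rng.uniform()} for i in range(40)})
        cutoffs = sorted(rng.uniform(size=6))
        sets = [set(filter_significant(stats, c)) for c in cutoffs]
        for small, big in zip(sets, sets[1:]):
            assert small <= big


class TestAllPairsSpl:
    def test_path_graph(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        assert all_pairs_spl(g, {"a", "d"}) == {frozenset("ad"): 3}

    def test_star_leaves(self):
        g = nx.star_graph(["h", "l1", "l2", "l3", "l4"])
        assert all_pairs_spl(g, {"l1", "l2"})[frozenset(("l1", "l2"))] == 2

    def test_unreachable_pair_absent(self):
        g = nx.Graph([("a", "b"), ("c", "d")])
        assert all_pairs_spl(g, {"a", "c"}) == {}

    def test_sources_absent_from_network_dropped(self, caplog):
        g = nx.path_graph(["a", "b"])
        assert all_pairs_spl(g, {"a", "zz"}) == {}
        assert any("absent" in r.message for r in caplog.records)

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(2, 16))
            g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(2**31 - 1)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)})
            sources = set(g.nodes)
            expected = {pair: d for pair, d in floyd_warshall_spl(g).items()
                        if math.isfinite(d)}
            assert all_pairs_spl(g, sources) == expected

    def test_spl_uses_full_network_not_significant_subgraph(self):
        # u - x - v: x is the only bridge and is non-significant
        g = nx.path_graph(["u", "x", "v"])
        assert all_pairs_spl(g, {"u", "v"}) == {frozenset(("u", "v")): 2}
        g.remove_node("x")
        assert all_pairs_spl(g, {"u", "v"}) == {}  # disconnects entirely


class TestBuildEdges:
    CAPTION_SPLS = {frozenset("AB"): 3, frozenset("CD"): 4}

    @pytest.mark.parametrize("cutoff, expected", [
        (5, {frozenset("AB"), frozenset("CD")}),
        (4, {frozenset("AB")}),
        (3, set()),
    ])
    def test_strictly_below_cutoff(self, cutoff, expected):
        edges = build_edges({"A", "B", "C", "D"}, self.CAPTION_SPLS, cutoff)
        assert set(edges) == expected

    def test_restricted_to_significant(self):
        edges = build_edges({"A", "B"}, self.CAPTION_SPLS, 10)
        assert set(edges) == {frozenset("AB")}

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        nodes = [f"s{i}" for i in range(12)]
        spl = {frozenset(p): int(rng.integers(1, 9))
               for p in itertools.combinations(nodes, 2)}
        prev: set = set()
        for cutoff in range(2, 11):
            cur = set(build_edges(set(nodes), spl, cutoff))
            assert prev <= cur
            prev = cur

    def test_cutoff_validation(self):
        with pytest.raises(UsageError):
            build_edges({"A", "B"}, self.CAPTION_SPLS, 1)


class TestPruneBestEdges:
    def test_neighbor_best_edge_survives(self):
        edges = {frozenset("XY"): 1, frozenset("YZ"): 2, frozenset("XZ"): 3}
        assert prune_best_edges(edges) == {frozenset("XY"): 1, frozenset("YZ"): 2}

    def test_ties_all_kept(self):
        edges = {frozenset("XY"): 2, frozenset("XZ"): 2}
        assert prune_best_edges(edges) == edges

    def test_single_edge_kept(self):
        edges = {frozenset("XY"): 4}
        assert prune_best_edges(edges) == edges

    def test_soundness_on_random_edge_sets(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            nodes = [f"v{i}" for i in range(n)]
            pairs = list(itertools.combinations(nodes, 2))
            keep = rng.uniform(size=len(pairs)) < 0.4
            edges = {frozenset(p): int(rng.integers(1, 7))
                     for p, k in zip(pairs, keep) if k}
            if not edges:
                continue
            pruned = prune_best_edges(edges)
            assert set(pruned) <= set(edges)
            best = {}
            for pair, d in edges.items():
                for node in pair:
                    best[node] = min(best.get(node, d), d)
            # every kept edge is minimal for >=1 endpoint, every dropped
            # edge is minimal for neither, and no node loses all its edges
            for pair, d in edges.items():
                minimal = any(d == best[v] for v in pair)
                assert (pair in pruned) == minimal
            assert {v for e in pruned for v in e} == {v for e in edges for v in e}


class TestAssemble:
    STYLE = {"size": 20.0, "direction_score": 0.0, "color": "#F7F7F7"}

    def test_isolated_significant_nodes_kept(self):
        viz = assemble_visualization_network(
            {"A": 0.01, "B": 0.02, "C": 0.03}, {frozenset("AB"): 2},
            {s: dict(self.STYLE) for s in "ABC"}, lambda spl: 1.0)
        assert set(viz.nodes) == {"A", "B", "C"}
        assert viz.degree("C") == 0

    def test_empty_network(self, caplog):
        viz = assemble_visualization_network({}, {}, {}, lambda spl: 1.0)
        assert len(viz) == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_missing_style_is_internal_error(self):
        with pytest.raises(RuntimeError, match="styling"):
            assemble_visualization_network({"A": 0.01}, {}, {}, lambda spl: 1.0)


class TestReduceNetwork:
    def test_pruning_toggle(self, caption_case):
        c = caption_case
        # add a triangle-ish redundancy: connect A to D via a 2-hop path
        net = c.network.copy()
        nx.add_path(net, ["A", "m1", "D"])
        pruned = reduce_network(c.gss, net, c.gsc, c.gls,
                                Config(spl_cutoff=6, prune=True))
        unpruned = reduce_network(c.gss, net, c.gsc, c.gls,
                                  Config(spl_cutoff=6, prune=False))
        assert set(pruned.edges) <= set(unpruned.edges)
        assert unpruned.number_of_edges() > pruned.number_of_edges()

    def test_adjacent_significant_sets_get_thickest_edge(self):
        g = nx.path_graph(["A", "B", "C"])
        gss = _stats({"A": {"p": 0.01}, "B": {"p": 0.01}, "C": {"p": 0.5}})
        viz = reduce_network(gss, g, config=Config())
        assert viz.edges["A", "B"]["spl"] == 1
        assert viz.edges["A", "B"]["thickness"] == Config().style.thick_max
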