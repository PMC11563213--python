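"""z-transform, module scoring, greedy growth and the overlap filter."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from pathnet.active_subnetworks import (
    CalibrationTable,
    Subnetwork,
    calibrate,
    find_subnetworks,
    greedy_search,
    min_set_overlap,
    overlap_filter,
    score_subnetwork,
    z_transform,
)
from pathnet.io_formats import GeneScoreTable, PPINetwork


def make_scores(pvals, ppi):
    table = GeneScoreTable(entries=dict(pvals), layer_label="genomic")
    return z_transform(table, ppi)


def net_from_edges(edges, extra_nodes=()):
    nodes = set(itertools.chain.from_iterable(edges)) | set(extra_nodes)
    return PPINetwork(nodes=nodes, edges={frozenset(e) for e in edges})


class TestZTransform:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.5, 0.0), (0.05, 1.6449), (0.975, -1.9600)],
    )
    def test_inverse_normal_values(self, p, expected, path_graph):
        scores = make_scores({"A": p, "B": 0.5, "C": 0.5}, path_graph)
        z = {s.gene_id: s.z for s in scores}
        assert z["A"] == pytest.approx(expected, abs=1e-4)

    def test_genes_outside_network_dropped(self, path_graph):
        scores = make_scores({"A": 0.1, "ZZZ": 0.01}, path_graph)
        assert {s.gene_id for s in scores} == {"A"}

    def test_z_monotone_in_p(self, path_graph):
        ps = [0.001, 0.01, 0.2, 0.5, 0.8, 0.999]
        scores = make_scores(
            {g: p for g, p in zip("ABC", ps[:3])}, path_graph
        )
        zs = [s.z for s in sorted(scores, key=lambda s: s.p_value)]
        assert zs == sorted(zs, reverse=True)


class TestScoring:
    def test_single_node_score_is_z(self, path_graph):
        scores = make_scores({"A": 0.05}, path_graph)
        sub = score_subnetwork({"A"}, scores)
        assert sub.z_score == pytest.approx(scores[0].z)

    def test_aggregate_algebra(self):
        # k=4, all z=2 -> z_A = 8/sqrt(4) = 4
        sub = score_subnetwork(
            {"a", "b", "c", "d"}, {g: 2.0 for g in "abcd"}
        )
        assert sub.z_score == pytest.approx(4.0)

    def test_calibration_standardises_random_sets(self):
        """Random 10-node sets under uniform p: s_A has mean ~0, sd ~1."""
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(200)]
        ppi = net_from_edges(
            [(genes[i], genes[i + 1]) for i in range(199)]
        )
        pvals = {g: float(rng.uniform()) for g in genes}
        scores = make_scores(pvals, ppi)
        cal = calibrate(scores, max_k=12, n_samples=2000, rng=rng)
        draws = [
            score_subnetwork(
                set(rng.choice(genes, 10, replace=False)),
                scores, cal,
            ).s_score
            for _ in range(1000)
        ]
        assert np.mean(draws) == pytest.approx(0.0, abs=0.1)
        assert np.std(draws) == pytest.approx(1.0, abs=0.1)

    def test_calibration_interpolates_outside_range(self):
        cal = CalibrationTable(
            sizes=np.array([1, 2, 3]), mu=np.array([0.0, 1.0, 2.0]),
            sigma=np.array([1.0, 1.0, 2.0]), n_samples=10,
        )
        assert cal.moments(10) == (2.0, 2.0)  # clamped extrapolation


class TestGreedySearch:
    def test_star_graph_keeps_center_only(self):
        edges = [("hub", f"leaf{i}") for i in range(5)]
        ppi = net_from_edges(edges)
        zmap = {"hub": 3.0} | {f"leaf{i}": -1.0 for i in range(5)}
        # realise the z values through p = norm.sf(z)
        from scipy.stats import norm

        table = GeneScoreTable(
            entries={g: float(norm.sf(z)) for g, z in zmap.items()},
            layer_label="genomic",
        )
        node_scores = z_transform(table, ppi)
        (top, *_) = greedy_search(ppi, node_scores, calibration=None, n_seeds=1)
        assert top.members == frozenset({"hub"})

    def test_path_grows_to_positive_pair(self, path_graph):
        """A(z=2)-B(z=2)-C(z=-3): exhaustive optimum is {A,B}, score 4/sqrt(2)."""
        from scipy.stats import norm

        table = GeneScoreTable(
            entries={"A": float(norm.sf(2)), "B": float(norm.sf(2)),
                     "C": float(norm.sf(-3))},
            layer_label="genomic",
        )
        node_scores = z_transform(table, path_graph)
        (top, *_) = greedy_search(path_graph, node_scores, None, n_seeds=1)
        assert top.members == frozenset({"A", "B"})
        assert top.z_score == pytest.approx(4 / math.sqrt(2), rel=1e-6)

    def test_all_zero_scores_return_seeds(self, path_graph):
        table = GeneScoreTable(
            entries={g: 0.5 for g in "ABC"}, layer_label="genomic"
        )
        node_scores = z_transform(table, path_graph)
        mods = greedy_search(path_graph, node_scores, None, n_seeds=3)
        assert all(m.size == 1 for m in mods)
        assert all(m.z_score == pytest.approx(0.0, abs=1e-12) for m in mods)

    def test_connectivity_of_all_modules(self):
        rng = np.random.default_rng(7)
        g = nx.gnp_random_graph(40, 0.1, seed=3)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
        ppi = PPINetwork.from_networkx(g)
        table = GeneScoreTable(
            entries={n: float(rng.uniform(1e-6, 1)) for n in ppi.nodes},
            layer_label="genomic",
        )
        mods = find_subnetworks(table, ppi, rng=np.random.default_rng(0))
        gx = ppi.to_networkx()
        for m in mods:
            assert nx.is_connected(gx.subgraph(m.members))

    def test_deterministic_under_fixed_rng(self):
        g = nx.gnp_random_graph(30, 0.15, seed=9)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
        ppi = PPINetwork.from_networkx(g)
        rng = np.random.default_rng(11)
        table = GeneScoreTable(
            entries={n: float(rng.uniform(1e-6, 1)) for n in ppi.nodes},
            layer_label="genomic",
        )
        a = find_subnetworks(table, ppi, rng=np.random.default_rng(5))
        b = find_subnetworks(table, ppi, rng=np.random.default_rng(5))
        assert [(m.members, m.s_score) for m in a] == [
            (m.members, m.s_score) for m in b
        ]

    def test_near_optimal_on_small_graphs(self):
        """The best greedily grown module scores >=90% of the exhaustive
        optimum over connected subsets on graphs with <=10 nodes (every node
        acts as a seed; positive optima only)."""
        n_checked = 0
        for trial in range(100):
            rng = np.random.default_rng(trial)
            g = nx.gnp_random_graph(8, 0.35, seed=trial)
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
            ppi = PPINetwork.from_networkx(g)
            table = GeneScoreTable(
                entries={n: float(rng.uniform(1e-4, 1)) for n in ppi.nodes},
                layer_label="genomic",
            )
            node_scores = z_transform(table, ppi)
            zmap = {s.gene_id: s.z for s in node_scores}
            gx = ppi.to_networkx()
            best = -math.inf
            nodes = sorted(gx.nodes())
            for r in range(1, len(nodes) + 1):
                for comb in itertools.combinations(nodes, r):
                    sub = gx.subgraph(comb)
                    if nx.is_connected(sub):
                        za = sum(zmap[n] for n in comb) / math.sqrt(r)
                        best = max(best, za)
            if best <= 0:
                continue
            n_checked += 1
            mods = greedy_search(ppi, node_scores, None, n_seeds=len(nodes))
            assert mods[0].z_score >= 0.9 * best - 1e-12
        assert n_checked >= 50


class TestOverlapFilter:
    def _sub(self, members, score):
        return Subnetwork(frozenset(members), score, score)

    def test_identical_sets_second_rejected(self):
        subs = [self._sub("abc", 3.0), self._sub("abc", 2.0)]
        assert overlap_filter(subs) == [subs[0]]

    def test_disjoint_sets_both_kept(self):
        subs = [self._sub("ab", 3.0), self._sub("cd", 2.0)]
        assert overlap_filter(subs) == subs

    def test_boundary_overlap_inclusive(self):
        # |A|=4, |B|=6, |A∩B|=2 -> overlap 0.5 <= 0.5 -> accepted
        a = self._sub({"1", "2", "3", "4"}, 3.0)
        b = self._sub({"1", "2", "5", "6", "7", "8"}, 2.0)
        assert min_set_overlap(a.members, b.members) == pytest.approx(0.5)
        assert overlap_filter([a, b]) == [a, b]

    def test_pairwise_bound_holds_after_filter(self):
        rng = np.random.default_rng(13)
        subs = sorted(
            (
                self._sub(
                    set(map(str, rng.choice(30, rng.integers(2, 10), replace=False))),
                    float(rng.normal()),
                )
                for _ in range(40)
            ),
            key=lambda s: -s.s_score,
        )
        kept = overlap_filter(subs)
        for x, y in itertools.combinations(kept, 2):
            assert min_set_overlap(x.members, y.members) <= 0.5
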