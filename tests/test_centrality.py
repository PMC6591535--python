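"""Weight transform and the four centrality measures vs brute-force oracles."""

import numpy as np
import pytest

from ssnkit.centrality import (
    DistanceWeightTransform,
    SimilarityNetwork,
    betweenness,
    closeness,
    eigenvector_centrality,
    mst_centrality_graph,
    threshold_graph,
    to_weights,
    weighted_degree,
)
from ssnkit.distance import DistanceMatrix

from tests.conftest import (
    make_distance_matrix,
    random_connected_network,
    random_distance_matrix,
)
from tests.oracles import (
    brute_betweenness,
    brute_closeness,
    dense_leading_eigenpair,
)


def net_from_lengths(ids, edges):
    """Network from explicit transformed edge lengths (absent = no edge)."""
    ids = tuple(ids)
    n = len(ids)
    index = {name: i for i, name in enumerate(ids)}
    lengths = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for (a, b), d in edges.items():
        i, j = index[a], index[b]
        lengths[i, j] = lengths[j, i] = float(d)
        mask[i, j] = mask[j, i] = True
    return SimilarityNetwork.from_lengths(ids, lengths, mask=mask)


def edge_dict(net):
    return {
        (i, j): net.lengths[i, j]
        for i in range(len(net))
        for j in range(i + 1, len(net))
        if net.mask[i, j]
    }


class TestToWeights:
    def test_zero_distance_maps_to_weight_one(self, dm_factory):
        dm = dm_factory("ab", {("a", "b"): 0.0})
        net = to_weights(dm)
        assert net.lengths[0, 1] == 1e-200
        assert abs(net.weights[0, 1] - 1.0) < 1e-15

    def test_tiny_distance_compresses(self, dm_factory):
        dm = dm_factory("ab", {("a", "b"): 1e-100})
        net = to_weights(dm, q=0.01)
        assert net.lengths[0, 1] == pytest.approx(0.1, rel=1e-12)
        assert net.weights[0, 1] == pytest.approx(1 / 1.1, rel=1e-12)

    def test_unit_distance(self, dm_factory):
        dm = dm_factory("ab", {("a", "b"): 1.0})
        net = to_weights(dm)
        assert net.weights[0, 1] == pytest.approx(0.5, rel=1e-12)

    def test_weight_strictly_decreasing_in_distance(self):
        d = np.sort(10.0 ** np.linspace(-150, 3, 40))
        w = []
        for x in d:
            dm = make_distance_matrix("ab", {("a", "b"): x})
            w.append(to_weights(dm).weights[0, 1])
        assert all(a > b for a, b in zip(w, w[1:]))

    def test_symmetry_and_diagonal_preserved(self, rng):
        dm = random_distance_matrix(rng, 6)
        net = to_weights(dm)
        assert np.array_equal(net.weights, net.weights.T)
        assert np.all(np.diag(net.weights) == 0)
        assert np.all(np.diag(net.lengths) == 0)
        off = ~np.eye(6, dtype=bool)
        assert np.all(net.weights[off] > 0)
        assert np.all(net.weights[off] <= 1.0)

    @pytest.mark.parametrize("q,delta", [(0.0, 1e-200), (-1, 1e-200),
                                         (0.01, 0.0), (0.01, -1)])
    def test_nonpositive_parameters_rejected(self, q, delta, dm_factory):
        dm = dm_factory("ab", {("a", "b"): 1.0})
        with pytest.raises(ValueError):
            to_weights(dm, q=q, delta=delta)


class TestWeightedDegree:
    def test_row_sums(self):
        net = net_from_lengths("abc", {("a", "b"): 1.0, ("a", "c"): 1.0,
                                       ("b", "c"): 1.0})
        assert weighted_degree(net) == {
            "a": pytest.approx(1.0), "b": pytest.approx(1.0),
            "c": pytest.approx(1.0),
        }

    def test_star(self):
        # center-leaf weight 0.9 => length 1/0.9-1; leaf-leaf 0.1
        d_cl = 1 / 0.9 - 1
        d_ll = 1 / 0.1 - 1
        edges = {("c", x): d_cl for x in "pqr"}
        edges.update(
            {(x, y): d_ll for x, y in [("p", "q"), ("p", "r"), ("q", "r")]}
        )
        wd = weighted_degree(net_from_lengths("cpqr", edges))
        assert wd["c"] == pytest.approx(2.7)
        assert wd["p"] == pytest.approx(1.1)

    def test_single_node(self):
        net = SimilarityNetwork.from_lengths(
            ("a",), np.zeros((1, 1)), mask=np.zeros((1, 1), dtype=bool)
        )
        assert weighted_degree(net) == {"a": 0.0}


class TestCloseness:
    def test_path_graph_closed_form(self):
        net = net_from_lengths("abc", {("a", "b"): 1.0, ("b", "c"): 1.0})
        cc = closeness(net)
        assert cc["b"] == pytest.approx(1.0)
        assert cc["a"] == pytest.approx(2 / 3)
        assert cc["c"] == pytest.approx(2 / 3)

    def test_complete_graph_symmetry(self):
        t = 0.37
        edges = {(a, b): t for a, b in
                 [("a", "b"), ("a", "c"), ("b", "c")]}
        cc = closeness(net_from_lengths("abc", edges))
        for v in cc.values():
            assert v == pytest.approx(1 / t)

    def test_paths_shortcut_direct_edges(self):
        # triangle violating the triangle inequality: a-b direct 5,
        # via c only 2
        edges = {("a", "b"): 5.0, ("a", "c"): 1.0, ("b", "c"): 1.0}
        cc = closeness(net_from_lengths("abc", edges))
        assert cc["a"] == pytest.approx(2 / 3)

    def test_isolated_node_gets_zero(self):
        net = net_from_lengths("abc", {("a", "b"): 1.0})
        assert closeness(net)["c"] == 0.0


class TestBetweenness:
    def test_star_center_counts_leaf_pairs(self):
        edges = {("c", x): 1.0 for x in "pqr"}
        nodes, _ = betweenness(net_from_lengths("cpqr", edges))
        assert nodes["c"] == pytest.approx(3.0)
        assert nodes["p"] == 0.0

    def test_path_graph_enumeration(self):
        edges = {("a", "b"): 1.0, ("b", "c"): 1.0, ("c", "d"): 1.0}
        nodes, edge_bt = betweenness(net_from_lengths("abcd", edges))
        assert nodes["b"] == pytest.approx(2.0)
        assert nodes["c"] == pytest.approx(2.0)
        assert edge_bt[("b", "c")] == pytest.approx(4.0)

    def test_complete_graph_equal_lengths_all_zero(self):
        edges = {(a, b): 1.0 for a, b in
                 [("a", "b"), ("a", "c"), ("b", "c")]}
        nodes, _ = betweenness(net_from_lengths("abc", edges))
        assert all(v == 0.0 for v in nodes.values())

    def test_matches_networkx_on_random_graphs(self, rng):
        import networkx as nx

        for _ in range(10):
            net = random_connected_network(rng)
            nodes, _ = betweenness(net)
            g = nx.Graph()
            g.add_nodes_from(net.ids)
            for (i, j), d in edge_dict(net).items():
                g.add_edge(net.ids[i], net.ids[j], length=d)
            expected = nx.betweenness_centrality(
                g, weight="length", normalized=False
            )
            for u in net.ids:
                assert nodes[u] == pytest.approx(expected[u], abs=1e-9)


class TestEigenvector:
    def test_complete_graph_closed_form(self):
        w = 0.5  # equal weights: x uniform, lambda = (n-1) w
        length = 1 / w - 1
        edges = {(a, b): length for a, b in
                 [("a", "b"), ("a", "c"), ("b", "c")]}
        values, lam = eigenvector_centrality(net_from_lengths("abc", edges))
        for v in values.values():
            assert v == pytest.approx(1 / np.sqrt(3), rel=1e-9)
        assert lam == pytest.approx(2 * w, rel=1e-9)

    def test_disconnected_warns_and_computes_per_component(self):
        net = net_from_lengths("abcd", {("a", "b"): 1.0, ("c", "d"): 1.0})
        with pytest.warns(RuntimeWarning, match="disconnected"):
            values, lam = eigenvector_centrality(net)
        assert values["a"] == pytest.approx(values["c"], rel=1e-9)
        assert lam > 0

    def test_matches_dense_solver(self, rng):
        for _ in range(10):
            net = random_connected_network(rng)
            values, lam = eigenvector_centrality(net)
            expected_vec, expected_lam = dense_leading_eigenpair(net.weights)
            ours = np.array([values[u] for u in net.ids])
            assert lam == pytest.approx(expected_lam, rel=1e-9, abs=1e-12)
            assert np.allclose(ours, expected_vec, atol=1e-9)

    def test_unit_norm_and_nonnegative(self, rng):
        net = random_connected_network(rng)
        values, _ = eigenvector_centrality(net)
        vec = np.array(list(values.values()))
        assert np.linalg.norm(vec) == pytest.approx(1.0)
        assert np.all(vec >= 0)


class TestOracleEquivalence:
    """Implementation vs exhaustive path enumeration on small graphs."""

    def test_closeness_and_betweenness(self, rng):
        for _ in range(20):
            net = random_connected_network(rng)
            edges = edge_dict(net)
            n = len(net)
            cc = closeness(net)
            expected_cc = brute_closeness(n, edges)
            for i, u in enumerate(net.ids):
                assert cc[u] == pytest.approx(expected_cc[i], rel=1e-9)
            nodes, edge_bt = betweenness(net)
            exp_nodes, exp_edges = brute_betweenness(n, edges)
            for i, u in enumerate(net.ids):
                assert nodes[u] == pytest.approx(exp_nodes[i], abs=1e-9)
            for (i, j), v in exp_edges.items():
                assert edge_bt[(net.ids[i], net.ids[j])] == pytest.approx(
                    v, abs=1e-9
                )


class TestZeroDistanceCore:
    def test_clique_members_share_closeness_and_eigenvector(self):
        # 3-member zero-distance clique plus two outside sequences
        dm = make_distance_matrix(
            "abcde",
            {("a", "b"): 0.0, ("a", "c"): 0.0, ("b", "c"): 0.0,
             ("d", "e"): 1e-30},
            default=1e-10,
        )
        net = to_weights(dm)
        cc = closeness(net)
        ev, _ = eigenvector_centrality(net)
        for x in "bc":
            assert abs(cc[x] - cc["a"]) < 1e-12
            assert abs(ev[x] - ev["a"]) < 1e-12

    def test_betweenness_finite_on_core(self):
        dm = make_distance_matrix(
            "abcd", {("a", "b"): 0.0, ("a", "c"): 0.0, ("b", "c"): 0.0},
            default=1e-5,
        )
        nodes, _ = betweenness(to_weights(dm))
        assert all(np.isfinite(v) for v in nodes.values())


class TestThresholdGraph:
    def test_edge_survival_count(self, dm_factory):
        dm = dm_factory(
            "abcd",
            {("a", "b"): 1e-150, ("a", "c"): 1e-60, ("a", "d"): 1e-10},
            default=1.0,
        )
        doc = threshold_graph(dm, 1e-50)
        assert len(doc.edges) == 2
        assert len(doc.nodes) == 4  # nodes always retained

    def test_zero_threshold_keeps_only_exact_zero_edges(self, dm_factory):
        dm = dm_factory("abc", {("a", "b"): 0.0}, default=1e-10)
        doc = threshold_graph(dm, 0.0)
        assert [(e["source"], e["target"]) for e in doc.edges] == [("a", "b")]

    def test_infinite_threshold_keeps_complete_graph(self, rng):
        dm = random_distance_matrix(rng, 5)
        doc = threshold_graph(dm, np.inf)
        assert len(doc.edges) == 10

    def test_edge_count_monotone_in_threshold(self, rng):
        dm = random_distance_matrix(rng, 6)
        thresholds = [0.0, 1e-100, 1e-80, 1e-50, 1e-20, 1.0]
        counts = [len(threshold_graph(dm, t).edges) for t in thresholds]
        assert counts == sorted(counts)

    def test_centralities_recomputed_per_component(self, dm_factory):
        dm = dm_factory(
            "abcd", {("a", "b"): 1e-80, ("c", "d"): 1e-80}, default=1e-2
        )
        doc = threshold_graph(dm, 1e-50)
        comp = {n["id"]: n["component"] for n in doc.nodes}
        assert comp["a"] == comp["b"] != comp["c"]
        for node in doc.nodes:
            assert node["betweenness"] == 0.0

    def test_pre_threshold_centralities_flag(self, dm_factory):
        dm = dm_factory(
            "abc", {("a", "b"): 1e-80, ("a", "c"): 1e-4, ("b", "c"): 1e-4}
        )
        post = threshold_graph(dm, 1e-50, recompute="post")
        pre = threshold_graph(dm, 1e-50, recompute="pre")
        assert len(post.edges) == len(pre.edges) == 1
        wd_pre = {n["id"]: n["weighted_degree"] for n in pre.nodes}
        wd_post = {n["id"]: n["weighted_degree"] for n in post.nodes}
        assert wd_pre["c"] > wd_post["c"]  # full-graph value retained


class TestMstCentralityGraph:
    def test_tree_structure_and_leaf_betweenness(self, dm_factory):
        dm = dm_factory(
            "abc", {("a", "b"): 1e-9, ("b", "c"): 1e-9}, default=1e-3
        )
        doc = mst_centrality_graph(dm)
        assert len(doc.edges) == 2
        bt = {n["id"]: n["betweenness"] for n in doc.nodes}
        assert bt["a"] == bt["c"] == 0.0
        assert bt["b"] == pytest.approx(1.0)

    def test_star_tree_center(self, dm_factory):
        dm = dm_factory(
            "cpqr",
            {("c", "p"): 1e-9, ("c", "q"): 1e-9, ("c", "r"): 1e-9},
            default=1e-3,
        )
        doc = mst_centrality_graph(dm)
        bt = {n["id"]: n["betweenness"] for n in doc.nodes}
        assert bt["c"] == pytest.approx(3.0)

    def test_tree_values_match_oracle(self, rng):
        dm = random_distance_matrix(rng, 6)
        doc = mst_centrality_graph(dm)
        net_lengths = np.power(dm.values, 0.01) + 1e-200
        np.fill_diagonal(net_lengths, 0.0)
        idx = dm.index
        edges = {}
        for e in doc.edges:
            i, j = idx[e["source"]], idx[e["target"]]
            key = (i, j) if i < j else (j, i)
            edges[key] = net_lengths[key[0], key[1]]
        exp_nodes, _ = brute_betweenness(6, edges)
        bt = {n["id"]: n["betweenness"] for n in doc.nodes}
        for i, u in enumerate(dm.ids):
            assert bt[u] == pytest.approx(exp_nodes[i], abs=1e-9)


class TestDistanceWeightTransformEstimator:
    def test_transform_matches_to_weights(self, rng):
        dm = random_distance_matrix(rng, 5)
        est = DistanceWeightTransform().fit(dm)
        assert np.array_equal(est.transform(dm), to_weights(dm).weights)

    def test_pipeline_compatible(self, rng):
        from sklearn.pipeline import Pipeline

        dm = random_distance_matrix(rng, 4)
        pipe = Pipeline([("weights", DistanceWeightTransform())])
        w = pipe.fit_transform(dm.values)
        assert w.shape == (4, 4)
        assert np.all(np.diag(w) == 0)

    def test_invalid_params_raise_on_fit(self):
        with pytest.raises(ValueError):
            DistanceWeightTransform(q=-1).fit(np.zeros((2, 2)))
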