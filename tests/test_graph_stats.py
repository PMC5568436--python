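"""Network statistics against closed forms and brute-force oracles."""

import itertools
import math

import pytest

from sannet.fixtures import FixtureSpec, generate_corpus, generate_reference_graph
from sannet.graph_stats import (
    average_degree,
    characteristic_path_length,
    clustering_coefficient,
    diameter,
    hubs,
    node_edge_ratio,
    relation_frequencies,
    summarize,
    track_longitudinal,
)
from sannet.network_builder import SAN, build_san, components

from conftest import make_annotated


# ---------------------------------------------------------------- oracles
def adjacency(san):
    adj = {n: set() for n in san.nodes}
    for g, d in san.edges:
        adj[g].add(d)
        adj[d].add(g)
    return adj


def brute_clustering(san):
    """Triangle counting: linked neighbor pairs / possible pairs, per node."""
    adj = adjacency(san)
    total = 0.0
    for node, neigh in adj.items():
        k = len(neigh)
        if k < 2:
            continue
        linked = sum(
            1 for a, b in itertools.combinations(sorted(neigh), 2) if b in adj[a]
        )
        total += linked / (k * (k - 1) / 2)
    return total / len(adj)


def floyd_warshall(san):
    nodes = sorted(san.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    dist = [[math.inf] * n for _ in range(n)]
    for i in range(n):
        dist[i][i] = 0
    for g, d in san.edges:
        dist[idx[g]][idx[d]] = 1
        dist[idx[d]][idx[g]] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    return dist


def brute_path_stats(san):
    dist = floyd_warshall(san)
    n = len(dist)
    pair_dists = [dist[i][j] for i in range(n) for j in range(i + 1, n)]
    assert all(d < math.inf for d in pair_dists)
    return sum(pair_dists) / len(pair_dists), int(max(pair_dists))


def giant(san):
    return components(san)[0]


# ---------------------------------------------------------------- closed forms
class TestClosedForms:
    def test_any_tree_has_zero_clustering(self):
        for seed in (0, 1, 2):
            tree = generate_reference_graph("tree", 12, seed=seed)
            assert tree.n_edges() == 11
            assert clustering_coefficient(tree) == 0.0

    def test_triangle_clustering_is_one(self):
        assert clustering_coefficient(generate_reference_graph("complete", 3)) == 1.0

    def test_complete_graph_l_is_one_and_diameter_one(self):
        k5 = generate_reference_graph("complete", 5)
        assert characteristic_path_length(giant(k5)) == 1.0
        assert diameter(giant(k5)) == 1

    def test_path_graph_closed_form(self):
        p3 = generate_reference_graph("path", 3)
        assert characteristic_path_length(giant(p3)) == pytest.approx(4 / 3)
        p5 = generate_reference_graph("path", 5)
        assert diameter(giant(p5)) == 4

    def test_star_with_three_leaves(self):
        star = generate_reference_graph("star", 4)
        assert characteristic_path_length(giant(star)) == pytest.approx(1.5)

    def test_disconnected_graph_refused_with_guidance(self, six_utterances):
        san = build_san(six_utterances)
        with pytest.raises(ValueError, match="giant"):
            characteristic_path_length(san)
        with pytest.raises(ValueError, match="giant"):
            diameter(san)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_random_graphs_match_brute_force(self, seed):
        san = generate_reference_graph("random", 25 + (seed % 12), seed=seed)
        assert clustering_coefficient(san) == pytest.approx(
            brute_clustering(san), abs=1e-12
        )
        g = giant(san)
        sub = SAN()
        for n in g.member_nodes:
            sub.upsert_node(n)
        for (a, b), e in g.induced_edges().items():
            for label, c in e.labels.items():
                sub.upsert_edge(a, b, label, count=c)
        l_oracle, d_oracle = brute_path_stats(sub)
        assert characteristic_path_length(g) == pytest.approx(l_oracle, abs=1e-12)
        assert diameter(g) == d_oracle


class TestScalarStats:
    @pytest.mark.parametrize(
        "n,e,expected",
        [(38, 41, 2.158), (12, 11, 1.833), (29, 28, 1.931)],
    )
    def test_average_degree_reference_values(self, n, e, expected):
        assert round(average_degree(n, e), 3) == expected

    def test_average_degree_zero_edges(self):
        assert average_degree(10, 0) == 0.0

    @pytest.mark.parametrize(
        "n,e,expected",
        [(38, 41, 0.926829), (287, 583, 0.492281), (7, 7, 1.0)],
    )
    def test_node_edge_ratio_reference_values(self, n, e, expected):
        assert abs(node_edge_ratio(n, e) - expected) < 1e-6

    def test_zero_edge_ratio_reported_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            node_edge_ratio(5, 0)


class TestSummarize:
    def test_triangle_summary(self):
        stats = summarize(generate_reference_graph("complete", 3))
        assert (stats.n_nodes, stats.n_edges) == (3, 3)
        assert stats.clustering_C == 1.0
        assert stats.path_length_L == 1.0
        assert stats.diameter == 1
        assert stats.avg_degree_k == pytest.approx(2.0)
        assert stats.node_edge_ratio == pytest.approx(1.0)

    def test_tree_summary_has_zero_clustering(self):
        stats = summarize(generate_reference_graph("tree", 12, seed=1))
        assert (stats.n_nodes, stats.n_edges) == (12, 11)
        assert stats.clustering_C == 0.0
        assert not stats.small_world

    def test_fields_agree_with_standalone_operations(self):
        _, anns = generate_corpus(FixtureSpec(n_utterances=80, seed=21))
        san = build_san(anns)
        g = giant(san)
        stats = summarize(san, scope="giant")
        assert stats.n_nodes == g.n_nodes
        assert stats.n_edges == g.n_edges("pair")
        assert stats.clustering_C == pytest.approx(clustering_coefficient(g))
        assert stats.path_length_L == pytest.approx(characteristic_path_length(g))
        assert stats.diameter == diameter(g)
        assert stats.avg_degree_k == pytest.approx(
            average_degree(g.n_nodes, g.n_edges("pair"))
        )
        # internal consistency identities
        assert stats.avg_degree_k * stats.n_nodes == pytest.approx(
            2 * stats.n_edges, abs=1e-9
        )
        assert stats.node_edge_ratio * stats.n_edges == pytest.approx(
            stats.n_nodes, abs=1e-9
        )
        assert stats.diameter >= math.ceil(stats.path_length_L)

    def test_whole_scope_counts_whole_graph(self, six_utterances):
        san = build_san(six_utterances)
        whole = summarize(san, scope="whole")
        assert whole.n_nodes == 8 and whole.n_edges == 5
        giant_stats = summarize(san, scope="giant")
        assert giant_stats.n_nodes == 4

    def test_small_world_flag_separates_lattice_from_rewired_graph(self):
        import networkx as nx

        # pure ring lattice: clustered but path length grows with N -> not flagged
        lattice = generate_reference_graph("ring_lattice", 60)
        lattice_stats = summarize(lattice)
        assert lattice_stats.clustering_C == pytest.approx(0.5)
        assert not lattice_stats.small_world
        # a few rewired shortcuts shrink L while keeping C high -> flagged
        ws = nx.connected_watts_strogatz_graph(100, 6, 0.1, seed=2)
        san = SAN()
        for u, v in ws.edges():
            san.upsert_edge(f"w{u:03d}", f"w{v:03d}", "object")
        assert summarize(san).small_world

    def test_empty_san_is_an_error(self):
        with pytest.raises(ValueError):
            summarize(SAN())


class TestRelationFrequencies:
    def test_token_counts_every_arc(self, six_utterances):
        san = build_san(six_utterances)
        table = relation_frequencies(san=san, annotations=six_utterances, mode="token")
        assert table.rows == {"modifier": 4, "object": 2, "subject": 1}
        assert table.total() == sum(len(a.non_root_arcs) for a in six_utterances)

    def test_type_counts_distinct_triples(self, six_utterances):
        san = build_san(six_utterances)
        table = relation_frequencies(san=san, mode="type")
        assert table.rows == {"modifier": 2, "object": 2, "subject": 1}

    def test_same_arc_twice_token_vs_type(self, an_apple):
        san = build_san([an_apple, an_apple])
        token = relation_frequencies(
            san=san, annotations=[an_apple, an_apple], mode="token"
        )
        typ = relation_frequencies(san=san, mode="type")
        assert token.rows == {"modifier": 2}
        assert typ.rows == {"modifier": 1}

    def test_token_conservation_on_synthetic_corpus(self):
        _, anns = generate_corpus(FixtureSpec(n_utterances=50, seed=33))
        table = relation_frequencies(annotations=anns, mode="token")
        assert table.total() == sum(len(a.non_root_arcs) for a in anns)


class TestHubs:
    def test_star_center_degree(self):
        star = generate_reference_graph("star", 6)
        table = hubs(star, min_degree=1)
        assert table.rows[0][1] == 5
        assert all(deg == 1 for _, deg in table.rows[1:])

    def test_empty_san_gives_empty_table(self):
        assert hubs(SAN(), min_degree=1).rows == ()

    def test_labeled_mode_counts_parallel_relations(self):
        san = SAN()
        san.upsert_edge("is", "it", "subject")
        san.upsert_edge("is", "it", "object")
        assert hubs(san, 1, mode="labeled").rows[0] == ("is", 2)
        assert hubs(san, 1, mode="simple").rows[0] == ("is", 1)

    def test_sorted_desc_then_alphabetical_and_cutoff(self, six_utterances):
        san = build_san(six_utterances)
        table = hubs(san, min_degree=2)
        degrees = [d for _, d in table.rows]
        assert degrees == sorted(degrees, reverse=True)
        assert all(d >= 2 for d in degrees)
        by_oracle = {
            f: sum(len(set(e.labels)) for (g, d), e in san.edges.items() if f in (g, d))
            for f in san.nodes
        }
        for form, deg in table.rows:
            assert by_oracle[form] == deg
        ties = [f for f, d in table.rows if d == degrees[0]]
        assert ties == sorted(ties)


class TestLongitudinal:
    def test_degree_rows_across_sessions(self, an_apple, six_utterances):
        a = build_san([an_apple])
        b = build_san(six_utterances)
        report = track_longitudinal([("t1", a), ("t2", b)])
        assert report.degrees.loc["an"].tolist() == [1, 2]
        assert report.degrees.loc["doggie"].tolist() == [0, 2]

    def test_appearing_label_flagged(self, an_apple, six_utterances):
        a = build_san([an_apple])  # only "modifier"
        b = build_san(six_utterances)  # adds subject/object
        report = track_longitudinal([("t1", a), ("t2", b)])
        assert "subject" in report.appeared_labels
        assert "modifier" not in report.appeared_labels

    def test_permuting_sessions_permutes_columns_only(self, an_apple, six_utterances):
        a = build_san([an_apple])
        b = build_san(six_utterances)
        fwd = track_longitudinal([("t1", a), ("t2", b)])
        rev = track_longitudinal([("t2", b), ("t1", a)])
        assert fwd.degrees["t1"].equals(rev.degrees["t1"])
        assert fwd.degrees["t2"].equals(rev.degrees["t2"])

    def test_fewer_than_two_sessions_is_error(self, an_apple):
        with pytest.raises(ValueError):
            track_longitudinal([("t1", build_san([an_apple]))])
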