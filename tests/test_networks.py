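"""Daily graphs and the two node metrics, against independent oracles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from wardsense.errors import ValidationError
from wardsense.networks import (
    DailyGraph,
    build_daily_graph,
    clustering_coefficients,
    daily_graphs_from_events,
    eigenvector_centrality,
    node_metrics,
)


def graph_from_weights(edges) -> DailyGraph:
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, weight=w, minutes=10 ** w)
    return DailyGraph(day="2024-01-08", graph=g)


def _events(rows):
    return pd.DataFrame(rows, columns=["day", "a", "b", "start", "end", "duration_s"])


# -- graph construction ------------------------------------------------------


@pytest.mark.parametrize(
    "minutes, has_edge, weight",
    [(9.0, False, None), (10.0, False, None), (100.0, True, 2.0)],
)
def test_edge_rule_requires_strictly_more_than_ten_minutes(minutes, has_edge, weight):
    ev = _events([("2024-01-08", "A", "B", 0, minutes * 60, minutes * 60)])
    dg = build_daily_graph(ev, ["A", "B", "C"])
    assert dg.graph.has_edge("A", "B") == has_edge
    if has_edge:
        assert dg.graph["A"]["B"]["weight"] == pytest.approx(weight)


def test_dyadic_durations_sum_across_the_day():
    ev = _events(
        [
            ("2024-01-08", "A", "B", 0, 360, 360),
            ("2024-01-08", "A", "B", 1000, 1360, 360),
        ]
    )
    dg = build_daily_graph(ev, ["A", "B"])
    assert dg.graph.has_edge("A", "B")  # 12 min total, each piece only 6
    assert dg.graph["A"]["B"]["minutes"] == pytest.approx(12.0)


def test_no_events_gives_edgeless_graph_over_active_roster():
    dg = build_daily_graph(_events([]), ["A", "B", "C"], day="2024-01-08")
    assert sorted(dg.graph.nodes) == ["A", "B", "C"] and dg.graph.number_of_edges() == 0
    assert eigenvector_centrality(dg) == {"A": 0.0, "B": 0.0, "C": 0.0}
    assert clustering_coefficients(dg) == {"A": 0.0, "B": 0.0, "C": 0.0}


def test_event_participant_missing_from_active_roster_raises():
    ev = _events([("2024-01-08", "A", "Z", 0, 6000, 6000)])
    with pytest.raises(ValidationError, match="Z"):
        build_daily_graph(ev, ["A", "B"])


# -- analytic fixtures -------------------------------------------------------


def test_two_node_centrality_is_symmetric():
    c = eigenvector_centrality(graph_from_weights([("A", "B", 1.5)]))
    assert c["A"] == pytest.approx(1 / np.sqrt(2), abs=1e-10)
    assert c["B"] == pytest.approx(1 / np.sqrt(2), abs=1e-10)


def test_equal_triangle_centrality_and_clustering():
    dg = graph_from_weights([("A", "B", 2.0), ("B", "C", 2.0), ("A", "C", 2.0)])
    c = eigenvector_centrality(dg)
    for v in "ABC":
        assert c[v] == pytest.approx(1 / np.sqrt(3), abs=1e-10)
    assert clustering_coefficients(dg) == pytest.approx({v: 1.0 for v in "ABC"})


def test_path_centrality():
    c = eigenvector_centrality(graph_from_weights([("A", "B", 1.0), ("B", "C", 1.0)]))
    assert c["A"] == pytest.approx(0.5, abs=1e-8)
    assert c["B"] == pytest.approx(1 / np.sqrt(2), abs=1e-8)
    assert c["C"] == pytest.approx(0.5, abs=1e-8)


def test_star_hub_has_zero_clustering():
    dg = graph_from_weights([("H", f"L{i}", 1.0) for i in range(5)])
    assert clustering_coefficients(dg)["H"] == 0.0


def test_unequal_triangle_clustering():
    # raw weights (1, 1, 0.5); node A holds both weight-1 edges
    dg = graph_from_weights([("A", "B", 1.0), ("A", "C", 1.0), ("B", "C", 0.5)])
    c = clustering_coefficients(dg)
    # every node sits in the same (single) triangle: product 1 * 1 * 0.5
    assert c["A"] == pytest.approx(0.5 ** (1 / 3), abs=1e-12)  # ~0.7937
    assert c["B"] == pytest.approx(0.5 ** (1 / 3), abs=1e-12)
    assert c["C"] == pytest.approx(0.5 ** (1 / 3), abs=1e-12)


# -- oracles & properties ----------------------------------------------------


def _random_daily_graph(rng, n_max=12):
    n = rng.integers(2, n_max + 1)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < 0.4:
            g.add_edge(i, j, weight=float(rng.uniform(0.05, 3.0)))
    return DailyGraph(day="d", graph=g)


def brute_force_clustering(dg: DailyGraph) -> dict:
    """Exhaustive ordered-triple enumeration of the weighted clustering."""
    nodes = dg.nodes
    w = dg.normalized_adjacency()
    out = {}
    for i, v in enumerate(nodes):
        nbrs = [j for j in range(len(nodes)) if w[i, j] > 0]
        if len(nbrs) < 2:
            out[v] = 0.0
            continue
        s = sum(
            (w[i, j] * w[i, k] * w[j, k]) ** (1 / 3)
            for j in nbrs
            for k in nbrs
            if j != k
        )
        out[v] = s / (len(nbrs) * (len(nbrs) - 1))
    return out


def test_metrics_match_dense_oracles_on_random_graphs(rng):
    for _ in range(100):
        dg = _random_daily_graph(rng)
        a = dg.adjacency()
        cent = eigenvector_centrality(dg)
        vals, vecs = np.linalg.eigh(a)
        lead = np.abs(vecs[:, np.argmax(vals)])
        # compare only on connected leading structure: both unit-norm, abs
        got = np.array([cent[v] for v in dg.nodes])
        if a.any():
            assert np.abs(got - lead).max() < 1e-7
        clus = clustering_coefficients(dg)
        brute = brute_force_clustering(dg)
        for v in dg.nodes:
            assert clus[v] == pytest.approx(brute[v], abs=1e-12)
            assert 0.0 <= clus[v] <= 1.0


def test_clustering_matches_networkx_reference(rng):
    """Cross-check against the independent library implementation."""
    for _ in range(20):
        dg = _random_daily_graph(rng)
        ours = clustering_coefficients(dg)
        ref = nx.clustering(dg.graph, weight="weight")
        for v in dg.nodes:
            assert ours[v] == pytest.approx(ref[v], abs=1e-10)


def test_centrality_matches_networkx_reference(rng):
    for _ in range(20):
        dg = _random_daily_graph(rng)
        if len(dg.nodes) < 4 or not nx.is_connected(dg.graph):
            continue
        ours = eigenvector_centrality(dg)
        ref = nx.eigenvector_centrality_numpy(dg.graph, weight="weight")
        norm = np.sqrt(sum(v * v for v in ref.values()))
        for v in dg.nodes:
            assert ours[v] == pytest.approx(abs(ref[v]) / norm, abs=1e-7)


def test_permutation_equivariance(rng):
    dg = _random_daily_graph(rng, n_max=8)
    perm = {v: f"n{v}" for v in rng.permutation(dg.nodes)}
    relabelled = DailyGraph(day="d", graph=nx.relabel_nodes(dg.graph, perm))
    for fn in (eigenvector_centrality, clustering_coefficients):
        orig, new = fn(dg), fn(relabelled)
        for v in dg.nodes:
            assert new[perm[v]] == pytest.approx(orig[v], abs=1e-9)


def test_clustering_invariant_to_weight_rescaling(rng):
    dg = _random_daily_graph(rng, n_max=9)
    scaled = nx.Graph()
    scaled.add_nodes_from(dg.graph.nodes)
    for a, b, d in dg.graph.edges(data=True):
        scaled.add_edge(a, b, weight=d["weight"] * 7.3)
    c1 = clustering_coefficients(dg)
    c2 = clustering_coefficients(DailyGraph(day="d", graph=scaled))
    for v in dg.nodes:
        assert c1[v] == pytest.approx(c2[v], abs=1e-12)


def test_metrics_and_graph_tables(small_logs):
    from wardsense.ingest import active_time_table, filter_records
    from wardsense.interactions import reconstruct_interactions

    schedule, detections, battery = small_logs
    filtered, _ = filter_records(detections)
    events = reconstruct_interactions(filtered)
    active = active_time_table(battery)
    graphs = daily_graphs_from_events(events, active)
    assert len(graphs) == len(active["day"].unique())
    m = node_metrics(graphs[0])
    assert set(m.columns) == {"participant", "day", "eigenvector_centrality", "clustering", "degree"}
    omit = daily_graphs_from_events(events, active, omit_staff=True, roster=schedule.roster)
    assert all(v.startswith("P") for g in omit for v in g.graph.nodes)
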