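"""Reply-graph construction, degrees, shares, snapshots and ego networks."""

from collections import Counter
from datetime import datetime

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import random_digraph
from ohcnet.network import (
    DegreeSummary,
    build_reply_graph,
    degree_shares,
    degree_summary,
    ego_network,
    read_edgelist_csv,
    read_graphml,
    write_edgelist_csv,
    write_graphml,
    yearly_snapshots,
)
from ohcnet.synth import ForumDataset, PostRecord


def _post(pid, tid, author, is_root=False, ts=datetime(2019, 6, 1)):
    return PostRecord(
        post_id=pid,
        thread_id=tid,
        author_id=author,
        timestamp=ts,
        is_thread_root=is_root,
        n_reads=10 if is_root else None,
        n_replies=None,
        tokens=(),
    )


def _dataset(posts):
    return ForumDataset(forum_name="t", posts=posts, users=[])


def test_single_edge_accumulates_weight():
    posts = [_post("p0", "t1", "U1", is_root=True)] + [
        _post(f"p{i}", "t1", "U2") for i in range(1, 4)
    ]
    g = build_reply_graph(_dataset(posts))
    assert list(g.edges) == [("U2", "U1")]
    assert g["U2"]["U1"]["weight"] == 3
    assert len(g["U2"]["U1"]["timestamps"]) == 3


def test_self_reply_gives_node_but_no_edge():
    posts = [_post("p0", "t1", "U1", is_root=True), _post("p1", "t1", "U1")]
    g = build_reply_graph(_dataset(posts))
    assert g.number_of_edges() == 0
    assert "U1" in g


def test_orphan_reply_reported_not_dropped():
    posts = [_post("p0", "t1", "U1", is_root=True), _post("p1", "tX", "U2")]
    g = build_reply_graph(_dataset(posts))
    assert g.graph["rejects"] == ["p1"]
    assert g.number_of_edges() == 0


def test_direction_switch_transposes_edges():
    posts = [_post("p0", "t1", "U1", is_root=True), _post("p1", "t1", "U2")]
    fwd = build_reply_graph(_dataset(posts))
    rev = build_reply_graph(_dataset(posts), direction="author_to_replier")
    assert list(fwd.edges) == [("U2", "U1")]
    assert list(rev.edges) == [("U1", "U2")]


def test_edge_multiset_matches_brute_force(small_forum):
    g = build_reply_graph(small_forum)
    root_author = {p.thread_id: p.author_id for p in small_forum.thread_roots()}
    expected = Counter(
        (p.author_id, root_author[p.thread_id])
        for p in small_forum.replies()
        if root_author[p.thread_id] != p.author_id
    )
    got = {(u, v): d["weight"] for u, v, d in g.edges(data=True)}
    assert got == dict(expected)
    # total edge weight equals number of non-self replies
    assert sum(got.values()) == sum(expected.values())


def test_degree_summary_trivial():
    g = nx.DiGraph()
    g.add_edge("A", "B")
    s = degree_summary(g).frame
    assert tuple(s.loc["A"]) == (0, 1, 1)
    assert tuple(s.loc["B"]) == (1, 0, 1)


def test_degree_summary_complete_digraph():
    g = nx.complete_graph(3, nx.DiGraph)
    s = degree_summary(g).frame
    assert (s["total_degree"] == 4).all()


def test_degree_summary_matches_adjacency_sums():
    g = random_digraph(50, 0.1, seed=5)
    a = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
    s = degree_summary(g).frame.loc[sorted(g.nodes)]
    assert np.array_equal(s["out_degree"].to_numpy(), a.sum(axis=1).astype(int))
    assert np.array_equal(s["in_degree"].to_numpy(), a.sum(axis=0).astype(int))
    # handshake identity
    assert s["in_degree"].sum() == s["out_degree"].sum() == g.number_of_edges()


def _summary_from_degrees(degrees):
    frame = pd.DataFrame(
        {
            "in_degree": degrees,
            "out_degree": [0] * len(degrees),
            "total_degree": degrees,
        },
        index=pd.Index([f"u{i}" for i in range(len(degrees))], name="user_id"),
    )
    return DegreeSummary(frame)


def test_degree_shares_rounding():
    degrees = [1] * 8968 + [2] * (22610 - 8968)
    shares = degree_shares(_summary_from_degrees(degrees))
    assert shares["exact"] == 39.7


def test_degree_shares_all_zero():
    shares = degree_shares(_summary_from_degrees([0, 0, 0]))
    assert shares["exact"] == 0.0
    assert shares["low"] == 100.0


def test_yearly_snapshots_single_year_equals_full_graph(small_forum):
    one_year = [p for p in small_forum.posts if p.timestamp.year == 2019]
    roots = {p.thread_id for p in one_year if p.is_thread_root}
    posts = [p for p in one_year if p.is_thread_root or p.thread_id in roots]
    ds = ForumDataset("t", posts, [])
    snaps, evo = yearly_snapshots(ds)
    assert [y for y, _ in snaps] == [2019]
    full = build_reply_graph(ds)
    g2019 = snaps[0][1]
    assert set(g2019.nodes) == set(full.nodes)
    assert set(g2019.edges) == set(full.edges)


def test_snapshot_node_union_covers_full_graph(small_forum):
    snaps, _ = yearly_snapshots(small_forum)
    union = set()
    for _, g in snaps:
        union |= set(g.nodes)
    assert union == set(build_reply_graph(small_forum).nodes)


def test_evolution_ratio_published_counts():
    counts = pd.DataFrame(
        {"n_active_nodes": [4510, 943], "n_active_edges": [55741, 2731]},
        index=pd.Index([2015, 2019], name="year"),
    )
    from ohcnet.network import EvolutionSummary

    evo = EvolutionSummary(counts)
    assert evo.ratio_percent(2019, 2015, "n_active_nodes") == 21
    assert evo.ratio_percent(2019, 2015, "n_active_edges") == 5


class TestEgoNetwork:
    def test_star_center_is_whole_star(self):
        g = nx.star_graph(5)
        ego = ego_network(g, 0)
        assert set(ego.nodes) == set(g.nodes)

    def test_star_leaf(self):
        g = nx.star_graph(5)
        ego = ego_network(g, 3)
        assert set(ego.nodes) == {0, 3}
        assert ego.number_of_edges() == 1

    def test_absent_node(self):
        with pytest.raises(KeyError, match="nope"):
            ego_network(nx.path_graph(3), "nope")

    def test_matches_brute_force_neighborhood(self):
        g = random_digraph(40, 0.08, seed=9)
        focal = 7
        nbrs = {focal} | set(g.successors(focal)) | set(g.predecessors(focal))
        ego = ego_network(g, focal)
        assert set(ego.nodes) == nbrs
        expected_edges = {
            (u, v) for u, v in g.edges if u in nbrs and v in nbrs
        }
        assert set(ego.edges) == expected_edges


def test_graphml_and_edgelist_round_trip(tmp_path, small_forum):
    g = build_reply_graph(small_forum)
    p1 = tmp_path / "g.graphml"
    write_graphml(g, p1)
    g2 = read_graphml(p1)
    assert set(g2.edges) == set(g.edges)
    u, v = next(iter(g.edges))
    assert g2[u][v]["weight"] == g[u][v]["weight"]
    assert g2[u][v]["timestamps"] == g[u][v]["timestamps"]

    p2 = tmp_path / "g.csv"
    write_edgelist_csv(g, p2)
    g3 = read_edgelist_csv(p2)
    assert {(u, v): d["weight"] for u, v, d in g3.edges(data=True)} == {
        (u, v): d["weight"] for u, v, d in g.edges(data=True)
    }
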