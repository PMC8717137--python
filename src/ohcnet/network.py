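"""Directed user-reply network construction and degree summaries.

Nodes are forum users; an edge u -> v means user u replied (at least once)
to a thread authored by v.  Replies to one's own thread contribute no edge.
Edge direction is configurable (default replier -> thread author); direction
affects in/out splits but not total degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import networkx as nx
import pandas as pd

from ._util import round_half_up
from .synth import ForumDataset, PostRecord

__all__ = [
    "build_reply_graph",
    "degree_summary",
    "degree_shares",
    "yearly_snapshots",
    "ego_network",
    "write_graphml",
    "read_graphml",
    "write_edgelist_csv",
    "read_edgelist_csv",
    "DegreeSummary",
    "EvolutionSummary",
]


@dataclass
class DegreeSummary:
    """Per-user (in, out, total) degrees over distinct neighbors per direction."""

    frame: pd.DataFrame  # index user_id; columns in_degree, out_degree, total_degree

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class EvolutionSummary:
    """Active node/edge counts per calendar year and later/earlier ratios."""

    counts: pd.DataFrame  # index year; columns n_active_nodes, n_active_edges

    def ratio_percent(self, later: int, earlier: int, what: str = "n_active_nodes") -> int:
        """later-year count as a percent of the earlier-year count (nearest integer)."""
        num = float(self.counts.loc[later, what])
        den = float(self.counts.loc[earlier, what])
        if den == 0:
            raise ZeroDivisionError(f"{what} is zero in {earlier}")
        return int(round_half_up(100.0 * num / den, 0))


def build_reply_graph(
    dataset: ForumDataset,
    window: tuple[datetime, datetime] | None = None,
    direction: str = "replier_to_author",
) -> nx.DiGraph:
    """Build the weighted directed reply graph from a ForumDataset.

    One edge per ordered (replier, root author) pair, weighted by the number
    of replies in the window and carrying the reply timestamps.  Self-replies
    are dropped (the user still becomes a node).  Replies referencing a
    missing root are collected in ``G.graph['rejects']`` rather than silently
    discarded.
    """
    if direction not in ("replier_to_author", "author_to_replier"):
        raise ValueError(f"unknown direction: {direction!r}")
    in_window = _window_predicate(window)
    root_author = {
        p.thread_id: p.author_id for p in dataset.posts if p.is_thread_root
    }
    g = nx.DiGraph(forum=dataset.forum_name)
    rejects: list[str] = []
    for p in dataset.posts:
        if not in_window(p):
            continue
        g.add_node(p.author_id)
        if p.is_thread_root:
            continue
        target = root_author.get(p.thread_id)
        if target is None:
            rejects.append(p.post_id)
            continue
        if target == p.author_id:
            continue
        src, dst = p.author_id, target
        if direction == "author_to_replier":
            src, dst = dst, src
        if g.has_edge(src, dst):
            g[src][dst]["weight"] += 1
            g[src][dst]["timestamps"].append(p.timestamp)
        else:
            g.add_edge(src, dst, weight=1, timestamps=[p.timestamp])
    g.graph["rejects"] = rejects
    return g


def _window_predicate(window):
    if window is None:
        return lambda p: True
    start, end = window
    return lambda p: start <= p.timestamp < end


def degree_summary(graph: nx.DiGraph) -> DegreeSummary:
    """In/out/total degrees per node; total = in + out over distinct neighbors."""
    nodes = list(graph.nodes)
    indeg = dict(graph.in_degree())
    outdeg = dict(graph.out_degree())
    frame = pd.DataFrame(
        {
            "in_degree": [indeg[n] for n in nodes],
            "out_degree": [outdeg[n] for n in nodes],
        },
        index=pd.Index(nodes, name="user_id"),
    )
    frame["total_degree"] = frame["in_degree"] + frame["out_degree"]
    return DegreeSummary(frame)


def degree_shares(
    summary: DegreeSummary,
    exact: int = 1,
    high: int = 100,
    low: int = 5,
) -> dict[str, float]:
    """Percentage of users at degree == exact, >= high, <= low (1 decimal)."""
    if len(summary) == 0:
        raise ValueError("empty degree summary")
    total = summary.frame["total_degree"]
    n = len(total)
    return {
        "exact": round_half_up(100.0 * (total == exact).sum() / n, 1),
        "high": round_half_up(100.0 * (total >= high).sum() / n, 1),
        "low": round_half_up(100.0 * (total <= low).sum() / n, 1),
    }


def yearly_snapshots(
    dataset: ForumDataset,
    direction: str = "replier_to_author",
) -> tuple[list[tuple[int, nx.DiGraph]], EvolutionSummary]:
    """Per-calendar-year reply graphs plus an activity EvolutionSummary.

    The snapshot for year Y is built from posts timestamped in Y only.  A
    node is counted active in Y if it posted in Y (the default activity
    rule); an edge is active if at least one of its replies fell in Y.
    """
    years = sorted({p.timestamp.year for p in dataset.posts})
    snapshots: list[tuple[int, nx.DiGraph]] = []
    rows = []
    for y in years:
        window = (datetime(y, 1, 1), datetime(y + 1, 1, 1))
        g = build_reply_graph(dataset, window=window, direction=direction)
        snapshots.append((y, g))
        rows.append(
            {
                "year": y,
                "n_active_nodes": g.number_of_nodes(),
                "n_active_edges": g.number_of_edges(),
            }
        )
    counts = pd.DataFrame(rows).set_index("year")
    return snapshots, EvolutionSummary(counts)


def ego_network(graph: nx.Graph, focal, radius: int = 1) -> nx.Graph:
    """Ego plus alters within ``radius`` (either direction), with all edges among them."""
    if focal not in graph:
        raise KeyError(f"node not in graph: {focal!r}")
    undirected = graph.to_undirected(as_view=True)
    nodes = set(nx.single_source_shortest_path_length(undirected, focal, cutoff=radius))
    return graph.subgraph(nodes).copy()


# -- serialization ----------------------------------------------------------

def write_graphml(graph: nx.Graph, path) -> None:
    g = graph.copy()
    for _, _, data in g.edges(data=True):
        if "timestamps" in data:
            data["timestamps"] = "|".join(t.isoformat() for t in data["timestamps"])
    g.graph.pop("rejects", None)
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path)
    for _, _, data in g.edges(data=True):
        if isinstance(data.get("timestamps"), str):
            data["timestamps"] = [
                datetime.fromisoformat(t) for t in data["timestamps"].split("|") if t
            ]
    return g


def write_edgelist_csv(graph: nx.Graph, path) -> None:
    rows = [
        {"source": u, "target": v, "weight": d.get("weight", 1)}
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(path, index=False)


def read_edgelist_csv(path, directed: bool = True) -> nx.Graph:
    frame = pd.read_csv(path)
    g = nx.DiGraph() if directed else nx.Graph()
    for row in frame.itertuples(index=False):
        g.add_edge(row.source, row.target, weight=int(row.weight))
    return g
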