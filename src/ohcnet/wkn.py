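"""Weighted knowledge network (WKN) over extracted key phrases.

Keywords become nodes weighted by their share of keyword occurrences within
the selected phrases, q(k_i) = m(k_i)/M; phrase co-occurrence becomes an
undirected edge weighted by the phrase's share of phrase occurrences,
q(e_ij) = n(e_ij)/N.  Both weight sets normalize to 1 over the selected
phrases.  Keywords can be classified into the eight standard patient-forum
topic categories via a user-supplied lexicon.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import networkx as nx
import pandas as pd

from ._util import round_half_up

__all__ = [
    "TOPIC_CATEGORIES",
    "build_wkn",
    "classify_topics",
    "split_periods",
    "keyword_ego",
    "load_lexicon",
    "write_wkn_graphml",
    "read_wkn_graphml",
    "wkn_tables",
    "compare_periods",
]

TOPIC_CATEGORIES = (
    "etiology and pathological knowledge",
    "diagnosis and examination",
    "treatment",
    "disease management",
    "complications",
    "social life",
    "disease prevention",
    "education and research",
)


def build_wkn(
    phrases,
    period: tuple[datetime, datetime] | None = None,
    forum: str | None = None,
) -> nx.Graph:
    """Build the WKN graph from ranked phrase candidates.

    With n(e_ij) the phrase's occurrence count, N the total occurrences over
    the selected phrases, m(k_i) the keyword's occurrence count within them
    and M the total keyword occurrences, edge weights are n/N and node
    weights m/M; each sums to 1 exactly.
    """
    # self-pairs (x, x) cannot form an edge between distinct keywords and are
    # excluded up front so that both weight sets normalize to 1 exactly
    phrases = [c for c in phrases if c.pair[0] != c.pair[1]]
    if not phrases:
        raise ValueError("empty phrase list")
    n_total = sum(c.frequency for c in phrases)
    m_kw: dict[str, int] = {}
    for c in phrases:
        for w in c.pair:
            m_kw[w] = m_kw.get(w, 0) + c.frequency
    m_total = sum(m_kw.values())  # = 2 * n_total
    g = nx.Graph(forum=forum or "", period=_period_str(period))
    for w, m in m_kw.items():
        g.add_node(w, weight=m / m_total, occurrences=m)
    for c in phrases:
        x, y = c.pair
        if g.has_edge(x, y):
            # the same unordered pair can appear as two ordered phrases
            g[x][y]["weight"] += c.frequency / n_total
            g[x][y]["occurrences"] += c.frequency
        else:
            g.add_edge(x, y, weight=c.frequency / n_total, occurrences=c.frequency)
    return g


def _period_str(period) -> str:
    if period is None:
        return ""
    start, end = period
    return f"{start.isoformat()}/{end.isoformat()}"


def classify_topics(graph: nx.Graph, lexicon: dict) -> pd.DataFrame:
    """Per-category keyword counts and percentage shares (1 decimal).

    Every keyword takes its lexicon category, or "unclassified" when absent;
    shares are percentages of all keywords and sum to 100 up to rounding.
    Also attaches the category as a ``topic`` node attribute.
    """
    if lexicon is None:
        raise ValueError("lexicon must be a mapping (may be empty)")
    bad = {c for c in lexicon.values() if c not in TOPIC_CATEGORIES}
    if bad:
        raise ValueError(f"unknown topic categories in lexicon: {sorted(bad)}")
    counts = {c: 0 for c in TOPIC_CATEGORIES}
    counts["unclassified"] = 0
    for node in graph.nodes:
        cat = lexicon.get(node, "unclassified")
        graph.nodes[node]["topic"] = cat
        counts[cat] += 1
    total = graph.number_of_nodes()
    rows = [
        {
            "category": cat,
            "n_keywords": n,
            "share_percent": round_half_up(100.0 * n / total, 1) if total else 0.0,
        }
        for cat, n in counts.items()
    ]
    return pd.DataFrame(rows).set_index("category")


def split_periods(posts, cut: datetime):
    """Partition posts by timestamp; the boundary instant joins the second period."""
    before = [p for p in posts if p.timestamp < cut]
    after = [p for p in posts if p.timestamp >= cut]
    return before, after


def keyword_ego(graph: nx.Graph, keyword) -> nx.Graph:
    """Ego WKN: the keyword, its direct co-occurrence partners, and all edges
    among them, with parent weights preserved (no renormalization)."""
    if keyword not in graph:
        raise KeyError(f"keyword not in WKN: {keyword!r}")
    nodes = {keyword} | set(graph.neighbors(keyword))
    return graph.subgraph(nodes).copy()


def compare_periods(wkn_before: nx.Graph, wkn_after: nx.Graph) -> pd.DataFrame:
    """Keyword table with per-period node weights and appearance status.

    status is "new" (second period only), "disappeared" (first only) or
    "shared"; a descriptive comparison, no test attached.
    """
    keys = sorted(set(wkn_before.nodes) | set(wkn_after.nodes))
    rows = []
    for k in keys:
        w1 = wkn_before.nodes[k]["weight"] if k in wkn_before else None
        w2 = wkn_after.nodes[k]["weight"] if k in wkn_after else None
        status = "shared" if w1 is not None and w2 is not None else (
            "disappeared" if w2 is None else "new"
        )
        rows.append(
            {"keyword": k, "weight_before": w1, "weight_after": w2, "status": status}
        )
    return pd.DataFrame(rows).set_index("keyword")


def load_lexicon(path) -> dict:
    """Topic lexicon from a 2-column CSV (keyword, category).

    Later duplicates of a keyword are ignored: first match wins, so the file
    order documents the resolution of multi-category keywords.
    """
    frame = pd.read_csv(path)
    if not {"keyword", "category"} <= set(frame.columns):
        raise ValueError("lexicon CSV needs 'keyword' and 'category' columns")
    lex: dict = {}
    for row in frame.itertuples(index=False):
        lex.setdefault(str(row.keyword), str(row.category))
    bad = {c for c in lex.values() if c not in TOPIC_CATEGORIES}
    if bad:
        raise ValueError(f"unknown topic categories in lexicon: {sorted(bad)}")
    return lex


def wkn_tables(graph: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(nodes, edges) CSV-ready tables."""
    nodes = pd.DataFrame(
        {
            "keyword": list(graph.nodes),
            "weight": [graph.nodes[n]["weight"] for n in graph.nodes],
            "occurrences": [graph.nodes[n]["occurrences"] for n in graph.nodes],
            "topic": [graph.nodes[n].get("topic", "") for n in graph.nodes],
        }
    )
    edges = pd.DataFrame(
        {
            "source": [u for u, _ in graph.edges],
            "target": [v for _, v in graph.edges],
            "weight": [graph[u][v]["weight"] for u, v in graph.edges],
            "occurrences": [graph[u][v]["occurrences"] for u, v in graph.edges],
        }
    )
    return nodes, edges


def write_wkn_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_wkn_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
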