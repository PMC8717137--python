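"""Topological network statistics and the small-world coefficient.

Definitions used throughout (on the binary adjacency; edge weights are
ignored):

* local clustering of node k: with n = |union of in- and out-neighbors of k|,
  the number of directed links among those neighbors divided by n(n-1);
  0 by convention when n < 2.  On an undirected graph (symmetric adjacency)
  this reduces to the standard Watts-Strogatz local clustering.
* average path length L: shortest-path distances d_ij with d_ij = 0 when
  i = j or j is unreachable from i; "all_pairs" mode averages over all N(N-1)
  ordered pairs (unreachable pairs contribute 0), "reachable" mode averages
  over finite positive distances only.
* small-world sigma: (C/C_r) / (L/L_r) against Erdos-Renyi equivalents with
  the same node and edge counts, replicated (default 50) with mean and SD
  reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "NetworkMetrics",
    "SmallWorldResult",
    "local_clustering",
    "average_clustering",
    "path_stats",
    "er_equivalent",
    "small_world_sigma",
    "network_metrics",
]


@dataclass(frozen=True)
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_clustering: float
    avg_path_length: float
    diameter: int
    no_paths: bool = False  # True when the graph has no finite positive distance

    def as_dict(self) -> dict:
        return {
            "Number of nodes": self.n_nodes,
            "Number of edges": self.n_edges,
            "Average node degree": self.avg_degree,
            "Network diameter": self.diameter,
            "Average clustering coefficient": self.avg_clustering,
            "Average path length": self.avg_path_length,
        }


@dataclass(frozen=True)
class SmallWorldResult:
    c_obs: float
    l_obs: float
    c_null_mean: float
    l_null_mean: float
    sigma_mean: float
    sigma_sd: float
    sigma_values: tuple[float, ...]
    n_replicates: int
    seed: int | None


def _adjacency(graph: nx.Graph) -> tuple[sp.csr_array, list]:
    nodes = list(graph.nodes)
    a = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight=None, format="csr")
    if not graph.is_directed():
        a = a.maximum(a.T)
    a.setdiag(0)
    a.eliminate_zeros()
    return a.astype(np.int8), nodes


def _local_clustering_all(a: sp.csr_array) -> np.ndarray:
    """Directed local clustering per node from a binary adjacency."""
    n = a.shape[0]
    csc = a.tocsc()
    out = np.zeros(n)
    # dense submatrix lookups are much faster at desk scale
    dense = a.toarray() if n <= 4000 else None
    for k in range(n):
        succ = a.indices[a.indptr[k]:a.indptr[k + 1]]
        pred = csc.indices[csc.indptr[k]:csc.indptr[k + 1]]
        nb = np.union1d(succ, pred)
        nb = nb[nb != k]
        m = nb.size
        if m < 2:
            continue
        if dense is not None:
            links = int(dense[np.ix_(nb, nb)].sum())
        else:
            links = a[nb][:, nb].sum()
        out[k] = links / (m * (m - 1))
    return out


def local_clustering(graph: nx.Graph, node) -> float:
    """Clustering of one node: directed links among its neighbor union / n(n-1)."""
    if node not in graph:
        raise KeyError(f"node not in graph: {node!r}")
    a, nodes = _adjacency(graph)
    k = nodes.index(node)
    succ = a.indices[a.indptr[k]:a.indptr[k + 1]]
    csc = a.tocsc()
    pred = csc.indices[csc.indptr[k]:csc.indptr[k + 1]]
    nb = np.union1d(succ, pred)
    nb = nb[nb != k]
    if nb.size < 2:
        return 0.0
    return float(a[nb][:, nb].sum() / (nb.size * (nb.size - 1)))


def average_clustering(graph: nx.Graph) -> float:
    """Unweighted mean of local clustering over all nodes (degree<2 counts as 0)."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    a, _ = _adjacency(graph)
    return float(_local_clustering_all(a).mean())


def _path_stats_from_adj(a: sp.csr_array, mode: str) -> tuple[float, int, bool]:
    n = a.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    if a.nnz == 0:
        return 0.0, 0, True
    d = shortest_path(a, method="D", directed=True, unweighted=True)
    np.fill_diagonal(d, np.inf)
    finite = np.isfinite(d)
    if not finite.any():
        return 0.0, 0, True
    diameter = int(d[finite].max())
    if mode == "all_pairs":
        l = float(d[finite].sum() / (n * (n - 1)))
    elif mode == "reachable":
        l = float(d[finite].mean())
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return l, diameter, False


def path_stats(graph: nx.Graph, mode: str = "all_pairs") -> tuple[float, int]:
    """(average path length, diameter).

    ``all_pairs`` mode divides the sum of finite shortest-path lengths by
    N(N-1), counting unreachable ordered pairs as 0; ``reachable`` averages
    over finite positive distances only.  A graph with no finite positive
    distance reports (0, 0).
    """
    a, _ = _adjacency(graph)
    l, diameter, _ = _path_stats_from_adj(a, mode)
    return l, diameter


def network_metrics(graph: nx.Graph, mode: str = "all_pairs") -> NetworkMetrics:
    """All Table-style topological metrics of one graph."""
    a, _ = _adjacency(graph)
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    l, diameter, no_paths = _path_stats_from_adj(a, mode)
    c = float(_local_clustering_all(a).mean())
    # average total degree: every edge contributes to two nodes' totals
    avg_degree = 2.0 * m / n
    return NetworkMetrics(
        n_nodes=n,
        n_edges=m,
        avg_degree=avg_degree,
        avg_clustering=c,
        avg_path_length=l,
        diameter=diameter,
        no_paths=no_paths,
    )


def _er_edge_sample(
    n_nodes: int, n_edges: int, directed: bool, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n_edges distinct (no self-loop) edges uniformly at random.

    Equivalent to repeatedly linking a uniformly chosen currently unlinked
    pair until n_edges are placed: both procedures are uniform over
    admissible edge sets.
    """
    if n_nodes <= 0:
        raise ValueError("n_nodes must be > 0")
    max_edges = n_nodes * (n_nodes - 1) if directed else n_nodes * (n_nodes - 1) // 2
    if n_edges < 0 or n_edges > max_edges:
        raise ValueError(
            f"infeasible edge count {n_edges} for {n_nodes} nodes "
            f"({'directed' if directed else 'undirected'} max {max_edges})"
        )
    idx = rng.choice(max_edges, size=n_edges, replace=False)
    if directed:
        src = idx // (n_nodes - 1)
        rem = idx % (n_nodes - 1)
        dst = np.where(rem >= src, rem + 1, rem)
    else:
        # map linear index to upper-triangle (i < j)
        i = (
            n_nodes
            - 2
            - np.floor(
                np.sqrt(-8.0 * idx + 4.0 * n_nodes * (n_nodes - 1) - 7.0) / 2.0 - 0.5
            )
        ).astype(np.int64)
        j = (
            idx
            + i
            + 1
            - (n_nodes * (n_nodes - 1)) // 2
            + ((n_nodes - i) * (n_nodes - i - 1)) // 2
        ).astype(np.int64)
        src, dst = i, j
    return src.astype(np.int64), dst.astype(np.int64)


def _er_sparse(
    n_nodes: int, n_edges: int, directed: bool, rng: np.random.Generator
) -> sp.csr_array:
    src, dst = _er_edge_sample(n_nodes, n_edges, directed, rng)
    data = np.ones(len(src), dtype=np.int8)
    a = sp.csr_array((data, (src, dst)), shape=(n_nodes, n_nodes))
    if not directed:
        a = a.maximum(a.T)
    return a


def er_equivalent(
    n_nodes: int, n_edges: int, directed: bool = True, seed=None
) -> nx.Graph:
    """Erdos-Renyi equivalent: exactly ``n_edges`` distinct random edges, no self-loops."""
    rng = np.random.default_rng(seed)
    src, dst = _er_edge_sample(n_nodes, n_edges, directed, rng)
    g = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(range(n_nodes))
    g.add_edges_from(zip(src.tolist(), dst.tolist()))
    return g


def small_world_sigma(
    graph: nx.Graph,
    n_replicates: int = 50,
    seed=None,
    mode: str = "all_pairs",
) -> SmallWorldResult:
    """Small-world sigma against replicated ER equivalents.

    For each replicate an ER graph with the observed node and edge counts
    (and the observed directedness) is generated; sigma_i =
    (C/C_r_i)/(L/L_r_i) and the mean and SD over replicates are reported.
    Replicates whose null clustering or path length is zero are unusable and
    skipped; if every replicate is unusable a ValueError explains why.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("graph has no edges; sigma undefined")
    a, _ = _adjacency(graph)
    c_obs = float(_local_clustering_all(a).mean())
    l_obs, _, no_paths = _path_stats_from_adj(a, mode)
    if no_paths or l_obs <= 0:
        raise ValueError("observed average path length is zero; sigma undefined")
    n, m = graph.number_of_nodes(), graph.number_of_edges()
    directed = graph.is_directed()
    rng = np.random.default_rng(seed)
    sigmas: list[float] = []
    c_rs: list[float] = []
    l_rs: list[float] = []
    for _ in range(n_replicates):
        null = _er_sparse(n, m, directed, rng)
        c_r = float(_local_clustering_all(null).mean())
        l_r, _, null_no_paths = _path_stats_from_adj(null, mode)
        if c_r <= 0 or null_no_paths or l_r <= 0:
            continue
        c_rs.append(c_r)
        l_rs.append(l_r)
        sigmas.append((c_obs / c_r) / (l_obs / l_r))
    if not sigmas:
        raise ValueError(
            "sigma undefined: every ER replicate had zero clustering or no paths "
            f"(n={n}, m={m}); the graph is too sparse for a meaningful null"
        )
    arr = np.asarray(sigmas)
    return SmallWorldResult(
        c_obs=c_obs,
        l_obs=l_obs,
        c_null_mean=float(np.mean(c_rs)),
        l_null_mean=float(np.mean(l_rs)),
        sigma_mean=float(arr.mean()),
        sigma_sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        sigma_values=tuple(float(s) for s in arr),
        n_replicates=n_replicates,
        seed=seed if isinstance(seed, int) else None,
    )
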