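"""Hubs, shortest-path distributions, betweenness and clustering profiles.

Hierarchy in a reaction network shows up as (i) hub molecules whose degree
dwarfs the average, (ii) short typical path lengths despite the network
size, (iii) betweenness centrality that grows with degree, and (iv) a
degree-dependent local clustering coefficient that decays roughly like
1/k.  The operations here quantify each signature on any of the graph
views (bipartite, molecule, reaction).

Heavy loops run in C: all-source / sampled BFS uses
``scipy.sparse.csgraph`` and betweenness uses igraph (Brandes with an
optional pivot-source subset, rescaled by ``n / n_pivots``).  Exact modes
are auto-selected on small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
from scipy.sparse import csgraph
from scipy.sparse import csr_array

__all__ = [
    "HubCriterion",
    "HubSet",
    "PathLengthDistribution",
    "ClusteringProfile",
    "BetweennessProfile",
    "find_hubs_total",
    "rank_hubs_in_degree",
    "path_length_distribution",
    "clustering",
    "betweenness_by_degree",
]


def _as_nx(graph) -> nx.Graph | nx.DiGraph:
    """Accept a raw networkx graph or any wrapper exposing ``.graph``."""
    return graph if isinstance(graph, (nx.Graph, nx.DiGraph)) else graph.graph


@dataclass(frozen=True)
class HubCriterion:
    d_avg: float
    multiplier: float
    basis: str  # {'total_degree', 'in_degree'}

    @property
    def threshold(self) -> float:
        return self.multiplier * self.d_avg


@dataclass
class HubSet:
    """Hub nodes under a degree threshold, sorted by descending degree."""

    members: list[tuple[str, int]]
    criterion: HubCriterion
    proportion: float
    top_ranked: list[tuple[str, int]] = field(default_factory=list)

    @property
    def ids(self) -> set:
        return {m for m, _ in self.members}


def find_hubs_total(graph, multiplier: float = 100.0) -> HubSet:
    """Molecules whose total (in+out) degree exceeds ``multiplier * d_avg``.

    ``d_avg = 2 |E| / |V|`` on the collapsed molecule graph.  Ties in the
    descending ordering break lexicographically on the node id.
    """
    g = _as_nx(graph)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    d_avg = 2.0 * g.number_of_edges() / n
    crit = HubCriterion(d_avg=d_avg, multiplier=multiplier, basis="total_degree")
    degs = dict(g.degree())
    members = sorted(
        ((node, d) for node, d in degs.items() if d > crit.threshold),
        key=lambda nd: (-nd[1], str(nd[0])),
    )
    return HubSet(members=members, criterion=crit, proportion=len(members) / n)


def rank_hubs_in_degree(graph, multiplier: float = 100.0, top_n: int = 10) -> HubSet:
    """Molecules ranked by in-degree (times formed as product).

    Membership cuts at ``in_degree > multiplier * mean(in_degree)``;
    ``top_ranked`` carries the first ``top_n`` of the full ranking for
    reporting regardless of the cut.
    """
    g = _as_nx(graph)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    indeg = dict(g.in_degree()) if g.is_directed() else dict(g.degree())
    d_avg = sum(indeg.values()) / n
    crit = HubCriterion(d_avg=d_avg, multiplier=multiplier, basis="in_degree")
    ranking = sorted(indeg.items(), key=lambda nd: (-nd[1], str(nd[0])))
    members = [(node, d) for node, d in ranking if d > crit.threshold]
    return HubSet(
        members=members,
        criterion=crit,
        proportion=len(members) / n,
        top_ranked=ranking[:top_n],
    )


# ---------------------------------------------------------------------------
# Shortest paths
# ---------------------------------------------------------------------------


@dataclass
class PathLengthDistribution:
    histogram: dict[int, float]  # distance -> probability mass (finite pairs)
    mean: float
    n_sources_sampled: int
    seed: int
    exact: bool


def _to_csr(g: nx.Graph | nx.DiGraph) -> tuple[csr_array, list]:
    nodes = sorted(g.nodes(), key=str)
    idx = {n: i for i, n in enumerate(nodes)}
    rows, cols = [], []
    for u, v in g.edges():
        rows.append(idx[u])
        cols.append(idx[v])
    data = np.ones(len(rows), dtype=np.int8)
    adj = csr_array((data, (rows, cols)), shape=(len(nodes), len(nodes)))
    return adj, nodes


def path_length_distribution(
    graph,
    n_sources: int = 1000,
    seed: int = 0,
    directed: bool = False,
    exact_threshold: int = 10_000,
) -> PathLengthDistribution:
    """Distribution of finite shortest-path lengths.

    BFS runs from every node when the graph has at most
    ``exact_threshold`` nodes, otherwise from ``n_sources`` uniformly
    sampled sources.  Unreachable pairs and self-pairs carry no mass.
    """
    g = _as_nx(graph)
    if not directed and g.is_directed():
        g = g.to_undirected(as_view=False)
    adj, nodes = _to_csr(g)
    n = len(nodes)
    if n == 0:
        return PathLengthDistribution({}, float("nan"), 0, seed, True)

    exact = n <= exact_threshold or n_sources >= n
    if exact:
        sources = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        sources = np.sort(rng.choice(n, size=n_sources, replace=False))

    counts: dict[int, int] = {}
    chunk = max(1, int(5_000_000 // max(n, 1)))
    for start in range(0, sources.size, chunk):
        block = sources[start : start + chunk]
        dist = csgraph.shortest_path(adj, method="D", directed=directed, unweighted=True, indices=block)
        finite = dist[np.isfinite(dist) & (dist > 0)].astype(np.int64)
        if finite.size:
            binc = np.bincount(finite)
            for d in np.nonzero(binc)[0]:
                counts[int(d)] = counts.get(int(d), 0) + int(binc[d])

    total = sum(counts.values())
    if total == 0:
        return PathLengthDistribution({}, float("nan"), sources.size, seed, exact)
    histogram = {d: c / total for d, c in sorted(counts.items())}
    mean = sum(d * c for d, c in counts.items()) / total
    return PathLengthDistribution(histogram, mean, sources.size, seed, exact)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusteringProfile:
    global_coefficient: float
    global_se: float
    local_by_degree: dict[int, float]
    loglog_slope: float


def _degree_binned_means(degrees: np.ndarray, values: np.ndarray, k_floor: int = 1):
    """Mean of ``values`` per degree: exact bins to 64, log bins above."""
    centers, means = [], []
    mask_small = (degrees <= 64) & (degrees >= k_floor)
    for k in np.unique(degrees[mask_small]):
        sel = degrees == k
        centers.append(float(k))
        means.append(float(values[sel].mean()))
    edge = 64.0
    while edge < degrees.max():
        hi = edge * 1.5
        sel = (degrees > edge) & (degrees <= hi)
        if sel.any():
            centers.append(float(np.sqrt(edge * hi)))
            means.append(float(values[sel].mean()))
        edge = hi
    return np.asarray(centers), np.asarray(means)


def _loglog_slope(centers: np.ndarray, means: np.ndarray) -> float:
    keep = (centers >= 1) & (means > 0)
    if keep.sum() < 2:
        return float("nan")
    return float(np.polyfit(np.log(centers[keep]), np.log(means[keep]), 1)[0])


def clustering(graph) -> ClusteringProfile:
    """Global transitivity with a node-jackknife standard error, plus the
    degree-dependent mean local coefficient and its log-log slope.

    On any bipartite view the global coefficient is exactly zero: the graph
    contains no triangles by construction.
    """
    g = _as_nx(graph)
    if g.is_directed():
        g = g.to_undirected(as_view=False)
    nodes = list(g.nodes())
    n = len(nodes)
    if n == 0:
        return ClusteringProfile(0.0, 0.0, {}, float("nan"))

    tri = nx.triangles(g)
    t = np.asarray([tri[v] for v in nodes], dtype=np.float64)  # triangles at v
    d = np.asarray([g.degree(v) for v in nodes], dtype=np.float64)
    p = d * (d - 1) / 2.0  # triples centred at v
    T, P = t.sum() / 3.0, p.sum()
    global_c = 3.0 * T / P if P > 0 else 0.0

    # jackknife: deleting v removes t_v triangles, its own triples, and one
    # triple at each neighbour u per pair through v, i.e. (d_u - 1) each
    adj = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csr")
    neigh_loss = adj @ (d - 1.0)
    denom = P - p - neigh_loss
    num = 3.0 * (T - t)
    valid = denom > 0
    if valid.sum() >= 2:
        theta = num[valid] / denom[valid]
        m = theta.size
        se = float(np.sqrt((m - 1) / m * np.sum((theta - theta.mean()) ** 2)))
    else:
        se = 0.0

    local = nx.clustering(g)
    lv = np.asarray([local[v] for v in nodes], dtype=np.float64)
    di = d.astype(np.int64)
    by_degree: dict[int, float] = {}
    sel = di >= 2
    for k in np.unique(di[sel]):
        by_degree[int(k)] = float(lv[di == k].mean())
    centers, means = _degree_binned_means(di[sel], lv[sel], k_floor=2)
    slope = _loglog_slope(centers, means)
    return ClusteringProfile(float(global_c), se, by_degree, slope)


# ---------------------------------------------------------------------------
# Betweenness
# ---------------------------------------------------------------------------


@dataclass
class BetweennessProfile:
    per_node: dict
    by_degree: dict[int, float]
    loglog_slope: float
    n_pivots: int
    seed: int
    exact: bool


def betweenness_by_degree(
    graph,
    n_pivots: int = 1000,
    seed: int = 0,
    exact_threshold: int = 5000,
) -> BetweennessProfile:
    """Shortest-path betweenness, exact or pivot-sampled, binned by degree.

    Pivot sampling computes Brandes dependencies from ``n_pivots`` random
    source nodes and rescales by ``n / n_pivots``; graphs at or below
    ``exact_threshold`` nodes are computed exactly.
    """
    g = _as_nx(graph)
    if g.is_directed():
        g = g.to_undirected(as_view=False)
    nodes = sorted(g.nodes(), key=str)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty graph")
    idx = {v: i for i, v in enumerate(nodes)}
    h = ig.Graph(n, [(idx[u], idx[v]) for u, v in g.edges()], directed=False)

    exact = n <= exact_threshold or n_pivots >= n
    if exact:
        bc = np.asarray(h.betweenness(), dtype=np.float64)
        pivots_used = n
    else:
        rng = np.random.default_rng(seed)
        sources = sorted(int(s) for s in rng.choice(n, size=n_pivots, replace=False))
        bc = np.asarray(h.betweenness(sources=sources), dtype=np.float64)
        bc *= n / len(sources)
        pivots_used = len(sources)

    deg = np.asarray([g.degree(v) for v in nodes], dtype=np.int64)
    by_degree: dict[int, float] = {}
    for k in np.unique(deg[deg >= 1]):
        by_degree[int(k)] = float(bc[deg == k].mean())
    centers, means = _degree_binned_means(deg[deg >= 1], bc[deg >= 1], k_floor=1)
    slope = _loglog_slope(centers, means)
    return BetweennessProfile(
        per_node={v: float(b) for v, b in zip(nodes, bc)},
        by_degree=by_degree,
        loglog_slope=slope,
        n_pivots=pivots_used,
        seed=seed,
        exact=exact,
    )
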