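"""Graph statistics for the pharmacology networks.

Implements every statistic the analysis reports: per-node degree k and the
degree distribution P(k), average degree ⟨k⟩ = 2E/N, average path length L
and diameter D over connected node pairs, the local clustering coefficient
C_i = 2e_i / (k_i(k_i−1)) with C_i = 0 for k_i < 2, the three centrality
indices

    Cd(i) = k_i / (N−1)
    Cb(i) = Σ_{j<k} g_jk(i) / g_jk        (raw; normalized by (N−1)(N−2)/2)
    Cc(i) = (N_comp−1) / Σ_j d_ij         (per connected component)

a log–log least-squares power-law fit of P(k), a small-world comparison
against size-matched G(N, E) random graphs, hub ranking, and robust-z
centrality outlier flagging.

Shortest-path and betweenness computations delegate to networkx (Brandes'
accumulation); exhaustive oracles used to validate them live in the test
suite, not here. Full precision is kept internally; rounding happens only at
report serialization.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sstats

from .exceptions import DomainError, FitError
from .synthetic_data import DegreeTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# degree statistics
# ---------------------------------------------------------------------------

def degree_statistics(graph: nx.Graph
                      ) -> tuple[dict, float | None, DegreeTable | None, dict]:
    """Per-node degrees, average degree ⟨k⟩ = 2E/N, the degree-frequency
    table (rows sorted by descending k), and the distribution P(k).

    On an empty graph returns ``({}, None, None, {})`` with a warning.
    """
    if graph.number_of_nodes() == 0:
        logger.warning("degree_statistics: empty graph; all statistics null")
        return {}, None, None, {}
    degrees = dict(graph.degree())
    n = len(degrees)
    mean_degree = 2.0 * graph.number_of_edges() / n
    table = DegreeTable.from_degrees(degrees.values())
    pk = {k: freq / n for k, freq in table.rows}
    return degrees, mean_degree, table, pk


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def clustering_coefficient(graph: nx.Graph, node=None):
    """Local clustering coefficient C_i = 2e_i / (k_i(k_i−1)) where e_i is
    the number of edges among the neighbors of i; C_i = 0 when k_i < 2.

    With *node* given returns that node's value; otherwise a dict over all
    nodes.
    """
    if node is not None:
        if node not in graph:
            raise LookupError(f"node {node!r} not in graph")
        return nx.clustering(graph, node)
    return nx.clustering(graph)


def mean_clustering(graph: nx.Graph) -> tuple[float | None, float | None]:
    """(mean over all nodes, mean over nodes with k >= 2)."""
    if graph.number_of_nodes() == 0:
        return None, None
    values = nx.clustering(graph)
    all_mean = sum(values.values()) / len(values)
    k2 = [values[v] for v in values if graph.degree(v) >= 2]
    return all_mean, (sum(k2) / len(k2) if k2 else None)


# ---------------------------------------------------------------------------
# path statistics
# ---------------------------------------------------------------------------

@dataclass
class GeodesicSummary:
    """All-pairs shortest-path lengths and geodesic counts.

    ``g_through(j, k, i)`` gives the number of j–k geodesics passing through
    the interior node i, via the identity g_jk(i) = g_ji·g_ik when
    d_ji + d_ik = d_jk (0 otherwise).
    """

    distances: dict
    sigma: dict  # sigma[u][v]: number of shortest u-v paths

    def g_through(self, j, k, i) -> int:
        if i == j or i == k:
            return 0
        dj = self.distances[j]
        if k not in dj or i not in dj or k not in self.distances[i]:
            return 0
        if dj[i] + self.distances[i][k] != dj[k]:
            return 0
        return self.sigma[j][i] * self.sigma[i][k]


def geodesic_summary(graph: nx.Graph) -> GeodesicSummary:
    """BFS all-pairs distances and shortest-path counts (unweighted)."""
    distances = {}
    sigma = {}
    for source in graph:
        dist, count = _bfs_counts(graph, source)
        distances[source] = dist
        sigma[source] = count
    return GeodesicSummary(distances, sigma)


def _bfs_counts(graph: nx.Graph, source):
    dist = {source: 0}
    count = {source: 1}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    count[v] = count[u]
                    nxt.append(v)
                elif dist[v] == dist[u] + 1:
                    count[v] += count[u]
        frontier = nxt
    return dist, count


def path_statistics(graph: nx.Graph
                    ) -> tuple[float | None, int | None, bool]:
    """(L, D, connected): average path length over connected unordered node
    pairs, diameter (max distance over connected pairs), and whether the
    graph is connected. L and D are None when no connected pair exists."""
    n = graph.number_of_nodes()
    if n < 2:
        return None, None, n == 1
    total = 0
    n_pairs = 0
    diameter = 0
    reachable_all = True
    for source, dist in nx.all_pairs_shortest_path_length(graph):
        if len(dist) < n:
            reachable_all = False
        for target, d in dist.items():
            if d > 0:
                total += d
                n_pairs += 1
                if d > diameter:
                    diameter = d
    if n_pairs == 0:
        return None, None, False
    # each unordered pair counted twice in the directed sweep
    return total / n_pairs, diameter, reachable_all


# ---------------------------------------------------------------------------
# centrality indices
# ---------------------------------------------------------------------------

def degree_centrality(graph: nx.Graph) -> dict:
    """Cd(i) = k_i / (N−1)."""
    n = graph.number_of_nodes()
    if n < 2:
        raise DomainError("degree centrality requires at least 2 nodes")
    return {node: deg / (n - 1) for node, deg in graph.degree()}


def betweenness_centrality(graph: nx.Graph, normalized: bool = True) -> dict:
    """Cb(i) = Σ over unordered pairs j<k (excluding i) of g_jk(i)/g_jk,
    via Brandes' single-source accumulation. The normalized variant divides
    by (N−1)(N−2)/2."""
    return nx.betweenness_centrality(graph, normalized=normalized)


def closeness_centrality(graph: nx.Graph) -> dict:
    """Cc(i) = (N_comp−1) / Σ_{j in comp} d_ij, computed per connected
    component (component size stands in for N); isolated nodes get 0."""
    return nx.closeness_centrality(graph, wf_improved=False)


# ---------------------------------------------------------------------------
# power-law fit
# ---------------------------------------------------------------------------

def powerlaw_fit(pk: dict) -> tuple[float, float]:
    """Least-squares line on (log10 k, log10 P(k)) over entries with k >= 1
    and P(k) > 0; returns (gamma, r_squared) with gamma = −slope.

    Raises :class:`FitError` with fewer than 3 usable points.
    """
    points = [(k, p) for k, p in pk.items() if k >= 1 and p > 0]
    if len(points) < 3:
        raise FitError(
            f"power-law fit needs >= 3 distinct degrees with P(k) > 0; got "
            f"{len(points)}")
    log_k = np.log10([k for k, _ in points])
    log_p = np.log10([p for _, p in points])
    fit = sstats.linregress(log_k, log_p)
    return -fit.slope, fit.rvalue ** 2


# ---------------------------------------------------------------------------
# small-world comparison
# ---------------------------------------------------------------------------

def smallworld_compare(graph: nx.Graph, n_random: int = 100,
                       seed: int = 0) -> dict:
    """Compare clustering and path length against G(N, E) random baselines.

    Baselines are Erdős–Rényi graphs with matched node and edge counts;
    C_rand and L_rand are means over *n_random* replicates (path length taken
    on the largest component when a replicate is disconnected). Returns the
    ratios and the small-world coefficient
    sigma = (C̄/C_rand) / (L/L_rand); sigma >> 1 indicates small-world
    structure.
    """
    if n_random < 1:
        raise DomainError("n_random must be >= 1")
    n, m = graph.number_of_nodes(), graph.number_of_edges()
    c_obs, _ = mean_clustering(graph)
    sub = graph.subgraph(max(nx.connected_components(graph), key=len))
    l_obs, _, _ = path_statistics(sub)
    rng = np.random.default_rng(seed)
    c_samples, l_samples = [], []
    for _ in range(n_random):
        random_graph = nx.gnm_random_graph(n, m, seed=int(rng.integers(2 ** 31)))
        c_r, _ = mean_clustering(random_graph)
        comp = random_graph.subgraph(
            max(nx.connected_components(random_graph), key=len))
        l_r, _, _ = path_statistics(comp)
        c_samples.append(c_r)
        if l_r is not None:
            l_samples.append(l_r)
    c_rand = float(np.mean(c_samples))
    l_rand = float(np.mean(l_samples)) if l_samples else math.nan
    c_ratio = c_obs / c_rand if c_rand > 0 else math.inf
    l_ratio = l_obs / l_rand if l_rand and not math.isnan(l_rand) else math.nan
    sigma = c_ratio / l_ratio if l_ratio and not math.isnan(l_ratio) else math.nan
    return {
        "clustering": c_obs, "clustering_random": c_rand,
        "clustering_ratio": c_ratio,
        "path_length": l_obs, "path_length_random": l_rand,
        "path_length_ratio": l_ratio,
        "sigma": sigma, "n_random": n_random,
    }


# ---------------------------------------------------------------------------
# rankings and outliers
# ---------------------------------------------------------------------------

RANK_METRICS = ("k", "Cd", "Cb", "Cc", "C_i")


def rank_nodes(table: pd.DataFrame, by: str = "k",
               top_n: int | None = None) -> pd.DataFrame:
    """Rank the per-node table by one metric, descending, ties broken by
    ascending node id; optionally truncated to the top *top_n* rows."""
    if by not in RANK_METRICS:
        raise DomainError(f"unknown ranking metric {by!r}; one of {RANK_METRICS}")
    out = table.sort_values([by, "node"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
    return out.head(top_n) if top_n is not None else out


def centrality_outliers(table: pd.DataFrame, z_threshold: float = 2.0
                        ) -> list[str]:
    """Flag nodes whose robust z-score exceeds *z_threshold* on at least one
    of the three centralities (Cd, Cb, Cc).

    The robust z on each axis is 0.6745·(x − median)/MAD; only the
    high-value direction is flagged, since the analysis looks for unusually
    central proteins. On an axis with zero MAD the mean absolute deviation
    substitutes; if every axis is degenerate (all values equal) a warning is
    logged and no node is flagged unless some value strictly exceeds its
    axis maximum's median — in that degenerate case the top node per
    informative axis is flagged instead.
    """
    if len(table) < 3:
        raise DomainError("outlier flagging requires at least 3 nodes")
    axes = [c for c in ("Cd", "Cb", "Cc") if c in table.columns]
    if not axes:
        raise DomainError("table carries none of the centrality columns Cd/Cb/Cc")
    flagged: set[str] = set()
    informative = False
    for axis in axes:
        x = table[axis].to_numpy(dtype=float)
        med = float(np.median(x))
        mad = float(np.median(np.abs(x - med)))
        scale = mad / 0.6745
        if scale == 0:
            mean_ad = float(np.mean(np.abs(x - med)))
            scale = mean_ad / 0.7979  # consistency factor for the normal
        if scale == 0:
            continue  # all values identical on this axis
        informative = True
        z = (x - med) / scale
        flagged.update(table.loc[z > z_threshold, "node"])
    if not informative:
        logger.warning("centrality_outliers: zero spread on every axis; "
                       "falling back to rank-based flagging")
        for axis in axes:
            x = table[axis].to_numpy(dtype=float)
            if x.max() > x.min():
                top = table.loc[x.argmax(), "node"]
                flagged.add(top)
    return sorted(flagged)


# ---------------------------------------------------------------------------
# assembled report
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Global and per-node statistics of one graph."""

    n_nodes: int
    n_edges: int
    connected: bool
    mean_degree: float | None
    average_path_length: float | None
    diameter: int | None
    mean_clustering: float | None
    mean_clustering_k2: float | None
    degree_table: DegreeTable | None
    degree_distribution: dict = field(default_factory=dict)
    powerlaw: tuple[float, float] | None = None
    per_node: pd.DataFrame | None = None
    smallworld: dict | None = None


def compute_metrics(graph: nx.Graph, include_paths: bool = True,
                    include_centralities: bool = True,
                    smallworld_replicates: int = 0,
                    seed: int = 0) -> MetricsReport:
    """Assemble a full :class:`MetricsReport` for one graph.

    The power-law fit is attempted and silently omitted when the degree
    distribution has too few support points. Small-world comparison runs
    only when ``smallworld_replicates > 0`` and the graph has edges.
    """
    degrees, mean_degree, table, pk = degree_statistics(graph)
    n, m = graph.number_of_nodes(), graph.number_of_edges()
    c_all, c_k2 = mean_clustering(graph)
    if include_paths and n >= 2:
        length, diameter, connected = path_statistics(graph)
    else:
        length, diameter, connected = None, None, n <= 1
    try:
        powerlaw = powerlaw_fit(pk) if pk else None
    except FitError:
        powerlaw = None

    per_node = None
    if include_centralities and n >= 2:
        clustering = nx.clustering(graph)
        cd = degree_centrality(graph)
        cb_raw = betweenness_centrality(graph, normalized=False)
        norm = (n - 1) * (n - 2) / 2.0
        cc = closeness_centrality(graph)
        nodes = list(graph.nodes())
        per_node = pd.DataFrame({
            "node": [str(v) for v in nodes],
            "k": [degrees[v] for v in nodes],
            "C_i": [clustering[v] for v in nodes],
            "Cd": [cd[v] for v in nodes],
            "Cb_raw": [cb_raw[v] for v in nodes],
            "Cb": [cb_raw[v] / norm if norm > 0 else 0.0 for v in nodes],
            "Cc": [cc[v] for v in nodes],
        })

    smallworld = None
    if smallworld_replicates > 0 and m > 0 and n >= 2:
        smallworld = smallworld_compare(graph, n_random=smallworld_replicates,
                                        seed=seed)

    return MetricsReport(
        n_nodes=n, n_edges=m, connected=connected,
        mean_degree=mean_degree,
        average_path_length=length, diameter=diameter,
        mean_clustering=c_all, mean_clustering_k2=c_k2,
        degree_table=table, degree_distribution=pk,
        powerlaw=powerlaw, per_node=per_node, smallworld=smallworld,
    )
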