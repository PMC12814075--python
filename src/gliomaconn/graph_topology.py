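"""Tumor-as-node brain-graph construction and nodal topology.

The lesion (or its mirrored control) joins the cortical parcels as one node
of a functional graph.  Edges are the strongest Fisher-z weights retained at
a sparsity threshold (proportion of all possible edges), ranked by signed z
so strong positive correlations enter first; graphs are binary after
thresholding.  The admissible sparsity range is the set of levels at which
every subject's graph has no isolated node and a small-world index
sigma = (C/C_rand)/(L/L_rand) above 1.1, where the reference values come
from degree-preserving rewirings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

SPARSITY_CANDIDATES = (0.15, 0.20, 0.25, 0.30, 0.35, 0.40)
SIGMA_MIN = 1.1
#: Sparsity level at which nodal statistics are reported.
PRIMARY_SPARSITY = 0.15


@dataclass
class FunctionalGraph:
    """A thresholded binary graph over parcels plus one seed node."""

    graph: nx.Graph
    sparsity: float
    weights: np.ndarray          # underlying Fisher z matrix
    nodes: list

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class NodalTopology:
    """Per-node topology metrics plus the graph-level small-world index."""

    degree_centrality: dict
    betweenness_centrality: dict
    closeness_centrality: dict
    clustering_coefficient: dict
    small_world_sigma: float | None = None

    def row(self, node) -> dict:
        return {
            "degree": self.degree_centrality[node],
            "betweenness": self.betweenness_centrality[node],
            "closeness": self.closeness_centrality[node],
            "clustering": self.clustering_coefficient[node],
        }


def build_graph(z_matrix: np.ndarray, sparsity: float, node_names=None,
                ranking: str = "signed") -> FunctionalGraph:
    """Keep the K = round(sparsity * N(N-1)/2) strongest edges, unweighted.

    ``ranking="signed"`` ranks by the signed Fisher z (strong positive
    correlations first); ``"absolute"`` ranks by |z|.  Ties are broken by
    lexicographic node-pair order.  NaN weights (unusable node pairs) are
    never selected.
    """
    z = np.asarray(z_matrix, dtype=float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ValueError("z_matrix must be square")
    if not np.allclose(np.nan_to_num(z), np.nan_to_num(z.T), atol=1e-10):
        raise ValueError("z_matrix must be symmetric")
    if not 0.0 < sparsity <= 1.0:
        raise ValueError("sparsity must lie in (0, 1]")
    n = z.shape[0]
    if node_names is None:
        node_names = list(range(n))
    iu, ju = np.triu_indices(n, k=1)
    w = z[iu, ju]
    if ranking == "absolute":
        w = np.abs(w)
    elif ranking != "signed":
        raise ValueError("ranking must be 'signed' or 'absolute'")
    k = int(round(sparsity * n * (n - 1) / 2.0))
    if k == 0:
        raise ValueError("sparsity too low: zero edges requested")
    rank_w = np.where(np.isfinite(w), w, -np.inf)
    order = np.lexsort((ju, iu, -rank_w))
    order = order[np.isfinite(rank_w[order])][:k]
    if order.size < k:
        warnings.warn(f"only {order.size} finite edges available for K={k}", stacklevel=2)
    g = nx.Graph()
    g.add_nodes_from(node_names)
    g.add_edges_from((node_names[iu[e]], node_names[ju[e]]) for e in order)
    return FunctionalGraph(graph=g, sparsity=sparsity, weights=z, nodes=list(node_names))


def has_isolates(fg: FunctionalGraph | nx.Graph) -> bool:
    g = fg.graph if isinstance(fg, FunctionalGraph) else fg
    return any(d == 0 for _, d in g.degree())


def _clustering_and_path(g: nx.Graph) -> tuple[float, float]:
    c = nx.average_clustering(g)
    if nx.is_connected(g):
        l = nx.average_shortest_path_length(g)
    else:
        comp = max(nx.connected_components(g), key=len)
        l = nx.average_shortest_path_length(g.subgraph(comp))
    return c, l


def small_world_sigma(fg: FunctionalGraph | nx.Graph, n_random: int = 10,
                      seed: int = 0, swaps_per_edge: int = 10) -> float:
    """Small-world index sigma = (C/C_rand) / (L/L_rand).

    Reference clustering and path length are averaged over ``n_random``
    degree-preserving rewirings (``swaps_per_edge`` double-edge swaps per
    edge, seeded).  Disconnected graphs use the largest component with a
    warning.  Graphs where no swap is possible (e.g. complete graphs) keep
    their own values as reference, giving sigma = 1.
    """
    g = fg.graph if isinstance(fg, FunctionalGraph) else fg
    if g.number_of_nodes() < 4:
        raise ValueError("sigma needs at least 4 nodes")
    if not nx.is_connected(g):
        warnings.warn("graph disconnected; sigma computed on the largest component", stacklevel=2)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
    c, l = _clustering_and_path(g)
    rng = np.random.default_rng(seed)
    n_edges = g.number_of_edges()
    c_rand, l_rand = [], []
    for _ in range(n_random):
        h = g.copy()
        try:
            nx.double_edge_swap(h, nswap=swaps_per_edge * n_edges,
                                max_tries=20 * swaps_per_edge * n_edges,
                                seed=int(rng.integers(2**31)))
        except nx.NetworkXException:
            pass  # too dense / no swappable pair: reference = the graph itself
        cr, lr = _clustering_and_path(h)
        c_rand.append(cr)
        l_rand.append(lr)
    c_ref, l_ref = float(np.mean(c_rand)), float(np.mean(l_rand))
    if c_ref == 0 or l_ref == 0 or l == 0:
        return float("nan")
    return float((c / c_ref) / (l / l_ref))


@dataclass
class SweepReport:
    """Per-level, per-subject validity of the sparsity sweep."""

    candidates: tuple
    no_isolates: dict            # level -> list[bool] per subject
    small_world: dict            # level -> list[float] sigma per subject
    valid_levels: list           # levels where all subjects pass both criteria
    graphs: dict                 # (level, subject_index) -> FunctionalGraph


def sweep_sparsity(z_matrices, candidates=SPARSITY_CANDIDATES, sigma_min: float = SIGMA_MIN,
                   n_random: int = 10, seed: int = 0, node_names=None) -> SweepReport:
    """Validate each candidate sparsity level across all subjects.

    A level is admissible when no subject's graph has an isolated node and
    every subject's sigma exceeds ``sigma_min``.
    """
    z_matrices = list(z_matrices)
    if not z_matrices:
        raise ValueError("need at least one subject")
    no_iso: dict = {}
    sw: dict = {}
    graphs: dict = {}
    valid = []
    for lev in candidates:
        iso_flags, sigmas = [], []
        for si, z in enumerate(z_matrices):
            fg = build_graph(z, lev, node_names=node_names)
            graphs[(lev, si)] = fg
            iso_flags.append(not has_isolates(fg))
            sigmas.append(small_world_sigma(fg, n_random=n_random, seed=seed + si))
        no_iso[lev] = iso_flags
        sw[lev] = sigmas
        if all(iso_flags) and all(s > sigma_min for s in sigmas):
            valid.append(lev)
    return SweepReport(tuple(candidates), no_iso, sw, valid, graphs)


def all_nodal_metrics(fg: FunctionalGraph, with_sigma: bool = False,
                      n_random: int = 10, seed: int = 0) -> NodalTopology:
    """The four nodal metrics for every node (same path for seed and parcels).

    Degree centrality is degree/(N-1); betweenness is normalized shortest-path
    betweenness; closeness uses the Wasserman-Faust component-scaled form;
    clustering is triangles over possible neighbour pairs.
    """
    g = fg.graph
    return NodalTopology(
        degree_centrality=nx.degree_centrality(g),
        betweenness_centrality=nx.betweenness_centrality(g, normalized=True),
        closeness_centrality=nx.closeness_centrality(g, wf_improved=True),
        clustering_coefficient=nx.clustering(g),
        small_world_sigma=small_world_sigma(fg, n_random=n_random, seed=seed)
        if with_sigma else None,
    )


def nodal_metrics(fg: FunctionalGraph, node) -> dict:
    """Metric row for one node.

    Betweenness requires the full all-pairs computation; degree, closeness
    and clustering are evaluated for the requested node only.  Values are
    identical to the corresponding entries of :func:`all_nodal_metrics`.
    """
    g = fg.graph if isinstance(fg, FunctionalGraph) else fg
    if node not in g:
        raise ValueError(f"node {node!r} not in graph")
    n = g.number_of_nodes()
    return {
        "degree": g.degree(node) / (n - 1) if n > 1 else 0.0,
        "betweenness": nx.betweenness_centrality(g, normalized=True)[node],
        "closeness": nx.closeness_centrality(g, u=node, wf_improved=True),
        "clustering": nx.clustering(g, node),
    }
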