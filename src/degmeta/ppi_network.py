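"""Dense-subnetwork detection and hub calling on a protein-protein graph.

Multi-study genes are projected onto a STRING-style interaction graph;
MCODE-style clustering then extracts densely interconnected subnetworks
(putative complexes/pathway cores), and betweenness centrality picks hub
genes within and across clusters.  The MCODE implementation follows the
canonical published description: vertex weighting by the
core-clustering coefficient (density of the highest k-core of a node's
closed neighbourhood, scaled by that core's k), seeded greedy expansion
with a node-score cutoff relative to the seed, and post-processing by
k-core filtering with optional haircut and fluff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, NamedTuple, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HubConfig",
    "HubResult",
    "McodeParams",
    "SubnetworkCluster",
    "betweenness_hubs",
    "induced_subgraph",
    "mcode_clusters",
    "mcode_vertex_weights",
    "normalized_betweenness",
    "read_edge_list",
]


@dataclass(frozen=True)
class McodeParams:
    """MCODE parameters; the defaults are the standard parameter set
    (degree cutoff 2, node density cutoff 0.3, node score cutoff 0.2,
    k-core 4, max depth 100)."""

    degree_cutoff: int = 2
    node_density_cutoff: float = 0.3
    node_score_cutoff: float = 0.2
    k_core: int = 4
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False

    def __post_init__(self) -> None:
        if min(self.degree_cutoff, self.node_density_cutoff,
               self.node_score_cutoff, self.k_core, self.max_depth) <= 0:
            raise ValueError("all MCODE parameters must be positive")


@dataclass
class SubnetworkCluster:
    """One detected dense subnetwork."""

    members: frozenset
    seed_node: Hashable
    cluster_score: float                      # density x size
    main_hub: Hashable = None
    hub_betweenness: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class HubConfig:
    """Candidate-hub selection: normalized betweenness above the threshold,
    computed on the whole graph (default) or within each cluster."""

    candidate_threshold: float = 0.5
    scope: str = "whole_graph"

    def __post_init__(self) -> None:
        if not (0.0 < self.candidate_threshold < 1.0):
            raise ValueError("candidate_threshold must lie in (0, 1)")
        if self.scope not in ("whole_graph", "per_cluster"):
            raise ValueError(f"scope must be 'whole_graph' or 'per_cluster', got {self.scope!r}")


def read_edge_list(path, threshold: int = 400, *, sep: str = "\t") -> nx.Graph:
    """Read a STRING-style TSV (node1, node2, combined_score) into a graph.

    Edges below the combined-score threshold are dropped (default 400,
    STRING's "medium confidence").  Self-loops and duplicate edges are
    removed; isolated nodes do not arise from an edge list.  Malformed
    rows are skipped with a logged line number.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected columns node1, node2, combined_score")
    g = nx.Graph()
    n_bad = 0
    for i, (u, v, s) in enumerate(df.itertuples(index=False, name=None), start=1):
        try:
            score = float(s)
        except (TypeError, ValueError):
            logger.warning("%s line %d: non-numeric score %r, row skipped", path, i, s)
            n_bad += 1
            continue
        if u == v:
            logger.warning("%s line %d: self-loop on %r dropped", path, i, u)
            continue
        if score < threshold:
            continue
        if g.has_edge(u, v):
            g[u][v]["combined_score"] = max(g[u][v]["combined_score"], score)
        else:
            g.add_edge(u, v, combined_score=score)
    logger.info("%s: %d nodes, %d edges at threshold %d (%d malformed rows)",
                path, g.number_of_nodes(), g.number_of_edges(), threshold, n_bad)
    return g


def induced_subgraph(g: nx.Graph, genes) -> nx.Graph:
    """Subgraph induced by a gene list (e.g. genes with n_agree >= 2),
    with isolated nodes dropped."""
    sub = g.subgraph(set(genes)).copy()
    sub.remove_nodes_from([n for n in sub if sub.degree(n) == 0])
    return sub


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _highest_k_core(g: nx.Graph) -> tuple[nx.Graph, int]:
    """The maximal-k k-core of a graph and its k."""
    core_num = nx.core_number(g)
    k_max = max(core_num.values())
    core = g.subgraph([n for n, c in core_num.items() if c >= k_max])
    return core, k_max


def mcode_vertex_weights(g: nx.Graph, params: McodeParams | None = None) -> dict:
    """Core-clustering-coefficient vertex weights.

    For each node of degree >= degree_cutoff: the density of the highest
    k-core of the node's closed neighbourhood, multiplied by that core's
    k.  Low-degree nodes weigh 0 and can neither seed nor join expansion.
    """
    params = params or McodeParams()
    weights: dict = {}
    for v in g:
        if g.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = g.subgraph(set(g[v]) | {v})
        core, k_max = _highest_k_core(nbhd)
        weights[v] = _density(core) * k_max
    return weights


def mcode_clusters(g: nx.Graph, params: McodeParams | None = None) -> list[SubnetworkCluster]:
    """Seeded greedy MCODE clustering.

    Seeds are taken in decreasing vertex-weight order (ties by node id).
    Expansion is a breadth-first walk from the seed including unassigned
    neighbours whose weight is at least ``seed_weight * (1 -
    node_score_cutoff)``, to at most ``max_depth`` hops.  A node joins at
    most one cluster.  Post-processing discards clusters that do not
    contain a k-core of k = ``k_core``; haircut trims the cluster to its
    2-core; fluff adds neighbours whose closed-neighbourhood density
    exceeds ``node_density_cutoff`` (fluff nodes may repeat across
    clusters).  Clusters come back ordered by score (density x size),
    descending.
    """
    params = params or McodeParams()
    if g.number_of_nodes() == 0:
        return []
    weights = mcode_vertex_weights(g, params)
    order = sorted(g.nodes, key=lambda v: (-weights[v], v))
    assigned: set = set()
    clusters: list[SubnetworkCluster] = []

    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for u in frontier:
                for v in g[u]:
                    if v in members or v in assigned:
                        continue
                    if weights[v] >= threshold:
                        members.add(v)
                        nxt.append(v)
            frontier = nxt
            depth += 1
        assigned |= members

        sub = g.subgraph(members)
        core_ok = max(nx.core_number(sub).values()) >= params.k_core if sub.number_of_nodes() else False
        if not core_ok:
            continue
        if params.haircut:
            sub = nx.k_core(sub, 2)
            members = set(sub.nodes)
        if params.fluff:
            extra = set()
            for u in members:
                for v in g[u]:
                    if v in members or v in extra:
                        continue
                    if _density(g.subgraph(set(g[v]) | {v})) > params.node_density_cutoff:
                        extra.add(v)
            members |= extra
            sub = g.subgraph(members)

        bc = normalized_betweenness(g.subgraph(members))
        main_hub = min(bc, key=lambda n: (-bc[n], n))
        clusters.append(
            SubnetworkCluster(
                members=frozenset(members),
                seed_node=seed,
                cluster_score=_density(g.subgraph(members)) * len(members),
                main_hub=main_hub,
                hub_betweenness=bc,
            )
        )
    clusters.sort(key=lambda c: (-c.cluster_score, str(c.seed_node)))
    return clusters


def normalized_betweenness(g: nx.Graph) -> dict:
    """Betweenness centrality normalized per connected component.

    Each component is treated independently and normalized by
    (n-1)(n-2)/2 for its own n, so a component's central node can reach
    1.0 regardless of the rest of the graph.  Components with n < 3 score 0.
    """
    bc: dict = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        bc.update(nx.betweenness_centrality(sub, normalized=True))
    return bc


class HubResult(NamedTuple):
    betweenness: dict                 # node -> normalized betweenness (whole graph)
    candidates: set                   # nodes above the candidate threshold
    main_hub_by_cluster: dict         # cluster index -> member with max betweenness


def betweenness_hubs(
    g: nx.Graph,
    clusters: Sequence[SubnetworkCluster] = (),
    cfg: HubConfig | None = None,
) -> HubResult:
    """Call candidate hub genes by normalized betweenness centrality.

    Candidates are the nodes whose normalized betweenness exceeds the
    threshold in the configured scope (the whole multi-study graph by
    default, or each cluster's own subgraph).  For every cluster the main
    hub is its member with maximal betweenness (ties to the lower node id).
    """
    cfg = cfg or HubConfig()
    whole = normalized_betweenness(g)
    if cfg.scope == "whole_graph":
        candidates = {n for n, b in whole.items() if b > cfg.candidate_threshold}
        scope_bc = [whole] * len(clusters)
    else:
        scope_bc = [normalized_betweenness(g.subgraph(c.members)) for c in clusters]
        candidates = {n for bc in scope_bc for n, b in bc.items() if b > cfg.candidate_threshold}
    main_hubs = {}
    for i, (cluster, bc) in enumerate(zip(clusters, scope_bc)):
        members = [n for n in cluster.members if n in bc]
        main_hubs[i] = min(members, key=lambda n: (-bc[n], n)) if members else None
    return HubResult(whole, candidates, main_hubs)
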