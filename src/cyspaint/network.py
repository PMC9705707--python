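"""Interaction-network induction, community detection and connectivity tests.

The comparison proteins are mapped onto a protein-protein interaction
network (STRING-style scored edge list); communities are found by greedy
modularity maximization (the fast-greedy family), with divisive
edge-betweenness splitting available as an alternative. Nodes in components
or communities smaller than a minimum size are flagged as orphans.
Connectivity enrichment is assessed against an explicit permutation null:
the edge count of the induced subgraph is compared with the edge counts of
equal-size uniform random subsets of a background protein set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)


def induced_network(network: nx.Graph, proteins) -> nx.Graph:
    """Subgraph induced on ``proteins``; proteins absent from the network
    are retained as isolated nodes."""
    proteins = set(proteins)
    present = proteins & set(network.nodes)
    if not present:
        logger.warning("no requested protein is present in the network")
    sub = nx.Graph(network.subgraph(present))
    sub.add_nodes_from(sorted(proteins - present))
    return sub


@dataclass
class ClusterAssignment:
    """A disjoint, exhaustive partition of network nodes into communities.

    Cluster ids are assigned by descending cluster size (ties broken by the
    lexicographically smallest member). Nodes in clusters below the minimum
    size are flagged as orphans but keep their cluster id, so the partition
    stays exhaustive.
    """

    clusters: list[set]
    labels: dict
    orphan: dict
    modularity: float
    min_cluster_size: int

    def to_frame(self) -> pd.DataFrame:
        rows = [(node, self.labels[node], self.orphan[node])
                for node in sorted(self.labels)]
        return pd.DataFrame(rows, columns=["protein", "cluster", "orphan"])

    @property
    def n_major(self) -> int:
        """Number of clusters at or above the minimum size."""
        return sum(len(c) >= self.min_cluster_size for c in self.clusters)

    @property
    def n_orphans(self) -> int:
        return sum(self.orphan.values())


def _sorted_copy(network: nx.Graph) -> nx.Graph:
    """Rebuild the graph with deterministic (lexicographic) insertion order."""
    g = nx.Graph()
    g.add_nodes_from(sorted(network.nodes))
    g.add_edges_from(sorted((min(a, b), max(a, b)) for a, b in network.edges))
    return g


def detect_communities(
    network: nx.Graph,
    min_cluster_size: int = 3,
    method: str = "greedy",
) -> ClusterAssignment:
    """Partition the network into communities.

    ``method="greedy"`` (default) is greedy modularity maximization;
    ``method="girvan_newman"`` removes highest-betweenness edges and keeps
    the partition of maximal modularity along the divisive hierarchy. Both
    run on a lexicographically ordered copy of the graph, so identical
    inputs give identical partitions.
    """
    if min_cluster_size < 1:
        raise ConfigurationError("min_cluster_size must be >= 1")
    if network.number_of_nodes() == 0:
        return ClusterAssignment([], {}, {}, float("nan"), min_cluster_size)
    g = _sorted_copy(network)
    if g.number_of_edges() == 0:
        communities = [{n} for n in g.nodes]
        modularity = float("nan")
    elif method == "greedy":
        communities = [set(c) for c in
                       nx.community.greedy_modularity_communities(g)]
        modularity = nx.community.modularity(g, communities)
    elif method == "girvan_newman":
        components = [set(c) for c in nx.connected_components(g)]
        best, best_q = components, nx.community.modularity(g, components)
        for partition in nx.community.girvan_newman(g):
            parts = [set(c) for c in partition]
            q = nx.community.modularity(g, parts)
            if q > best_q:
                best, best_q = parts, q
        communities, modularity = best, best_q
    else:
        raise ConfigurationError("method must be 'greedy' or 'girvan_newman'")

    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    labels, orphan = {}, {}
    for cid, members in enumerate(communities):
        for node in members:
            labels[node] = cid
            orphan[node] = len(members) < min_cluster_size
    return ClusterAssignment(communities, labels, orphan, float(modularity),
                             min_cluster_size)


def connectivity_enrichment(
    network: nx.Graph,
    proteins,
    background,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, int]:
    """Empirical p-value that ``proteins`` are more interconnected than chance.

    The observed statistic is the edge count of the subgraph induced on
    ``proteins``; the null resamples equal-size subsets of ``background``
    uniformly without replacement. Returns (p, observed edge count) with the
    add-one estimator p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    proteins = set(proteins)
    background = sorted(set(background))
    if not proteins <= set(background):
        raise ConfigurationError("proteins must be a subset of the background")
    if len(proteins) < 2:
        raise ConfigurationError("enrichment test undefined for < 2 proteins")
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    adjacency = {node: set(network.adj[node]) for node in network.nodes}

    def edge_count(nodes) -> int:
        nodes = set(nodes)
        return sum(len(adjacency.get(n, set()) & nodes) for n in nodes) // 2

    observed = edge_count(proteins)
    k = len(proteins)
    exceed = 0
    for _ in range(n_perm):
        sample = rng.choice(background, size=k, replace=False)
        if edge_count(sample) >= observed:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return float(p), observed
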