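"""The four structural measures of an unweighted semantic network.

* CC  -- mean local clustering coefficient (Watts-Strogatz): for each node,
  the fraction of its neighbour pairs that are themselves connected, averaged
  over nodes (degree < 2 contributes 0).
* ASPL -- average shortest path length in hops over all unordered node pairs.
* Q   -- Newman modularity of the best partition found by Louvain community
  detection over several restarts.
* S   -- Humphries-Gurney small-world-ness, S = (CC / CC_rand) / (ASPL /
  ASPL_rand), where the reference terms are ensemble means over Erdos-Renyi
  graphs with the same node and edge counts.  S is ~1 for random graphs and
  substantially above 1 for small-world networks.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph
import networkx as nx
import numpy as np

from .exceptions import ValidationError

MEASURE_NAMES = ("cc", "aspl", "q", "s")


@dataclass(frozen=True)
class NetworkMeasures:
    """The (CC, ASPL, Q, S) tuple for one graph, with its size for context."""

    cc: float
    aspl: float
    q: float
    s: float
    n_nodes: int
    n_edges: int

    def as_dict(self) -> dict[str, float]:
        return {"cc": self.cc, "aspl": self.aspl, "q": self.q, "s": self.s}


def clustering_coefficient(g: nx.Graph) -> float:
    """Mean local clustering coefficient (nodes of degree < 2 contribute 0)."""
    if g.number_of_nodes() == 0:
        raise ValidationError("clustering coefficient needs at least one node")
    return float(nx.average_clustering(g))


def aspl(g: nx.Graph) -> float:
    """Average shortest path length in hops over unordered node pairs.

    A disconnected graph (possible only for user-supplied, non-TMFG graphs)
    is reduced to its largest connected component with a warning.
    """
    if g.number_of_edges() == 0:
        raise ValidationError("ASPL is undefined for an edgeless graph")
    if not nx.is_connected(g):
        warnings.warn("graph is disconnected; ASPL computed on the largest component",
                      stacklevel=2)
        g = g.subgraph(max(nx.connected_components(g), key=len))
    return float(nx.average_shortest_path_length(g))


def modularity(g: nx.Graph, seed: int, restarts: int = 10) -> tuple[float, list[set]]:
    """Best-of-``restarts`` Louvain modularity and its partition.

    Louvain is stochastic on graphs this small; running it several times from
    seeded starts and keeping the highest-Q (Newman modularity) partition
    tames that variability while remaining reproducible.  Community detection
    runs on igraph's Louvain implementation.
    """
    if g.number_of_edges() == 0:
        raise ValidationError("modularity needs at least one edge")
    nodes = list(g.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    h = igraph.Graph(n=len(nodes), edges=[(index[u], index[v]) for u, v in g.edges()])
    igraph.set_random_number_generator(random.Random(int(seed)))
    best_q, best_membership = -np.inf, None
    for _ in range(restarts):
        part = h.community_multilevel()
        q = h.modularity(part.membership)
        if q > best_q:
            best_q, best_membership = q, part.membership
    n_comms = max(best_membership) + 1
    partition = [set() for _ in range(n_comms)]
    for v, c in zip(nodes, best_membership):
        partition[c].add(v)
    return float(best_q), partition


def random_reference_stats(
    n_nodes: int,
    n_edges: int,
    n_ref: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Ensemble means (CC_rand, ASPL_rand) over Erdos-Renyi G(n, m) draws.

    ASPL of a disconnected draw is taken on its largest component.
    """
    rng = np.random.default_rng(seed)
    ccs = np.empty(n_ref)
    aspls = np.empty(n_ref)
    for i in range(n_ref):
        r = nx.gnm_random_graph(n_nodes, n_edges, seed=int(rng.integers(2**31)))
        ccs[i] = nx.average_clustering(r)
        if not nx.is_connected(r):
            r = r.subgraph(max(nx.connected_components(r), key=len))
        aspls[i] = nx.average_shortest_path_length(r)
    return float(ccs.mean()), float(aspls.mean())


def small_worldness(
    g: nx.Graph,
    seed: int = 0,
    n_ref: int = 100,
    ref_stats: tuple[float, float] | None = None,
) -> float:
    """Humphries-Gurney small-world-ness index.

    S = (CC / CC_rand) / (ASPL / ASPL_rand) against Erdos-Renyi references
    matched on node and edge count.  ``ref_stats`` may carry precomputed
    (CC_rand, ASPL_rand) to share one reference ensemble across many graphs
    of identical size.
    """
    cc = clustering_coefficient(g)
    length = aspl(g)
    if ref_stats is None:
        ref_stats = random_reference_stats(
            g.number_of_nodes(), g.number_of_edges(), n_ref=n_ref, seed=seed
        )
    cc_rand, aspl_rand = ref_stats
    if cc_rand == 0:
        raise ValidationError("reference clustering coefficient is 0; S is undefined")
    return float((cc / cc_rand) / (length / aspl_rand))


def measure_all(
    g: nx.Graph,
    seed: int = 0,
    restarts: int = 10,
    n_ref: int = 100,
    ref_stats: tuple[float, float] | None = None,
) -> NetworkMeasures:
    """Compute CC, ASPL, Q and S for one unweighted graph."""
    q, _ = modularity(g, seed=seed, restarts=restarts)
    return NetworkMeasures(
        cc=clustering_coefficient(g),
        aspl=aspl(g),
        q=q,
        s=small_worldness(g, seed=seed, n_ref=n_ref, ref_stats=ref_stats),
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
    )
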