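"""Homophilous scale-free social networks and targeting centralities.

The network grows by biased preferential attachment: at every step a
"density" parameter decides whether an extra edge is inserted between
existing members or the next person joins the network. Both choices are
biased by degree (popular people attract ties, yielding a power-law tail)
and by homophily (same sex, similar age and body weight), mirroring how
community ties form. The graph is static over the simulated two years.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, Iterable, List, Optional, Sequence, Set

import networkx as nx
import numpy as np

from .population import Person

__all__ = [
    "HomophilyParams",
    "SocialNetwork",
    "homophily_weight",
    "generate_network",
    "centrality",
    "top_fraction",
]

#: above this node count betweenness/closeness are delegated to igraph's
#: C implementation; results match networkx's definitions
_IGRAPH_THRESHOLD = 300


@dataclasses.dataclass(frozen=True)
class HomophilyParams:
    """Similarity kernel for tie formation.

    ``w = gender_boost^[same sex] * exp(-|dAge|/age_scale) * exp(-|dBW|/bw_scale)``
    """

    gender_boost: float = 2.0
    age_scale: float = 10.0  # years
    bw_scale: float = 10.0  # kg

    def __post_init__(self) -> None:
        if self.gender_boost < 1:
            raise ValueError("gender_boost must be >= 1")
        if self.age_scale <= 0 or self.bw_scale <= 0:
            raise ValueError("scales must be > 0")


@dataclasses.dataclass
class SocialNetwork:
    """Undirected simple graph over agent ids with generation metadata."""

    graph: nx.Graph
    density_param: float
    homophily_params: HomophilyParams
    seed: int

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()


def homophily_weight(a: Person, b: Person, params: HomophilyParams = HomophilyParams()) -> float:
    """Symmetric positive tie-formation weight between two persons."""
    w = params.gender_boost if a.sex == b.sex else 1.0
    w *= math.exp(-abs(a.age - b.age) / params.age_scale)
    w *= math.exp(-abs(a.bw0 - b.bw0) / params.bw_scale)
    return w


def _choice(rng, weights: np.ndarray) -> int:
    total = weights.sum()
    if total <= 0:
        raise ValueError("all candidate weights are zero")
    return int(rng.choice(len(weights), p=weights / total))


def generate_network(
    persons: Sequence[Person],
    density_param: float = 0.267,
    homophily: HomophilyParams = HomophilyParams(),
    seed: int = 0,
    seed_size: int = 3,
) -> SocialNetwork:
    """Grow the social network over ``persons``; deterministic given ``seed``.

    Starting from a small seed clique, each growth step either (with
    probability ``density_param``) adds one edge between two existing
    non-adjacent members — first endpoint chosen proportional to degree,
    second proportional to degree times homophily to the first — or attaches
    the next unplaced person to one existing member chosen proportional to
    degree times homophily. Arrival order is a random permutation.
    """
    if not (0.0 <= density_param < 1.0):
        raise ValueError("density_param must be in [0, 1); at 1 growth never terminates")
    if seed_size < 2:
        raise ValueError("seed_size must be >= 2")
    n = len(persons)
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    for p in persons:
        g.add_node(p.id)
    net = SocialNetwork(graph=g, density_param=density_param, homophily_params=homophily, seed=seed)
    if n == 0:
        return net

    order = rng.permutation(n)
    # attribute arrays in arrival order for vectorized homophily
    age = np.array([persons[i].age for i in order], dtype=float)
    bw = np.array([persons[i].bw0 for i in order], dtype=float)
    male = np.array([persons[i].sex == "male" for i in order])
    ids = [persons[i].id for i in order]

    k = min(seed_size, n)  # number of placed nodes (prefix of arrival order)
    for i in range(k):
        for j in range(i + 1, k):
            g.add_edge(ids[i], ids[j])
    deg = np.zeros(n)
    deg[:k] = k - 1
    neighbors: List[Set[int]] = [set(range(k)) - {i} if i < k else set() for i in range(n)]

    def hweight(idx: int, upto: int) -> np.ndarray:
        w = np.where(male[:upto] == male[idx], homophily.gender_boost, 1.0)
        w = w * np.exp(-np.abs(age[:upto] - age[idx]) / homophily.age_scale)
        w = w * np.exp(-np.abs(bw[:upto] - bw[idx]) / homophily.bw_scale)
        return w

    def add_edge(i: int, j: int) -> None:
        g.add_edge(ids[i], ids[j])
        neighbors[i].add(j)
        neighbors[j].add(i)
        deg[i] += 1
        deg[j] += 1

    while k < n:
        if k >= 2 and rng.random() < density_param:
            # edge step between existing members; re-draw if the first
            # endpoint is already connected to every other member
            for _ in range(100):
                i = _choice(rng, deg[:k])
                w = deg[:k] * hweight(i, k)
                w[i] = 0.0
                if neighbors[i]:
                    w[list(neighbors[i])] = 0.0
                if w.sum() > 0:
                    add_edge(i, _choice(rng, w))
                    break
            else:  # saturated prefix: fall through to a node step
                w = deg[:k] * hweight(k, k)
                add_edge(k, _choice(rng, w))
                k += 1
        else:
            w = deg[:k] * hweight(k, k)
            add_edge(k, _choice(rng, w))
            k += 1
    return net


# ---------------------------------------------------------------------------
# centralities

def _igraph_centrality(graph: nx.Graph, kind: str) -> Dict:
    import igraph as ig

    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges]
    h = ig.Graph(n=len(nodes), edges=edges, directed=False)
    if kind == "betweenness":
        vals = h.betweenness(directed=False)
    else:
        # normalized=True is (reachable-1)/sum(dist), the within-component
        # convention; isolated nodes come back nan -> 0
        vals = h.closeness(normalized=True)
        vals = [0.0 if (v is None or math.isnan(v)) else v for v in vals]
    return {nodes[i]: float(vals[i]) for i in range(len(nodes))}


def centrality(network, kind: str) -> Dict:
    """Per-node centrality scores: ``degree``, ``betweenness`` or ``closeness``.

    Betweenness is unnormalized (each unordered pair counted once);
    closeness is computed within each connected component as
    (reachable nodes)/(sum of shortest-path distances), isolated nodes 0.
    """
    graph = network.graph if isinstance(network, SocialNetwork) else network
    if graph.number_of_nodes() == 0:
        raise ValueError("centrality of an empty network is undefined")
    if kind == "degree":
        return {v: float(d) for v, d in graph.degree()}
    if kind == "betweenness":
        if graph.number_of_nodes() > _IGRAPH_THRESHOLD:
            return _igraph_centrality(graph, "betweenness")
        return {v: float(s) for v, s in nx.betweenness_centrality(graph, normalized=False).items()}
    if kind == "closeness":
        if graph.number_of_nodes() > _IGRAPH_THRESHOLD:
            return _igraph_centrality(graph, "closeness")
        return {v: float(s) for v, s in nx.closeness_centrality(graph, wf_improved=False).items()}
    raise ValueError(f"unknown centrality kind {kind!r}")


def top_fraction(scores: Dict, fraction: float, rng) -> Set:
    """Ids of the round(fraction*n) highest-scoring nodes, random tie-break."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    n = len(scores)
    k = int(round(fraction * n))
    if k == 0:
        return set()
    items = list(scores.items())
    jitter = rng.permutation(len(items))
    ranked = sorted(zip(items, jitter), key=lambda t: (-t[0][1], t[1]))
    return {node for (node, _score), _j in ranked[:k]}
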