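"""Projection of gene sets onto directed networks.

The subnetwork construction used to instantiate a disease network from a
seed module: take the seed's overlap with the network, expand to every node
within a path length ``k`` of the overlap, and keep the largest connected
subgraph induced on those nodes. Path length here is counted on the
undirected skeleton (a "path length of two" in the source networks mixes
edge directions); the directed layer searches used by key driver analysis
live in :mod:`cicnet.keydriver` and are deliberately distinct.

Distance 0 is the seed itself, so the seed genes present in the network are
always part of their own neighborhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .containers import GeneNetwork, GeneSet

logger = logging.getLogger(__name__)

__all__ = ["Subnetwork", "neighborhood", "largest_connected", "project_seed", "kdg_subnetwork"]

_MODES = ("undirected", "downstream", "upstream")


@dataclass(frozen=True)
class Subnetwork:
    """An induced subgraph of a parent network plus how it was derived."""

    parent: GeneNetwork
    nodes: frozenset
    edges: tuple
    provenance: tuple  # (seed name, path length k, direction mode)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def as_network(self) -> GeneNetwork:
        """The subnetwork as a standalone :class:`GeneNetwork`."""
        return GeneNetwork.from_edges(
            [(u, v, d["weight"]) if "weight" in d else (u, v)
             for u, v, d in self.edges],
            nodes=self.nodes,
        )


def _frontier_bfs(graph, seed_nodes, k: int, mode: str) -> set:
    """Multi-source BFS to depth k honoring edge direction per ``mode``."""
    if mode == "downstream":
        step = graph.successors
    elif mode == "upstream":
        step = graph.predecessors
    else:
        def step(n):
            yield from graph.successors(n)
            yield from graph.predecessors(n)
    visited = set(seed_nodes)
    frontier = set(seed_nodes)
    for _ in range(k):
        nxt = set()
        for node in frontier:
            for nb in step(node):
                if nb not in visited:
                    nxt.add(nb)
        if not nxt:
            break
        visited |= nxt
        frontier = nxt
    return visited


def neighborhood(net: GeneNetwork, seed, k: int, mode: str = "undirected") -> frozenset:
    """All genes within shortest-path distance ``k`` of the seed set.

    Parameters
    ----------
    net
        The directed network.
    seed
        Gene identifiers; members absent from the network are reported via
        a logged warning and otherwise ignored.
    k
        Maximum path length, >= 1.
    mode
        ``"undirected"`` (skeleton distance), ``"downstream"``
        (parent-to-child only) or ``"upstream"``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    seed = frozenset(seed)
    present = seed & net.nodes
    missing = seed - present
    if missing:
        logger.warning("%d seed gene(s) absent from the network, e.g. %s",
                       len(missing), sorted(missing)[:5])
    if not present:
        return frozenset()
    return frozenset(_frontier_bfs(net.graph, present, k, mode))


def largest_connected(net: GeneNetwork, nodes, provenance=("", 0, "undirected")) -> Subnetwork:
    """Largest weakly connected component of the subgraph induced on ``nodes``.

    Ties on component size are broken toward the component containing the
    lexicographically smallest node, so results are stable across runs.
    """
    nodes = frozenset(nodes)
    if not nodes:
        raise ValueError("empty node set")
    extra = nodes - net.nodes
    if extra:
        raise ValueError(f"node(s) not in network: {sorted(extra)[:5]}")
    sub = net.graph.subgraph(nodes)
    import networkx as nx

    comps = list(nx.weakly_connected_components(sub))
    best = min(comps, key=lambda c: (-len(c), min(c)))
    induced = net.graph.subgraph(best)
    edges = tuple(sorted(induced.edges(data=True), key=lambda e: (e[0], e[1])))
    return Subnetwork(parent=net, nodes=frozenset(best), edges=edges, provenance=provenance)


def project_seed(net: GeneNetwork, seed: GeneSet, k: int = 2) -> Subnetwork:
    """Project a seed gene set onto the network.

    Composition of :func:`neighborhood` (undirected, depth ``k``) and
    :func:`largest_connected`. ``k=2`` is the intestinal-tissue setting,
    ``k=3`` the macrophage-component setting.
    """
    present = seed.genes & net.nodes
    if not present:
        raise ValueError(
            f"seed {seed.name!r} shares no genes with the network; "
            "check that gene identifiers use the same namespace"
        )
    nodes = neighborhood(net, seed.genes, k, mode="undirected")
    return largest_connected(net, nodes, provenance=(seed.name, k, "undirected"))


def kdg_subnetwork(net: GeneNetwork, kdgs, k: int = 3) -> Subnetwork:
    """Subnetwork centered on a set of key driver genes.

    Identical construction to :func:`project_seed` with the drivers as the
    seed; ``k=3`` suits driver-centered components, ``k=2`` the windows used
    to validate perturbation signatures.
    """
    kdgs = frozenset(kdgs)
    return project_seed(net, GeneSet(name="kdgs", genes=kdgs), k=k)
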