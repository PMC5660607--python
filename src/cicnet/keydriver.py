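"""Key driver analysis (KDA) on directed gene networks.

Given a directed network N and a gene set G, KDA asks which network nodes
sit "upstream" of G: it builds the candidate pool NG (all nodes within
``expand_k`` layers of G's overlap with N), and for every candidate g
searches its h-layer neighborhoods HLN(g, h), h = 1..H, for the layer h*
maximizing the enrichment statistic

    ES_h* = max_h ES(HLN(g, h), G)

with the full network as the enrichment universe. The enrichment statistic
is -log10 of the one-sided hypergeometric p (ties broken toward the
smaller, more parsimonious h); raw fold enrichment at h* is reported
alongside it, so either convention can be compared downstream. Maximizing
the p-based statistic rather than raw fold avoids selecting degenerate
one-layer neighborhoods whose fold is high but carries no evidence. A
candidate whose neighborhood at h* is significantly enriched (corrected
across candidates) is called a driver; significant candidates with no
parent node (network roots) are *global* drivers, the rest *local*
drivers.

The neighborhood excludes the candidate itself, preventing a gene already
in G from counting toward its own enrichment. Driver calls are additionally
restricted to network hubs — nodes whose out-degree exceeds the network
mean by at least one standard deviation — because a handful of downstream
genes falling inside G by chance can produce an extreme hypergeometric tail
from a neighborhood too small to carry regulatory evidence; the gate is
configurable and can be disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .containers import GeneNetwork
from .enrich import adjust
from .projection import _frontier_bfs, neighborhood

__all__ = ["KdaConfig", "KeyDriverResult", "build_ng", "hln", "kda", "kdg_signature"]


@dataclass(frozen=True)
class KdaConfig:
    """Tuning knobs for a KDA run.

    h_max
        Upper bound H of the layer search grid (h = 1..H). Default 3.
    alpha
        Significance level applied to corrected p-values.
    correction
        ``"bonferroni"`` (default) or ``"BH"``, applied across all
        candidates within one call.
    direction
        ``"downstream"`` searches child layers only (regulator semantics);
        ``"undirected"`` ignores direction.
    expand_k
        Undirected layers used to build the candidate pool NG around G;
        0 restricts candidates to the overlap itself.
    hub_gate
        Minimum out-degree for a candidate to be callable as a driver.
        ``"auto"`` (default) uses mean + 1 SD of the network's out-degree
        distribution; a number sets an absolute floor; ``None`` disables
        the gate. Gated-out candidates keep their statistics but are
        classed ``none``.
    """

    h_max: int = 3
    alpha: float = 0.05
    correction: str = "bonferroni"
    direction: str = "downstream"
    expand_k: int = 1
    hub_gate: object = "auto"

    def __post_init__(self):
        if self.h_max < 1:
            raise ValueError("h_max must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.direction not in ("downstream", "undirected"):
            raise ValueError(f"direction must be downstream|undirected, got {self.direction!r}")
        if self.expand_k < 0:
            raise ValueError("expand_k must be >= 0")


@dataclass
class KeyDriverResult:
    """Per-candidate outcome of a KDA run.

    ``h_star`` is the layer achieving the maximal enrichment statistic
    (-log10 p, ties broken toward the smaller, more parsimonious h);
    ``es`` the fold enrichment there; ``driver_class`` one of
    global/local/none.
    """

    gene: str
    h_star: int
    es: float
    p: float
    p_adjusted: float
    neighborhood_size: int
    overlap: int
    driver_class: str = "none"

    COLUMNS = ("gene", "h_star", "es", "p", "p_adjusted",
               "neighborhood_size", "overlap", "driver_class")

    def as_row(self) -> tuple:
        return (self.gene, self.h_star, self.es, self.p, self.p_adjusted,
                self.neighborhood_size, self.overlap, self.driver_class)


def build_ng(net: GeneNetwork, g_set, expand_k: int) -> frozenset:
    """Candidate pool NG: nodes within ``expand_k`` undirected layers of G.

    ``expand_k=0`` returns the overlap of G with the network itself.
    """
    g_set = frozenset(g_set)
    overlap = g_set & net.nodes
    if not overlap:
        raise ValueError("gene set shares no genes with the network")
    if expand_k == 0:
        return frozenset(overlap)
    return neighborhood(net, overlap, expand_k, mode="undirected")


def hln(net: GeneNetwork, g, h: int, direction: str = "downstream") -> frozenset:
    """The h-layer neighborhood of gene ``g``, excluding ``g`` itself."""
    if not net.has_node(g):
        raise KeyError(f"gene {g!r} not in network")
    if h < 1:
        raise ValueError("h must be >= 1")
    mode = "downstream" if direction == "downstream" else "undirected"
    reached = _frontier_bfs(net.graph, {g}, h, mode)
    reached.discard(g)
    return frozenset(reached)


def _hln_layers(graph, g, h_max: int, direction: str):
    """Cumulative neighborhood sets for h = 1..h_max (each excludes g)."""
    if direction == "downstream":
        def step(n):
            return graph.successors(n)
    else:
        def step(n):
            yield from graph.successors(n)
            yield from graph.predecessors(n)
    visited = {g}
    frontier = {g}
    cumulative = set()
    out = []
    for _ in range(h_max):
        nxt = set()
        for node in frontier:
            for nb in step(node):
                if nb not in visited:
                    nxt.add(nb)
        visited |= nxt
        cumulative |= nxt
        out.append(set(cumulative))
        frontier = nxt
        if not nxt:
            # remaining layers identical
            while len(out) < h_max:
                out.append(set(cumulative))
            break
    return out


def kda(net: GeneNetwork, g_set, cfg: KdaConfig | None = None) -> list[KeyDriverResult]:
    """Run key driver analysis of gene set G against network N.

    Returns one :class:`KeyDriverResult` per candidate in NG, sorted by
    (adjusted p, -fold, gene). The enrichment universe is the full node set
    of N; the corrected significance gate uses ``cfg.alpha``.
    """
    cfg = cfg or KdaConfig()
    g_set = frozenset(g_set)
    overlap_set = g_set & net.nodes
    if not overlap_set:
        raise ValueError("gene set shares no genes with the network")
    candidates = sorted(build_ng(net, overlap_set, cfg.expand_k))
    universe_n = net.n_nodes
    k_hits = len(overlap_set)
    graph = net.graph

    if cfg.hub_gate is None:
        degree_floor = -1.0
    elif cfg.hub_gate == "auto":
        degrees = [d for _, d in graph.out_degree()]
        degree_floor = float(np.mean(degrees) + np.std(degrees))
    else:
        degree_floor = float(cfg.hub_gate)

    results = []
    for g in candidates:
        layers = _hln_layers(graph, g, cfg.h_max, cfg.direction)
        best = None  # maximize -log10 p, ties toward smaller h
        for h, layer in enumerate(layers, start=1):
            n_h = len(layer)
            ov = len(layer & overlap_set)
            if n_h == 0:
                p_h = 1.0
            else:
                p_h = float(hypergeom.sf(ov - 1, universe_n, k_hits, n_h))
                p_h = min(max(p_h, 1e-300), 1.0)
            if best is None or p_h < best[0] * (1 - 1e-12):
                best = (p_h, h, n_h, ov)
        p, h_star, n_star, ov_star = best
        expected = n_star * k_hits / universe_n
        if expected > 0:
            fold = ov_star / expected
        else:
            fold = 0.0
        results.append(KeyDriverResult(
            gene=g, h_star=h_star, es=fold, p=p, p_adjusted=p,
            neighborhood_size=n_star, overlap=ov_star,
        ))

    adjusted = adjust([r.p for r in results], method=cfg.correction)
    for r, padj in zip(results, adjusted):
        r.p_adjusted = padj
        is_hub = graph.out_degree(r.gene) > degree_floor
        if padj < cfg.alpha and r.overlap > 0 and is_hub:
            r.driver_class = "global" if net.in_degree(r.gene) == 0 else "local"
        else:
            r.driver_class = "none"
    results.sort(key=lambda r: (r.p_adjusted, -r.es, r.gene))
    return results


def kdg_signature(net: GeneNetwork, driver, k: int = 2) -> frozenset:
    """Genes the network predicts to be under a driver's control.

    The downstream nodes within directed path length ``k`` of the driver,
    excluding the driver itself. ``k=2`` matches the window used when
    validating perturbation signatures against the network.
    """
    return hln(net, driver, k, direction="downstream")
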