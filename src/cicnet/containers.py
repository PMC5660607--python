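"""Core in-memory containers shared across the pipeline.

Gene identifiers are opaque, case-sensitive strings throughout; no
symbol/accession mapping layer is provided (cross-species or cross-platform
identifier harmonisation is the caller's responsibility).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "GeneSet",
    "ModuleCollection",
    "SignatureTable",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers with an optional free-text description."""

    name: str
    genes: frozenset
    description: str = ""

    def __post_init__(self):
        if not self.name:
            raise ValueError("GeneSet requires a non-empty name")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, gene) -> bool:
        return gene in self.genes


class GeneNetwork:
    """A directed gene network with parent -> child causal edges.

    Thin wrapper around :class:`networkx.DiGraph` that enforces the
    structural invariants every downstream stage assumes: no self-loops, no
    duplicate edges (networkx collapses these on insertion; duplicates seen
    while building are reported by the readers), and edge endpoints that are
    registered nodes. Edges may carry a real ``weight`` attribute.
    """

    def __init__(self, graph: nx.DiGraph):
        loops = list(nx.nodes_with_selfloops(graph))
        if loops:
            raise ValueError(f"self-loops are not allowed: {sorted(loops)[:5]}")
        self._graph = graph

    @classmethod
    def from_edges(cls, edges: Iterable, nodes: Iterable | None = None) -> "GeneNetwork":
        """Build a network from ``(parent, child)`` or ``(parent, child, weight)`` tuples."""
        g = nx.DiGraph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for e in edges:
            if len(e) == 3:
                g.add_edge(e[0], e[1], weight=float(e[2]))
            else:
                g.add_edge(e[0], e[1])
        return cls(g)

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    @property
    def nodes(self) -> frozenset:
        return frozenset(self._graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def edges(self, data: bool = False):
        return self._graph.edges(data=data)

    def has_node(self, gene) -> bool:
        return self._graph.has_node(gene)

    def in_degree(self, gene) -> int:
        return self._graph.in_degree(gene)

    def roots(self) -> frozenset:
        """Nodes with no parents (in-degree zero)."""
        return frozenset(n for n, d in self._graph.in_degree() if d == 0)

    def __contains__(self, gene) -> bool:
        return self._graph.has_node(gene)

    def __repr__(self) -> str:
        return f"GeneNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


@dataclass
class ModuleCollection:
    """Per-cohort coexpression modules plus the cohort's expressed-gene universe.

    Invariants: every module is contained in the universe and module names
    are unique within the cohort.
    """

    cohort: str
    modules: list = field(default_factory=list)
    universe: frozenset = frozenset()

    def __post_init__(self):
        self.universe = frozenset(self.universe)
        names = [m.name for m in self.modules]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate module names in cohort {self.cohort!r}: {dupes}")
        for m in self.modules:
            extra = m.genes - self.universe
            if extra:
                raise ValueError(
                    f"module {m.name!r} contains genes outside the universe of "
                    f"cohort {self.cohort!r}: {sorted(extra)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.modules)


class SignatureTable:
    """A differential-expression (or trait-correlation) gene signature.

    Rows carry a signed effect, a raw p-value and a multiplicity-adjusted
    p-value per gene; gene identifiers are unique.
    """

    COLUMNS = ("gene", "effect", "p_value", "adjusted_p")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"signature table missing columns: {missing}")
        frame = frame.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if frame["gene"].duplicated().any():
            dupes = frame.loc[frame["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"duplicate genes in signature: {dupes[:5]}")
        for col in ("p_value", "adjusted_p"):
            vals = frame[col].to_numpy()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{col} outside [0, 1]")
        self.frame = frame

    @property
    def genes(self) -> frozenset:
        return frozenset(self.frame["gene"])

    def significant(self, alpha: float = 0.05, adjusted: bool = True) -> frozenset:
        """Genes passing the significance gate (adjusted p by default)."""
        col = "adjusted_p" if adjusted else "p_value"
        return frozenset(self.frame.loc[self.frame[col] < alpha, "gene"])

    def effect_of(self, gene) -> float:
        row = self.frame.loc[self.frame["gene"] == gene, "effect"]
        if row.empty:
            raise KeyError(gene)
        return float(row.iloc[0])

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        return f"SignatureTable(n_genes={len(self)})"
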