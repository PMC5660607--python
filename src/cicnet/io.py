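"""Readers and writers for every on-disk format the pipeline touches.

Formats are deliberately plain text: tab-separated edge lists, Cytoscape
SIF, GMT gene-set collections, TSV matrices with gene/variant row labels
and sample column labels, TSV signature tables, and a key-value truth file
for synthetic ground truth. All writers emit a ``#``-prefixed header
comment carrying the tool version and the writing parameters; all readers
skip ``#`` lines.

Missing values are rejected rather than imputed: every downstream statistic
assumes complete data, so an ``NA`` cell is a hard parse error.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import GeneNetwork, GeneSet, ModuleCollection, SignatureTable

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

__all__ = [
    "read_network",
    "write_network",
    "read_gmt",
    "write_gmt",
    "read_matrix",
    "write_matrix",
    "read_signature",
    "write_signature",
    "read_module_collection",
    "write_module_collection",
    "read_truth",
    "write_truth",
]


class ParseError(ValueError):
    """A file failed to parse; the message names the offending line."""


def _header(kind: str, params: str = "") -> str:
    extra = f" {params}" if params else ""
    return f"# cicnet v{__version__} {kind}{extra}\n"


def _data_lines(path):
    """Yield (line_number, stripped_line) skipping comments and blanks."""
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield i, line


def read_network(path, dialect: str = "edge-list") -> GeneNetwork:
    """Read a directed network from a tab-separated edge list or SIF file.

    Edge-list lines are ``parent<TAB>child[<TAB>weight]``; SIF lines are
    ``source<TAB>relation<TAB>target [target ...]`` (the relation label is
    ignored). Duplicate edges are collapsed with a logged warning; a
    self-loop is a validation error.
    """
    if dialect not in ("edge-list", "sif"):
        raise ValueError(f"unknown network dialect: {dialect!r}")
    g = nx.DiGraph()
    n_dupes = 0

    def add_edge(parent, child, lineno, weight=None):
        nonlocal n_dupes
        if parent == child:
            raise ParseError(f"{path}:{lineno}: self-loop on {parent!r}")
        if g.has_edge(parent, child):
            n_dupes += 1
        elif weight is None:
            g.add_edge(parent, child)
        else:
            g.add_edge(parent, child, weight=weight)

    for lineno, line in _data_lines(path):
        fields = line.split("\t") if "\t" in line else line.split()
        if dialect == "edge-list":
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'parent<TAB>child[<TAB>weight]'")
            weight = None
            if len(fields) >= 3:
                try:
                    weight = float(fields[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad weight {fields[2]!r}") from exc
            add_edge(fields[0], fields[1], lineno, weight)
        else:  # SIF
            if len(fields) == 1:
                g.add_node(fields[0])
                continue
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: SIF needs 'source relation target...'")
            src = fields[0]
            for target in fields[2:]:
                add_edge(src, target, lineno)
    if n_dupes:
        logger.warning("%s: collapsed %d duplicate edge(s)", path, n_dupes)
    return GeneNetwork(g)


def write_network(net: GeneNetwork, path, params: str = "") -> None:
    """Write a network as a tab-separated edge list (with weights where present)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header("edge-list", params))
        for u, v, data in sorted(net.edges(data=True)):
            w = data.get("weight")
            if w is None:
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u}\t{v}\t{w:.6g}\n")


def read_gmt(path) -> list:
    """Read a GMT file: one gene set per line, ``name<TAB>description<TAB>gene...``."""
    sets = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
        name, desc, genes = fields[0], fields[1], fields[2:]
        genes = [gene for gene in genes if gene]
        unique = list(dict.fromkeys(genes))
        if len(unique) != len(genes):
            logger.warning("%s:%d: deduplicated %d repeated gene(s) in %r",
                           path, lineno, len(genes) - len(unique), name)
        sets.append(GeneSet(name=name, genes=frozenset(unique), description=desc))
    return sets


def write_gmt(gene_sets, path, params: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header("gmt", params))
        for gs in gene_sets:
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{gs.description}\t{genes}\n")


def read_matrix(path) -> pd.DataFrame:
    """Read a labeled numeric TSV matrix (first row sample ids, first column row ids).

    Non-numeric cells (including ``NA``) and duplicate row/column labels are
    hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise ParseError(f"{path}: duplicate row label(s): {dupes[:5]}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise ParseError(f"{path}: duplicate column label(s): {dupes[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy(dtype=float, na_value=np.nan))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: non-numeric or missing value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return numeric


def write_matrix(df: pd.DataFrame, path, params: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header("matrix", params))
        df.to_csv(fh, sep="\t", lineterminator="\n")


def read_signature(path) -> SignatureTable:
    """Read a TSV signature table with columns gene, effect, p_value, adjusted_p."""
    df = pd.read_csv(path, sep="\t", comment="#")
    try:
        return SignatureTable(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_signature(sig: SignatureTable, path, params: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header("signature", params))
        sig.frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_module_collection(path, cohort: str | None = None) -> ModuleCollection:
    """Read a cohort's modules from GMT; the set named ``__universe__`` is the universe.

    If no universe set is present the union of all modules is used, with a
    logged warning.
    """
    sets = read_gmt(path)
    universe = None
    modules = []
    for gs in sets:
        if gs.name == "__universe__":
            universe = gs.genes
        else:
            modules.append(gs)
    if universe is None:
        universe = frozenset().union(*(m.genes for m in modules)) if modules else frozenset()
        logger.warning("%s: no __universe__ set; using union of modules", path)
    if cohort is None:
        cohort = Path(path).stem
    return ModuleCollection(cohort=cohort, modules=modules, universe=universe)


def write_module_collection(collection: ModuleCollection, path, params: str = "") -> None:
    sets = list(collection.modules) + [
        GeneSet("__universe__", collection.universe, "expressed-gene universe")
    ]
    write_gmt(sets, path, params=params or f"cohort={collection.cohort}")


def write_truth(truth, path) -> None:
    """Write synthetic ground truth in a line-oriented key-value text format.

    Record types (tab-separated): ``rng_seed``, ``noise_sd``, ``hub``,
    ``driver``, ``seed_module`` (one gene per line), ``intercept gene
    value``, ``edge parent child weight``, ``cis variant gene beta``.
    """
    sem = truth.sem
    with open(path, "w") as fh:
        fh.write(_header("truth"))
        fh.write(f"rng_seed\t{truth.rng_seed}\n")
        fh.write(f"noise_sd\t{sem.noise_sd!r}\n")
        for hub in sem.hubs:
            fh.write(f"hub\t{hub}\n")
        for gene in sorted(truth.planted_drivers):
            fh.write(f"driver\t{gene}\n")
        for gene in sorted(truth.seed_module):
            fh.write(f"seed_module\t{gene}\n")
        for gene in sem.genes:
            fh.write(f"intercept\t{gene}\t{sem.intercepts[gene]!r}\n")
        for u, v, d in sorted(sem.graph.edges(data=True)):
            fh.write(f"edge\t{u}\t{v}\t{d['weight']!r}\n")
        for variant, (gene, beta) in sorted(truth.cis_effects.items()):
            fh.write(f"cis\t{variant}\t{gene}\t{beta!r}\n")


def read_truth(path):
    """Read a ground-truth file written by :func:`write_truth`."""
    import networkx as nx

    from .synthetic import SemModel, SyntheticTruth

    rng_seed, noise_sd = 0, 1.0
    hubs, drivers, seed_module = [], set(), set()
    intercepts, cis_effects = {}, {}
    graph = nx.DiGraph()
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        kind = fields[0]
        try:
            if kind == "rng_seed":
                rng_seed = int(fields[1])
            elif kind == "noise_sd":
                noise_sd = float(fields[1])
            elif kind == "hub":
                hubs.append(fields[1])
            elif kind == "driver":
                drivers.add(fields[1])
            elif kind == "seed_module":
                seed_module.add(fields[1])
            elif kind == "intercept":
                intercepts[fields[1]] = float(fields[2])
                graph.add_node(fields[1])
            elif kind == "edge":
                graph.add_edge(fields[1], fields[2], weight=float(fields[3]))
            elif kind == "cis":
                cis_effects[fields[1]] = (fields[2], float(fields[3]))
            else:
                raise ParseError(f"{path}:{lineno}: unknown record type {kind!r}")
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: malformed {kind!r} record") from exc
    sem = SemModel(graph=graph, noise_sd=noise_sd, intercepts=intercepts,
                   hubs=tuple(hubs))
    return SyntheticTruth(sem=sem, planted_drivers=frozenset(drivers),
                          seed_module=frozenset(seed_module),
                          cis_effects=cis_effects, rng_seed=rng_seed)
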