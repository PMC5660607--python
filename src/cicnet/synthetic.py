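"""Synthetic networks, expression, genotypes and perturbation signatures.

The generators emulate the statistical structure the pipeline assumes about
real cohort data:

* a sparse directed acyclic gene network in which a small number of hub
  regulators sit at the roots and jointly control a shared downstream
  *program* of genes (master regulators of a coexpressed disease module),
  on top of a sparsely wired background;
* expression produced by a linear structural equation model (each gene =
  intercept + weighted sum of parents + homoscedastic Gaussian noise,
  evaluated in topological order);
* cis genetic effects that shift a target gene's intercept by
  beta x allele dosage on a synthetic 1-based linear coordinate system;
* gene knockouts modeled as clamp-to-zero interventions (the do-operator:
  incoming edges are ignored and the gene is fixed at zero in the knockout
  arm), whose effects propagate to network descendants as sums over
  directed paths of products of edge weights;
* per-cohort module collections containing a contaminated copy of the
  planted seed module plus decoy modules, with slightly differing
  expressed-gene universes across cohorts (platform differences).

Every generator is bit-reproducible from its parameters and ``rng_seed``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .containers import GeneNetwork, GeneSet, ModuleCollection, SignatureTable
from .enrich import adjust

logger = logging.getLogger(__name__)

__all__ = [
    "SemModel",
    "SyntheticTruth",
    "generate_dag",
    "synthesize_truth",
    "simulate_expression",
    "simulate_knockout",
    "simulate_genotypes_and_cis",
    "expression_with_genetics",
    "generate_module_collections",
]


@dataclass
class SemModel:
    """A linear-Gaussian structural equation model on a gene DAG.

    ``graph`` is a directed acyclic :class:`networkx.DiGraph` whose edges
    carry a signed real ``weight``; ``intercepts`` maps gene -> baseline
    expression; ``noise_sd`` is the per-gene homoscedastic noise standard
    deviation. ``hubs`` records the designated root regulators.
    """

    graph: nx.DiGraph
    noise_sd: float
    intercepts: dict
    hubs: tuple = ()

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("SEM graph must be acyclic")
        for u, v, d in self.graph.edges(data=True):
            w = d.get("weight")
            if w is None or not math.isfinite(w):
                raise ValueError(f"edge {u}->{v} lacks a finite weight")

    @property
    def edge_weights(self) -> dict:
        return {(u, v): d["weight"] for u, v, d in self.graph.edges(data=True)}

    @property
    def genes(self) -> list:
        return list(self.graph.nodes)

    def network(self) -> GeneNetwork:
        """The DAG as a :class:`GeneNetwork` (shares the underlying graph)."""
        return GeneNetwork(self.graph)


@dataclass
class SyntheticTruth:
    """Planted ground truth used to score every downstream pipeline stage."""

    sem: SemModel
    planted_drivers: frozenset
    seed_module: frozenset
    cis_effects: dict = field(default_factory=dict)  # variant -> (gene, beta)
    rng_seed: int = 0

    def __post_init__(self):
        nodes = set(self.sem.graph.nodes)
        if not set(self.planted_drivers) <= nodes:
            raise ValueError("planted_drivers must be network nodes")
        if not set(self.seed_module) <= nodes:
            raise ValueError("seed_module must be network nodes")
        for variant, (gene, _beta) in self.cis_effects.items():
            if gene not in nodes:
                raise ValueError(f"cis effect {variant!r} targets unknown gene {gene!r}")


def _gene_ids(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _sample_ids(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def generate_dag(
    n_genes: int,
    n_hubs: int,
    mean_out_degree: float = 2.0,
    rng_seed: int = 0,
    program_frac: float = 0.2,
    cascade_rate: float = 1.0,
    weight_range: tuple = (0.4, 1.2),
    neg_frac: float = 0.3,
    intercept_range: tuple = (4.0, 8.0),
    noise_sd: float = 1.0,
) -> SemModel:
    """Generate a hub-rooted sparse gene DAG with a shared regulatory program.

    Nodes are laid out in three tiers along a fixed topological order —
    hubs (roots with no incoming edges), a *program* pool of jointly
    regulated genes, and background genes — and every edge points from an
    earlier to a later node, so acyclicity holds by construction. Each hub
    wires to at least ``ceil(3 * mean_out_degree)`` program genes; program
    genes cascade among themselves at ``cascade_rate`` expected out-edges,
    so hub regulons overlap heavily (a shared disease program under
    multiple master regulators); background genes are wired sparsely among
    themselves to bring the overall mean out-degree toward
    ``mean_out_degree``. Edge weights are signed: magnitudes uniform on
    ``weight_range``, negative with probability ``neg_frac``. Intercepts
    (baseline expression, log2-like scale) are uniform on
    ``intercept_range``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    if n_hubs < 0:
        raise ValueError("n_hubs must be >= 0")
    if n_genes > 1 and n_hubs >= n_genes:
        raise ValueError("require n_hubs < n_genes")
    if n_genes == 1:
        rng = np.random.default_rng(rng_seed)
        g = nx.DiGraph()
        gene = _gene_ids(1)[0]
        g.add_node(gene)
        return SemModel(graph=g, noise_sd=noise_sd,
                        intercepts={gene: float(rng.uniform(*intercept_range))},
                        hubs=(gene,) if n_hubs == 1 else ())
    if mean_out_degree < 1:
        raise ValueError("mean_out_degree must be >= 1")

    rng = np.random.default_rng(rng_seed)
    ids = _gene_ids(n_genes)
    hubs = ids[:n_hubs]
    n_rest = n_genes - n_hubs
    n_program = min(n_rest, round(program_frac * n_rest))
    if n_hubs > 0:
        n_program = max(n_program, 1)
    program = ids[n_hubs:n_hubs + n_program]
    background = ids[n_hubs + n_program:]

    g = nx.DiGraph()
    g.add_nodes_from(ids)

    def draw_weight():
        w = float(rng.uniform(*weight_range))
        if rng.random() < neg_frac:
            w = -w
        return w

    # hubs -> program
    k_min = math.ceil(3 * mean_out_degree)
    for hub in hubs:
        if not program:
            break
        k = max(k_min, int(rng.poisson(3 * mean_out_degree)))
        k = min(k, len(program))
        for child in rng.choice(program, size=k, replace=False):
            g.add_edge(hub, str(child), weight=draw_weight())

    # program cascade (earlier -> later within the pool)
    for i, gene in enumerate(program):
        later = program[i + 1:]
        if not later:
            break
        k = min(int(rng.poisson(cascade_rate)), len(later))
        if k:
            for child in rng.choice(later, size=k, replace=False):
                g.add_edge(gene, str(child), weight=draw_weight())

    # background wiring sized to approach the requested overall density
    target_edges = int(round(mean_out_degree * n_genes))
    remaining = max(0, target_edges - g.number_of_edges())
    lam = remaining / len(background) if background else 0.0
    for i, gene in enumerate(background):
        later = background[i + 1:]
        if not later:
            break
        k = min(int(rng.poisson(lam)), len(later))
        if k:
            for child in rng.choice(later, size=k, replace=False):
                g.add_edge(gene, str(child), weight=draw_weight())

    intercepts = {gene: float(rng.uniform(*intercept_range)) for gene in ids}
    return SemModel(graph=g, noise_sd=noise_sd, intercepts=intercepts, hubs=tuple(hubs))


def synthesize_truth(
    n_genes: int = 500,
    n_hubs: int = 10,
    mean_out_degree: float = 2.0,
    rng_seed: int = 0,
    **dag_kwargs,
) -> SyntheticTruth:
    """Generate a DAG and plant its truth: hubs as drivers, their joint
    downstream program as the seed module."""
    sem = generate_dag(n_genes, n_hubs, mean_out_degree, rng_seed, **dag_kwargs)
    descendants = set()
    for hub in sem.hubs:
        descendants |= nx.descendants(sem.graph, hub)
    return SyntheticTruth(
        sem=sem,
        planted_drivers=frozenset(sem.hubs),
        seed_module=frozenset(descendants),
        rng_seed=rng_seed,
    )


def simulate_expression(
    sem: SemModel,
    n_samples: int,
    rng_seed: int = 0,
    clamp: dict | None = None,
    intercept_shift: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw a genes x samples expression matrix from the SEM.

    Genes are evaluated in topological order: value = intercept + sum of
    (edge weight x parent value) + N(0, noise_sd^2). ``clamp`` maps genes
    to fixed values (a do-intervention: parents are ignored, no noise).
    ``intercept_shift`` (genes x samples) adds per-sample offsets to the
    named genes' intercepts — the hook used for cis genetic effects.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    clamp = clamp or {}
    unknown = set(clamp) - set(sem.graph.nodes)
    if unknown:
        raise KeyError(f"clamp targets unknown gene(s): {sorted(unknown)[:5]}")
    rng = np.random.default_rng(rng_seed)
    samples = _sample_ids(n_samples)
    order = list(nx.topological_sort(sem.graph))
    values = {}
    for gene in order:
        if gene in clamp:
            values[gene] = np.full(n_samples, float(clamp[gene]))
            continue
        x = np.full(n_samples, sem.intercepts[gene])
        if intercept_shift is not None and gene in intercept_shift.index:
            x = x + intercept_shift.loc[gene].to_numpy(dtype=float)
        for parent in sem.graph.predecessors(gene):
            x = x + sem.graph[parent][gene]["weight"] * values[parent]
        x = x + rng.normal(0.0, sem.noise_sd, size=n_samples)
        values[gene] = x
    out = pd.DataFrame(
        np.vstack([values[gene] for gene in sem.genes]),
        index=sem.genes, columns=samples,
    )
    if not np.all(np.isfinite(out.to_numpy())):
        raise FloatingPointError("non-finite expression values generated")
    return out


def simulate_knockout(
    sem: SemModel,
    target,
    n_samples: int = 100,
    rng_seed: int = 0,
    alpha: float = 0.05,
) -> SignatureTable:
    """Differential-expression signature of a clamp-to-zero knockout.

    Simulates paired wild-type and knockout cohorts (``n_samples`` each;
    the target is clamped to zero in the knockout arm), applies a Welch
    t-test per gene and Benjamini-Hochberg adjustment, and returns the
    full per-gene signature (effect = mean knockout - mean wild type).
    """
    if target not in sem.graph:
        raise KeyError(f"unknown knockout target {target!r}")
    seed_rng = np.random.default_rng(rng_seed)
    s_wt, s_ko = seed_rng.integers(0, 2**31, size=2)
    wt = simulate_expression(sem, n_samples, rng_seed=int(s_wt))
    ko = simulate_expression(sem, n_samples, rng_seed=int(s_ko),
                             clamp={target: 0.0})
    stat = ttest_ind(ko.to_numpy(), wt.to_numpy(), axis=1, equal_var=False)
    p = np.nan_to_num(stat.pvalue, nan=1.0)
    # the clamped target has zero variance in the knockout arm; Welch's
    # statistic is still defined but guard the degenerate all-equal case
    effect = ko.mean(axis=1) - wt.mean(axis=1)
    frame = pd.DataFrame({
        "gene": sem.genes,
        "effect": effect.to_numpy(),
        "p_value": np.clip(p, 0.0, 1.0),
        "adjusted_p": adjust(np.clip(p, 0.0, 1.0), method="BH"),
    })
    return SignatureTable(frame)


def simulate_genotypes_and_cis(
    sem: SemModel,
    n_variants: int,
    maf_range: tuple = (0.05, 0.5),
    beta_range: tuple = (0.3, 1.0),
    n_samples: int = 200,
    rng_seed: int = 0,
    cis_fraction: float = 0.5,
    truth: SyntheticTruth | None = None,
    gene_spacing: int = 2_500_000,
    gene_span: int = 10_000,
):
    """Simulate dosage genotypes plus planted cis effects on expression.

    Genes are placed on a synthetic linear chromosome ``chr1`` (1-based,
    ``gene_spacing`` apart, each spanning ``gene_span`` bases). Dosages are
    Binomial(2, maf) draws with per-variant MAF uniform on ``maf_range``.
    A ``cis_fraction`` of variants is assigned a target gene and positioned
    within ±0.9 Mb of it (inside the standard ±1 Mb cis window); their
    effect sizes are uniform on ``beta_range`` and enter expression as
    beta x dosage added to the target gene's intercept per sample (see
    :func:`expression_with_genetics`). The remaining variants are placed on
    ``chr2`` and carry no effect.

    Returns ``(genotypes, gene_coords, variant_coords, truth)`` with the
    truth's ``cis_effects`` filled in.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("MAF range must satisfy 0 < low <= high <= 0.5")
    if n_variants < 1 or n_samples < 1:
        raise ValueError("n_variants and n_samples must be positive")
    rng = np.random.default_rng(rng_seed)
    genes = sem.genes
    gene_coords = pd.DataFrame({
        "chrom": "chr1",
        "start": [1 + i * gene_spacing for i in range(len(genes))],
    }, index=pd.Index(genes, name="gene"))
    gene_coords["end"] = gene_coords["start"] + gene_span - 1

    width = max(4, len(str(n_variants)))
    variant_ids = [f"V{i:0{width}d}" for i in range(1, n_variants + 1)]
    n_cis = int(round(cis_fraction * n_variants))
    mafs = rng.uniform(lo, hi, size=n_variants)
    dosages = rng.binomial(2, mafs[:, None], size=(n_variants, n_samples))
    genotypes = pd.DataFrame(dosages.astype(float),
                             index=pd.Index(variant_ids, name="variant"),
                             columns=_sample_ids(n_samples))

    targets = rng.choice(genes, size=n_cis, replace=n_cis > len(genes))
    offsets = rng.integers(-900_000, 900_001, size=n_cis)
    betas = rng.uniform(beta_range[0], beta_range[1], size=n_cis)
    chroms, positions = [], []
    cis_effects = {}
    for i, vid in enumerate(variant_ids):
        if i < n_cis:
            gene = str(targets[i])
            pos = max(1, int(gene_coords.loc[gene, "start"]) + int(offsets[i]))
            chroms.append("chr1")
            positions.append(pos)
            cis_effects[vid] = (gene, float(betas[i]))
        else:
            chroms.append("chr2")
            positions.append(1 + (i - n_cis) * 50_000)
    variant_coords = pd.DataFrame({"chrom": chroms, "pos": positions},
                                  index=pd.Index(variant_ids, name="variant"))

    if truth is None:
        truth = SyntheticTruth(sem=sem, planted_drivers=frozenset(),
                               seed_module=frozenset(), rng_seed=rng_seed)
    truth = replace(truth, cis_effects=cis_effects)
    return genotypes, gene_coords, variant_coords, truth


def expression_with_genetics(
    sem: SemModel,
    genotypes: pd.DataFrame,
    cis_effects: dict,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Regenerate expression with planted cis effects.

    Each cis effect (variant -> (gene, beta)) contributes beta x dosage to
    its target gene's intercept, per sample; samples are taken from the
    genotype matrix columns.
    """
    n_samples = genotypes.shape[1]
    shift = pd.DataFrame(0.0, index=sem.genes, columns=genotypes.columns)
    for variant, (gene, beta) in cis_effects.items():
        if variant not in genotypes.index:
            raise KeyError(f"cis effect references ungenotyped variant {variant!r}")
        shift.loc[gene] += beta * genotypes.loc[variant].to_numpy(dtype=float)
    expr = simulate_expression(sem, n_samples, rng_seed=rng_seed,
                               intercept_shift=shift)
    expr.columns = genotypes.columns
    return expr


def generate_module_collections(
    truth: SyntheticTruth,
    n_cohorts: int = 3,
    contamination: float = 0.0,
    rng_seed: int = 0,
    n_decoys: int = 10,
    universe_jitter: float = 0.02,
) -> list[ModuleCollection]:
    """Per-cohort module collections containing a contaminated seed module.

    Each cohort receives one *true* module — the planted seed module with a
    ``contamination`` fraction of its genes replaced by random non-seed
    genes — plus ``n_decoys`` decoy modules drawn from genes outside the
    seed module (decoys emulate unrelated coexpression modules, which share
    essentially no genes with the disease program). Cohort universes drop a
    random ``universe_jitter`` fraction of unused genes, emulating platform
    differences; with ``contamination=0`` and ``universe_jitter=0`` the
    cross-cohort core module recovers the planted seed exactly.
    """
    if not 0 <= contamination < 1:
        raise ValueError("contamination must be in [0, 1)")
    if n_cohorts < 1:
        raise ValueError("n_cohorts must be positive")
    rng = np.random.default_rng(rng_seed)
    all_genes = sorted(truth.sem.graph.nodes)
    seed = sorted(truth.seed_module)
    non_seed = sorted(set(all_genes) - set(seed))
    collections = []
    for c in range(n_cohorts):
        cohort = f"cohort{c + 1}"
        n_drop = int(round(contamination * len(seed)))
        kept = sorted(rng.choice(seed, size=len(seed) - n_drop, replace=False))
        n_add = min(n_drop, len(non_seed))
        added = sorted(rng.choice(non_seed, size=n_add, replace=False)) if n_add else []
        true_module = GeneSet(f"{cohort}_M0", frozenset(map(str, kept)) | frozenset(map(str, added)),
                              "seed-derived module")
        modules = [true_module]
        for d in range(n_decoys):
            size = int(rng.integers(max(5, len(seed) // 2), max(6, len(seed) + 1)))
            size = min(size, len(non_seed))
            genes = frozenset(map(str, rng.choice(non_seed, size=size, replace=False)))
            modules.append(GeneSet(f"{cohort}_D{d + 1}", genes, "decoy module"))
        used = frozenset().union(*(m.genes for m in modules))
        droppable = sorted(set(all_genes) - used)
        n_jitter = int(round(universe_jitter * len(droppable)))
        dropped = set(map(str, rng.choice(droppable, size=n_jitter, replace=False))) if n_jitter else set()
        universe = frozenset(all_genes) - dropped
        collections.append(ModuleCollection(cohort=cohort, modules=modules,
                                            universe=universe))
    return collections
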