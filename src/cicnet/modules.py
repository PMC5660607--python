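"""Cross-cohort core-module derivation.

Per cohort, coexpression modules are *tagged* when they are significantly
enriched for a seed gene set (one-sided Fisher test against the cohort's
own expressed-gene universe, raw P < alpha by default). The per-cohort
union of tagged modules is that cohort's *super-module*; the intersection
of super-modules across cohorts is the *core module* — the conserved seed
representation carried forward to network projection.
"""

from __future__ import annotations

import logging

from .containers import GeneSet, ModuleCollection
from .enrich import EnrichmentResult, adjust, fisher_overlap

logger = logging.getLogger(__name__)

__all__ = ["tag_modules", "super_module", "core_module", "derive_core_module"]


def tag_modules(
    collection: ModuleCollection,
    seed: GeneSet,
    alpha: float = 0.05,
    correction: str | None = None,
) -> list[tuple[GeneSet, EnrichmentResult]]:
    """Modules significantly enriched for the seed set, with their statistics.

    Enrichment is computed against the collection's own universe; the seed
    is first restricted to that universe. ``correction`` is ``None`` (raw
    P < alpha, the default significance gate) or ``"BH"``/``"bonferroni"``.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if not collection.universe:
        raise ValueError(f"cohort {collection.cohort!r} has an empty universe")
    seed_in = seed.genes & collection.universe
    if not seed_in:
        raise ValueError(
            f"seed {seed.name!r} is disjoint from the universe of cohort "
            f"{collection.cohort!r}; check that gene identifiers use the same namespace"
        )
    scored = [
        (m, fisher_overlap(m.genes, seed_in, collection.universe))
        for m in collection.modules
    ]
    if correction:
        adjusted = adjust([r.p for _, r in scored], method=correction)
        for (_, r), padj in zip(scored, adjusted):
            r.p_adjusted = padj
        return [(m, r) for m, r in scored if r.p_adjusted < alpha or alpha >= 1]
    # alpha = 1 is an explicit tag-everything boundary (p is capped at 1)
    return [(m, r) for m, r in scored if r.p < alpha or alpha >= 1]


def super_module(tagged: list[GeneSet], cohort: str = "") -> GeneSet:
    """Union of a cohort's tagged modules, named ``<cohort>_super``."""
    if not tagged:
        raise ValueError("super_module requires at least one tagged module")
    genes = frozenset().union(*(m.genes for m in tagged))
    name = f"{cohort}_super" if cohort else "super"
    return GeneSet(name=name, genes=genes,
                   description=f"union of {len(tagged)} tagged module(s)")


def core_module(supers: list[GeneSet]) -> GeneSet:
    """Intersection of super-modules across cohorts (the conserved core)."""
    if len(supers) < 2:
        raise ValueError("core_module requires super-modules from >=2 cohorts")
    genes = frozenset(supers[0].genes)
    for s in supers[1:]:
        genes &= s.genes
    if not genes:
        logger.warning("core module is empty: the super-modules share no genes")
    cohorts = ",".join(s.name.removesuffix("_super") for s in supers)
    return GeneSet(name="core", genes=genes,
                   description=f"intersection of super-modules from {cohorts}")


def derive_core_module(
    collections: list[ModuleCollection],
    seed: GeneSet,
    alpha: float = 0.05,
    correction: str | None = None,
) -> tuple[GeneSet, dict]:
    """Full derivation: tag -> per-cohort union -> cross-cohort intersection.

    Returns the core module plus a per-cohort report mapping cohort name to
    the list of (module, EnrichmentResult) tags and the super-module.
    """
    if len(collections) < 2:
        raise ValueError("core-module derivation requires >=2 cohorts")
    report = {}
    supers = []
    for coll in collections:
        tags = tag_modules(coll, seed, alpha=alpha, correction=correction)
        if not tags:
            raise ValueError(
                f"no module in cohort {coll.cohort!r} is enriched for the seed "
                f"at alpha={alpha}"
            )
        sup = super_module([m for m, _ in tags], cohort=coll.cohort)
        supers.append(sup)
        report[coll.cohort] = {"tagged": tags, "super": sup}
    return core_module(supers), report
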