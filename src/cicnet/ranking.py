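"""Composite rank-ordering of key drivers across disease-evidence gene sets.

Each driver's network-predicted target set (its bounded downstream
neighborhood) is tested for overlap with every disease trait gene set;
within a trait, drivers are ranked by ascending enrichment p (average rank
on ties), ranks are normalized by the driver count to [0, 1], and the
composite score is the mean normalized rank across traits. Drivers are then
ordered by ascending composite score. A driver with no evidence for a trait
(an empty predicted set) receives the worst normalized rank for that trait,
so uninformative drivers are never rewarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .containers import GeneNetwork, GeneSet
from .enrich import EnrichmentResult, fisher_overlap
from .keydriver import kdg_signature

__all__ = ["RankedDriver", "trait_evidence", "composite_rank"]


@dataclass
class RankedDriver:
    """A driver's per-trait evidence and its composite placement."""

    gene: str
    per_trait_p: dict = field(default_factory=dict)
    per_trait_rank: dict = field(default_factory=dict)  # normalized to (0, 1]
    composite: float = 1.0
    final_rank: int = 0


def trait_evidence(
    net: GeneNetwork,
    driver,
    trait_sets: list[GeneSet],
    universe,
    k: int = 2,
) -> dict[str, EnrichmentResult]:
    """Per-trait overlap of a driver's predicted target set.

    For each trait gene set, Fisher overlap of ``kdg_signature(driver, k)``
    with the trait set (both restricted to the universe).
    """
    if not net.has_node(driver):
        raise KeyError(f"driver {driver!r} not in network")
    universe = frozenset(universe)
    signature = kdg_signature(net, driver, k=k) & universe
    out = {}
    for trait in trait_sets:
        out[trait.name] = fisher_overlap(signature, trait.genes & universe, universe)
    return out


def composite_rank(
    evidence: dict[str, dict[str, EnrichmentResult]],
    mode: str = "equal",
) -> list[RankedDriver]:
    """Aggregate per-trait enrichments into a final driver ordering.

    Parameters
    ----------
    evidence
        Mapping driver -> trait -> EnrichmentResult.
    mode
        ``"equal"`` (default): composite = mean of normalized per-trait
        ranks, all traits weighted equally. ``"impact_weighted"``: adds a
        network-impact track — drivers ranked by descending predicted-target
        set size — averaged in alongside the trait tracks, so drivers with a
        larger network footprint are favored at equal disease support.

    Returns
    -------
    list of RankedDriver, ordered by final_rank (1 = best). Ties on the
    composite are broken by mean raw p, then gene id, so ranks are unique
    and contiguous.
    """
    if not evidence:
        raise ValueError("empty evidence map")
    if mode not in ("equal", "impact_weighted"):
        raise ValueError(f"unknown ranking mode: {mode!r}")
    drivers = sorted(evidence)
    traits = sorted({t for ev in evidence.values() for t in ev})
    if not traits:
        raise ValueError("no trait evidence present")
    n = len(drivers)

    norm_ranks = np.ones((n, len(traits)))
    raw_p = np.ones((n, len(traits)))
    for j, trait in enumerate(traits):
        p_col = np.ones(n)
        informative = np.zeros(n, dtype=bool)
        for i, d in enumerate(drivers):
            res = evidence[d].get(trait)
            if res is not None and res.set_a_size > 0:
                p_col[i] = res.p
                informative[i] = True
        raw_p[:, j] = p_col
        # rank informative drivers by ascending p (average rank on ties);
        # uninformative drivers get the worst normalized rank outright
        ranks = np.full(n, float(n))
        if informative.any():
            ranks[informative] = rankdata(p_col[informative], method="average")
            # informative ranks run 1..n_informative; keep uninformative at n
        norm_ranks[:, j] = ranks / n

    tracks = [norm_ranks]
    if mode == "impact_weighted":
        sizes = np.zeros(n)
        for i, d in enumerate(drivers):
            any_res = next(iter(evidence[d].values()), None)
            sizes[i] = any_res.set_a_size if any_res is not None else 0
        impact = rankdata(-sizes, method="average") / n
        tracks.append(impact[:, None])
    stacked = np.hstack(tracks)
    composite = stacked.mean(axis=1)
    mean_p = raw_p.mean(axis=1)

    order = sorted(range(n), key=lambda i: (composite[i], mean_p[i], drivers[i]))
    out = []
    for rank, i in enumerate(order, start=1):
        d = drivers[i]
        out.append(RankedDriver(
            gene=d,
            per_trait_p={t: float(raw_p[i, j]) for j, t in enumerate(traits)},
            per_trait_rank={t: float(norm_ranks[i, j]) for j, t in enumerate(traits)},
            composite=float(composite[i]),
            final_rank=rank,
        ))
    return out
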