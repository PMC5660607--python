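"""Gene-set overlap statistics.

One-sided (over-enrichment) Fisher/hypergeometric tests, fold enrichment,
multiple-testing corrections, and the perturbation-signature validation
statistic. Every enrichment reported anywhere in the pipeline — module
tagging, key driver calling, driver ranking, knockout validation — routes
through :func:`fisher_overlap`, so the conventions (one-sided "greater"
tail, fold = observed / expected overlap under independence) are uniform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import SignatureTable

logger = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "fisher_overlap", "adjust", "validate_prediction"]


@dataclass
class EnrichmentResult:
    """Outcome of a 2x2 overlap test between two gene sets in a universe.

    ``fold`` is observed / expected overlap where the expected overlap under
    independence is ``set_a_size * set_b_size / universe_size``; it is
    ``inf`` when the expectation is zero but an overlap was observed, and
    0.0 when both are zero. ``p`` is the one-sided (greater) hypergeometric
    tail probability P(X >= overlap).
    """

    set_a_size: int
    set_b_size: int
    universe_size: int
    overlap: int
    fold: float
    p: float
    p_adjusted: float | None = None

    def significant(self, alpha: float = 0.05) -> bool:
        p = self.p_adjusted if self.p_adjusted is not None else self.p
        return p < alpha


def _check_contained(name: str, s: frozenset, universe: frozenset) -> None:
    extra = s - universe
    if extra:
        shown = sorted(extra)[:10]
        raise ValueError(
            f"set {name!r} contains {len(extra)} gene(s) outside the universe, "
            f"e.g. {shown}"
        )


def fisher_overlap(a: Iterable, b: Iterable, universe: Iterable) -> EnrichmentResult:
    """One-sided Fisher's exact test for the overlap of two gene sets.

    Parameters
    ----------
    a, b
        Gene sets; both must be contained in ``universe``.
    universe
        Background gene universe (non-empty).

    Returns
    -------
    EnrichmentResult
        Fold enrichment and the hypergeometric upper-tail p-value
        P(X >= |a ∩ b|) with X ~ Hypergeom(|U|, |a|, |b|).
    """
    a, b, universe = frozenset(a), frozenset(b), frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    _check_contained("a", a, universe)
    _check_contained("b", b, universe)
    n_u, n_a, n_b = len(universe), len(a), len(b)
    overlap = len(a & b)
    expected = n_a * n_b / n_u
    if expected > 0:
        fold = overlap / expected
    else:
        fold = math.inf if overlap > 0 else 0.0
    # sf(k-1) = P(X >= k); exact for the hypergeometric
    p = float(hypergeom.sf(overlap - 1, n_u, n_a, n_b))
    p = min(max(p, 0.0), 1.0) or float(np.nextafter(0, 1))
    return EnrichmentResult(n_a, n_b, n_u, overlap, fold, p)


def adjust(p_values: Sequence[float], method: str = "bonferroni") -> list[float]:
    """Multiple-testing correction, order-preserving and clipped to [0, 1].

    ``method`` is ``"bonferroni"`` or ``"BH"`` (Benjamini–Hochberg step-up).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh", "fdr_bh": "fdr_bh"}.get(
        method.lower()
    )
    if key is None:
        raise ValueError(f"unknown correction method: {method!r}")
    adjusted = multipletests(p, method=key)[1]
    return np.clip(adjusted, 0.0, 1.0).tolist()


def validate_prediction(
    predicted: Iterable,
    observed_signature: SignatureTable,
    universe: Iterable,
    alpha: float = 0.05,
    adjusted: bool = True,
    exclude: Iterable = (),
) -> EnrichmentResult:
    """Test whether an observed perturbation signature hits its predicted targets.

    The network-validation statistic: the signature is filtered to its
    significant genes (adjusted p < ``alpha`` by default), restricted to the
    universe, and tested for overlap with the network-predicted target set
    by :func:`fisher_overlap`. Genes named in ``exclude`` (typically the
    perturbed gene itself, which is trivially differential) are dropped from
    the significant set before testing.

    An empty significant signature yields a zero-overlap result with p = 1
    and a logged warning rather than an error.
    """
    predicted = frozenset(predicted)
    universe = frozenset(universe)
    _check_contained("predicted", predicted, universe)
    sig = observed_signature.significant(alpha=alpha, adjusted=adjusted)
    sig -= frozenset(exclude)
    dropped = len(sig - universe)
    if dropped:
        logger.warning(
            "%d significant signature gene(s) absent from the universe were dropped",
            dropped,
        )
    sig &= universe
    if not sig:
        logger.warning("signature has no significant genes after filtering; overlap test degenerate")
        return EnrichmentResult(len(predicted), 0, len(universe), 0, 0.0, 1.0)
    return fisher_overlap(predicted, sig, universe)
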