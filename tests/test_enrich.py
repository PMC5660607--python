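"""Overlap statistics: exact-oracle agreement, symmetry, corrections."""

import math
from fractions import Fraction

import numpy as np
import pytest

from cicnet import SignatureTable, adjust, fisher_overlap, validate_prediction


def hypergeom_tail_exact(n_universe, n_a, n_b, k_min) -> float:
    """Independent oracle: exhaustive upper tail sum P(X >= k_min) in exact
    rational arithmetic, X ~ Hypergeom(n_universe, n_a, n_b)."""
    denom = math.comb(n_universe, n_b)
    total = Fraction(0)
    for k in range(max(k_min, 0), min(n_a, n_b) + 1):
        total += Fraction(math.comb(n_a, k) * math.comb(n_universe - n_a, n_b - k),
                          denom)
    return float(min(total, Fraction(1)))


def _random_config(rng):
    n_u = int(rng.integers(5, 501))
    n_a = int(rng.integers(1, n_u + 1))
    n_b = int(rng.integers(1, n_u + 1))
    universe = [f"g{i}" for i in range(n_u)]
    a = set(rng.choice(universe, size=n_a, replace=False))
    b = set(rng.choice(universe, size=n_b, replace=False))
    return a, b, set(universe)


def test_fisher_p_matches_exact_tail_sum_on_random_configurations():
    """Implementation p equals the exact rational tail sum to 1e-12."""
    rng = np.random.default_rng(1234)
    worst = 0.0
    for _ in range(300):
        a, b, universe = _random_config(rng)
        res = fisher_overlap(a, b, universe)
        oracle = hypergeom_tail_exact(len(universe), len(a), len(b), res.overlap)
        worst = max(worst, abs(res.p - oracle))
    assert worst < 1e-12


def test_fold_enrichment_definition():
    universe = {f"g{i}" for i in range(100)}
    a = {f"g{i}" for i in range(10)}
    b = {f"g{i}" for i in range(5, 15)}
    res = fisher_overlap(a, b, universe)
    assert res.overlap == 5
    assert res.fold == pytest.approx(5 / (10 * 10 / 100))  # == 5.0


def test_disjoint_sets_give_p_one_and_zero_fold():
    universe = {f"g{i}" for i in range(20)}
    res = fisher_overlap({"g0", "g1"}, {"g5", "g6"}, universe)
    assert res.overlap == 0
    assert res.p == pytest.approx(1.0)
    assert res.fold == 0.0


def test_symmetry_in_arguments():
    rng = np.random.default_rng(7)
    for _ in range(20):
        a, b, universe = _random_config(rng)
        r1 = fisher_overlap(a, b, universe)
        r2 = fisher_overlap(b, a, universe)
        assert r1.p == pytest.approx(r2.p, rel=1e-12)
        assert r1.fold == pytest.approx(r2.fold, rel=1e-12)


def test_sets_outside_universe_rejected():
    with pytest.raises(ValueError, match="outside the universe"):
        fisher_overlap({"x"}, {"g0"}, {"g0", "g1"})


def test_null_p_distribution_is_conservative():
    """Resampling b at random, P(p < alpha) <= alpha (stochastically)."""
    rng = np.random.default_rng(99)
    universe = [f"g{i}" for i in range(200)]
    a = set(universe[:30])
    hits = 0
    n_rep = 400
    for _ in range(n_rep):
        b = set(rng.choice(universe, size=40, replace=False))
        if fisher_overlap(a, b, set(universe)).p < 0.05:
            hits += 1
    # binomial 99.9% upper bound at p=0.05
    assert hits / n_rep <= 0.05 + 3.29 * math.sqrt(0.05 * 0.95 / n_rep)


@pytest.mark.parametrize("method,p_in,expected", [
    ("bonferroni", [0.01], [0.01]),
    ("bonferroni", [0.01, 0.02, 0.03], [0.03, 0.06, 0.09]),
    ("bonferroni", [0.5, 0.9], [1.0, 1.0]),
])
def test_adjust_bonferroni(method, p_in, expected):
    assert adjust(p_in, method) == pytest.approx(expected)


def test_adjust_bh_monotone_in_rank_order():
    rng = np.random.default_rng(3)
    p = rng.uniform(size=50)
    adjusted = np.asarray(adjust(p, "BH"))
    order = np.argsort(p)
    assert np.all(np.diff(adjusted[order]) >= -1e-12)
    assert np.all((adjusted >= p - 1e-12) & (adjusted <= 1.0))


def test_adjust_rejects_out_of_range():
    with pytest.raises(ValueError):
        adjust([0.5, 1.5])


def _signature(genes, p):
    import pandas as pd

    return SignatureTable(pd.DataFrame({
        "gene": genes, "effect": [1.0] * len(genes),
        "p_value": p, "adjusted_p": p,
    }))


def test_validate_prediction_filters_and_tests():
    universe = {f"g{i}" for i in range(50)}
    predicted = {f"g{i}" for i in range(10)}
    sig = _signature([f"g{i}" for i in range(12)],
                     [0.001] * 10 + [0.9, 0.9])
    res = validate_prediction(predicted, sig, universe, alpha=0.05)
    assert res.set_b_size == 10  # only significant genes tested
    assert res.overlap == 10
    assert res.p < 1e-6


def test_validate_prediction_empty_signature_warns_not_errors(caplog):
    universe = {f"g{i}" for i in range(10)}
    sig = _signature(["g0", "g1"], [0.9, 0.8])
    res = validate_prediction({"g2"}, sig, universe, alpha=0.05)
    assert res.overlap == 0 and res.p == 1.0


def test_validate_prediction_excludes_perturbed_gene():
    universe = {f"g{i}" for i in range(10)}
    sig = _signature(["g0", "g1"], [0.001, 0.001])
    res = validate_prediction({"g0", "g1"}, sig, universe, exclude={"g0"})
    assert res.set_b_size == 1
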