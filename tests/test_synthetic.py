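"""Synthetic generators: determinism, acyclicity, closed-form propagation."""

import networkx as nx
import numpy as np
import pytest

from cicnet import (
    SemModel,
    generate_dag,
    generate_module_collections,
    simulate_expression,
    simulate_genotypes_and_cis,
    simulate_knockout,
    synthesize_truth,
)


def _chain_sem(weights=(2.0, 1.5), noise_sd=1e-9, intercept=5.0):
    g = nx.DiGraph()
    names = [chr(ord("A") + i) for i in range(len(weights) + 1)]
    for i, w in enumerate(weights):
        g.add_edge(names[i], names[i + 1], weight=w)
    return SemModel(graph=g, noise_sd=noise_sd,
                    intercepts={n: intercept for n in names})


def test_single_node_graph_degenerate_case():
    sem = generate_dag(1, 0, mean_out_degree=1.0, rng_seed=0)
    assert sem.graph.number_of_nodes() == 1
    assert sem.graph.number_of_edges() == 0


def test_generate_dag_deterministic_under_seed():
    a = generate_dag(500, 10, rng_seed=7)
    b = generate_dag(500, 10, rng_seed=7)
    assert sorted(a.graph.edges(data="weight")) == sorted(b.graph.edges(data="weight"))
    assert a.intercepts == b.intercepts


def test_generate_dag_is_acyclic_with_root_hubs():
    """Independent cycle check by depth-first search; hubs are unparented
    and meet the out-degree floor."""
    sem = generate_dag(500, 10, mean_out_degree=2.0, rng_seed=3)
    order = {n: i for i, n in enumerate(nx.dfs_postorder_nodes(sem.graph))}
    assert all(order[u] > order[v] for u, v in sem.graph.edges)  # DFS cycle test
    assert nx.is_directed_acyclic_graph(sem.graph)
    for hub in sem.hubs:
        assert sem.graph.in_degree(hub) == 0
        assert sem.graph.out_degree(hub) >= 3 * 2.0


def test_generate_dag_rejects_bad_parameters():
    with pytest.raises(ValueError):
        generate_dag(0, 0)
    with pytest.raises(ValueError):
        generate_dag(10, 10)
    with pytest.raises(ValueError):
        generate_dag(10, 2, mean_out_degree=0.5)


def test_expression_linear_propagation_in_noiseless_limit():
    """B ~= w_AB * A + intercept along a chain when noise -> 0."""
    sem = _chain_sem(weights=(2.0,), noise_sd=1e-9, intercept=0.0)
    # intercept 0: B = 2 * A exactly in the limit
    expr = simulate_expression(sem, 50, rng_seed=1)
    np.testing.assert_allclose(expr.loc["B"], 2 * expr.loc["A"], atol=1e-6)


def test_expression_deterministic_and_finite():
    sem = generate_dag(100, 4, rng_seed=2)
    e1 = simulate_expression(sem, 30, rng_seed=9)
    e2 = simulate_expression(sem, 30, rng_seed=9)
    assert e1.equals(e2)
    assert np.isfinite(e1.to_numpy()).all()


def test_unconnected_genes_uncorrelated():
    g = nx.DiGraph()
    g.add_nodes_from(["A", "B"])
    sem = SemModel(graph=g, noise_sd=1.0, intercepts={"A": 0.0, "B": 0.0})
    expr = simulate_expression(sem, 10_000, rng_seed=11)
    r = np.corrcoef(expr.loc["A"], expr.loc["B"])[0, 1]
    assert abs(r) < 0.05


def test_knockout_effect_matches_path_weight_product():
    """Clamping A to 0 shifts C by (sum over paths of weight products) x mean(A)."""
    sem = _chain_sem(weights=(2.0, 1.5), noise_sd=0.3, intercept=5.0)
    sig = simulate_knockout(sem, "A", n_samples=4000, rng_seed=13)
    # E[A] = 5; closed form: dB = -2*5 = -10, dC = -2*1.5*5 = -15
    assert sig.effect_of("B") == pytest.approx(-10.0, abs=0.15)
    assert sig.effect_of("C") == pytest.approx(-15.0, abs=0.15)
    assert sig.significant(0.05) >= {"A", "B", "C"}


def test_knockout_target_has_largest_effect():
    sem = _chain_sem(weights=(0.5, 0.5), noise_sd=0.5, intercept=6.0)
    sig = simulate_knockout(sem, "A", n_samples=500, rng_seed=14)
    effects = dict(zip(sig.frame["gene"], sig.frame["effect"].abs()))
    assert effects["A"] == max(effects.values())


def test_knockout_of_leaf_controls_type_one_error():
    """No descendants: only the target should be significant, in expectation."""
    sem = generate_dag(200, 4, rng_seed=15)
    sinks = sorted(n for n in sem.graph.nodes if sem.graph.out_degree(n) == 0)
    false_calls = []
    for i, seed in enumerate(range(5)):
        sig = simulate_knockout(sem, sinks[i], n_samples=100, rng_seed=seed)
        false_calls.append(len(sig.significant(0.05) - {sinks[i]}))
    assert np.mean(false_calls) <= 2  # BH at 0.05 over ~200 null genes


def test_knockout_unknown_target():
    sem = _chain_sem()
    with pytest.raises(KeyError):
        simulate_knockout(sem, "ZZ", 10, 0)


def test_genotypes_dosage_distribution_and_determinism():
    sem = generate_dag(20, 2, rng_seed=16)
    g1, gc, vc, truth = simulate_genotypes_and_cis(
        sem, 50, maf_range=(0.5, 0.5), beta_range=(0.1, 0.5),
        n_samples=2000, rng_seed=17)
    g2, *_ = simulate_genotypes_and_cis(
        sem, 50, maf_range=(0.5, 0.5), beta_range=(0.1, 0.5),
        n_samples=2000, rng_seed=17)
    assert g1.equals(g2)
    assert set(np.unique(g1.to_numpy())) <= {0.0, 1.0, 2.0}
    assert g1.to_numpy().mean() == pytest.approx(1.0, abs=0.02)  # maf 0.5


def test_cis_variants_land_inside_window():
    sem = generate_dag(30, 2, rng_seed=18)
    _, gene_coords, variant_coords, truth = simulate_genotypes_and_cis(
        sem, 40, rng_seed=19)
    for variant, (gene, beta) in truth.cis_effects.items():
        pos = variant_coords.loc[variant, "pos"]
        start, end = gene_coords.loc[gene, ["start", "end"]]
        assert variant_coords.loc[variant, "chrom"] == gene_coords.loc[gene, "chrom"]
        assert start - 1_000_000 <= pos <= end + 1_000_000


def test_genotypes_reject_bad_maf():
    sem = generate_dag(5, 1, rng_seed=20)
    with pytest.raises(ValueError):
        simulate_genotypes_and_cis(sem, 10, maf_range=(0.0, 0.6))


def test_module_collections_structure(planted_truth):
    colls = generate_module_collections(planted_truth, n_cohorts=3,
                                        contamination=0.3, rng_seed=21)
    assert len(colls) == 3
    for coll in colls:
        for m in coll.modules:
            assert m.genes <= coll.universe
        true_mod = coll.modules[0]
        kept = true_mod.genes & planted_truth.seed_module
        assert len(kept) == pytest.approx(0.7 * len(planted_truth.seed_module), abs=1)
        for decoy in coll.modules[1:]:
            assert not decoy.genes & planted_truth.seed_module


def test_module_collections_deterministic(planted_truth):
    a = generate_module_collections(planted_truth, 2, 0.2, rng_seed=22)
    b = generate_module_collections(planted_truth, 2, 0.2, rng_seed=22)
    for ca, cb in zip(a, b):
        assert ca.universe == cb.universe
        assert [m.genes for m in ca.modules] == [m.genes for m in cb.modules]


def test_synthesize_truth_plants_hub_program():
    truth = synthesize_truth(n_genes=300, n_hubs=6, rng_seed=23)
    assert truth.planted_drivers == frozenset(truth.sem.hubs)
    for hub in truth.planted_drivers:
        assert nx.descendants(truth.sem.graph, hub) <= truth.seed_module
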