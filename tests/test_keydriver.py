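"""Key driver analysis: layer search, classification, and oracle agreement."""

import math
from fractions import Fraction

import numpy as np
import pytest

from cicnet import GeneNetwork, KdaConfig, build_ng, hln, kda, kdg_signature

from test_enrich import hypergeom_tail_exact


def test_hln_chain_layers(chain_net):
    assert hln(chain_net, "A", 1) == {"B"}
    assert hln(chain_net, "A", 2) == {"B", "C"}
    assert hln(chain_net, "D", 1) == set()  # leaf, downstream
    assert hln(chain_net, "B", 1, direction="undirected") == {"A", "C"}


def test_hln_excludes_the_candidate_itself(star_net):
    got = hln(star_net, "R", 3)
    assert "R" not in got and len(got) == 10


def test_hln_unknown_gene(chain_net):
    with pytest.raises(KeyError):
        hln(chain_net, "nope", 1)


def test_build_ng_zero_expansion_is_overlap(chain_net):
    assert build_ng(chain_net, {"B", "X"}, 0) == {"B"}


def test_build_ng_saturates(chain_net):
    assert build_ng(chain_net, {"B"}, 10) == {"A", "B", "C", "D"}


def test_build_ng_matches_neighborhood_oracle():
    from test_projection import random_network, shortest_path_oracle

    rng = np.random.default_rng(31)
    for _ in range(10):
        net = random_network(rng, n_max=120)
        seed = set(np.random.default_rng(1).choice(sorted(net.nodes), 4, replace=False))
        for k in (1, 2):
            assert build_ng(net, seed, k) == shortest_path_oracle(net, seed, k,
                                                                  "undirected")


def test_star_graph_recovers_hub_as_global_driver():
    """Hub R wired to 10 of 100 genes is the unique global driver for 8 leaves."""
    background = [f"b{i}" for i in range(89)]
    net = GeneNetwork.from_edges([("R", f"m{i}") for i in range(1, 11)],
                                 nodes=background)
    g_set = {f"m{i}" for i in range(1, 9)}
    results = kda(net, g_set, KdaConfig(h_max=2, expand_k=1))
    by_gene = {r.gene: r for r in results}
    r = by_gene["R"]
    assert r.driver_class == "global"
    # exact one-sided hypergeometric tail: universe 100, hits 8, draw 10, overlap 8
    assert r.p == pytest.approx(hypergeom_tail_exact(100, 8, 10, 8), abs=1e-12)
    assert r.overlap == 8 and r.neighborhood_size == 10
    globals_ = [x for x in results if x.driver_class == "global"]
    assert [x.gene for x in globals_] == ["R"]


def test_candidate_p_matches_exact_tail_at_selected_layer(planted_truth):
    """Reported p equals the exact rational tail sum for the reported table."""
    net = planted_truth.sem.network()
    rng = np.random.default_rng(8)
    pool = sorted(planted_truth.seed_module)
    g_set = set(rng.choice(pool, size=int(0.6 * len(pool)), replace=False))
    results = kda(net, g_set, KdaConfig())
    k_hits = len(g_set & net.nodes)
    for r in results[:50]:
        if r.neighborhood_size == 0:
            assert r.p == 1.0
            continue
        oracle = hypergeom_tail_exact(net.n_nodes, k_hits,
                                      r.neighborhood_size, r.overlap)
        assert r.p == pytest.approx(oracle, abs=1e-10)


def test_h_star_maximizes_enrichment_statistic(planted_truth):
    """p at h_star is minimal (ES = -log10 p maximal) over the whole h grid."""
    from scipy.stats import hypergeom

    from cicnet.keydriver import _hln_layers

    net = planted_truth.sem.network()
    rng = np.random.default_rng(9)
    pool = sorted(planted_truth.seed_module)
    g_set = frozenset(rng.choice(pool, size=int(0.6 * len(pool)), replace=False))
    cfg = KdaConfig(h_max=3)
    results = kda(net, g_set, cfg)
    overlap_set = g_set & net.nodes
    for r in results[:40]:
        layers = _hln_layers(net.graph, r.gene, cfg.h_max, cfg.direction)
        for layer in layers:
            if not layer:
                continue
            p_h = hypergeom.sf(len(layer & overlap_set) - 1, net.n_nodes,
                               len(overlap_set), len(layer))
            assert r.p <= p_h + 1e-12


def test_global_iff_root(planted_truth):
    net = planted_truth.sem.network()
    rng = np.random.default_rng(10)
    pool = sorted(planted_truth.seed_module)
    g_set = frozenset(rng.choice(pool, size=int(0.6 * len(pool)), replace=False))
    for r in kda(net, g_set, KdaConfig()):
        if r.driver_class == "global":
            assert net.in_degree(r.gene) == 0
        elif r.driver_class == "local":
            assert net.in_degree(r.gene) > 0


def test_empty_hln_gives_p_one_and_no_class():
    net = GeneNetwork.from_edges([("A", "B")], nodes=["A", "B", "C"])
    # candidate B is a sink: empty downstream HLN at every h
    results = kda(net, {"B", "C"}, KdaConfig(expand_k=1))
    by_gene = {r.gene: r for r in results}
    assert by_gene["B"].p == 1.0
    assert by_gene["B"].driver_class == "none"


def test_output_sorted_and_deterministic(star_net):
    g_set = {f"m{i}" for i in range(1, 9)}
    r1 = kda(star_net, g_set, KdaConfig())
    r2 = kda(star_net, g_set, KdaConfig())
    assert [x.gene for x in r1] == [x.gene for x in r2]
    keys = [(x.p_adjusted, -x.es, x.gene) for x in r1]
    assert keys == sorted(keys)


def test_kda_rejects_disjoint_gene_set(chain_net):
    with pytest.raises(ValueError):
        kda(chain_net, {"X"}, KdaConfig())


def test_kdg_signature_matches_bfs_oracle():
    from test_projection import random_network

    import networkx as nx

    rng = np.random.default_rng(77)
    for _ in range(10):
        net = random_network(rng, n_max=100)
        driver = sorted(net.nodes)[0]
        for k in (1, 2, 3):
            got = kdg_signature(net, driver, k=k)
            dist = nx.single_source_shortest_path_length(net.graph, driver, cutoff=k)
            expected = {n for n, d in dist.items() if 1 <= d <= k}
            assert got == expected


def test_kdg_signature_tree_levels():
    net = GeneNetwork.from_edges([
        ("r", "a"), ("r", "b"), ("a", "c"), ("b", "d"), ("c", "e"),
    ])
    assert kdg_signature(net, "r", k=2) == {"a", "b", "c", "d"}
    assert kdg_signature(net, "e", k=2) == set()
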