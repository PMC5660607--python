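"""Plant a synthetic ground truth: a hub-rooted causal gene network.

Generates a 500-gene DAG in which 10 hub regulators jointly control a
downstream program, simulates expression from the linear SEM, and prints
the planted structure. The hubs are the drivers every downstream stage is
later scored against.
"""

import networkx as nx

from cicnet import simulate_expression, synthesize_truth

truth = synthesize_truth(n_genes=500, n_hubs=10, rng_seed=1)
sem = truth.sem

print(f"network: {sem.graph.number_of_nodes()} genes, "
      f"{sem.graph.number_of_edges()} causal edges")
print(f"planted drivers (hub roots): {sorted(truth.planted_drivers)}")
print(f"planted program (their joint descendants): {len(truth.seed_module)} genes")

expr = simulate_expression(sem, n_samples=50, rng_seed=2)
hub = sorted(truth.planted_drivers)[0]
child = next(iter(sem.graph.successors(hub)))
r = expr.loc[[hub, child]].T.corr().iloc[0, 1]
print(f"expression matrix: {expr.shape[0]} genes x {expr.shape[1]} samples")
print(f"corr({hub} -> {child}) = {r:.2f}  "
      "(causal edges leave a correlation footprint)")
depth = len(nx.dag_longest_path(sem.graph, weight=None)) - 1
print(f"longest causal path: {depth} edges")
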