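# Methods

## Overview

cicnet implements a seed-to-regulator pipeline for directed gene networks:
a conserved core module is distilled from per-cohort coexpression modules,
projected onto a directed causal network, and searched for the upstream
regulators (key driver genes, KDGs) whose bounded downstream neighborhoods
are over-enriched for the module. Drivers are then rank-ordered across
disease-evidence gene sets and validated against perturbation signatures.
Supporting statistics — a cis-eQTL scan with a permutation null and a
polygenic risk score — use the same data containers. All stages are
exercised against a synthetic generator that plants known ground truth.

## Overlap statistics

Every enrichment in the package is the one-sided ("greater")
hypergeometric tail P(X ≥ overlap), X ~ Hypergeom(|U|, |A|, |B|), i.e.,
Fisher's exact test for over-representation; under-enrichment is never
tested because no stage interprets it. Fold enrichment is
overlap / (|A||B|/|U|), reported as infinity when the expectation is zero
but an overlap exists. Multiple-testing corrections are Bonferroni and
Benjamini–Hochberg (via statsmodels). Sets are validated to lie inside the
declared universe; signature genes outside the universe are dropped with a
logged count rather than silently, since silent loss corrupts the fold
denominator.

## Core-module derivation

Per cohort, a module is *tagged* when its Fisher enrichment for the seed
set reaches raw P < α (default 0.05, no correction — a deliberately
permissive gate, since the union that follows is meant to be inclusive; an
optional BH/Bonferroni flag exists). The enrichment universe is the
cohort's own expressed-gene universe, not a global one: cohort platforms
differ, and a shared universe would bias tagging toward the
best-covered cohort. α ≥ 1 is an explicit tag-everything boundary (p-values
are capped at exactly 1, so a strict inequality would otherwise exclude
zero-overlap modules even at α = 1). The super-module is the union of a
cohort's tagged modules; the core module is the intersection of
super-modules and requires at least two cohorts. An empty intersection is
returned with a warning (the pipeline aborts at the next stage with a
clear message).

## Projection

Neighborhood expansion counts shortest-path layers on the undirected
skeleton, with the seed at distance 0; the directed layer searches inside
KDA are a separate, deliberately distinct primitive. "Connected" means
weakly connected, because realistic causal networks mix edge directions
within one functional component. Equal-size components are tie-broken
toward the one containing the lexicographically smallest node so outputs
are stable across runs. k = 2 is the default projection depth for
tissue-level networks, k = 3 for narrower cell-type components.

## Key driver analysis

Given network N and gene set G:

1. Candidate pool N_G: all nodes within `expand_k` (default 1) undirected
   layers of G ∩ N.
2. For each candidate g, the downstream (default) cumulative layer sets
   HLN(g, h), h = 1..H (default H = 3), each excluding g itself —
   excluding the candidate prevents a gene already in G from counting
   toward its own enrichment.
3. The search statistic is ES = −log10 of the hypergeometric tail p of
   HLN(g, h) against G, with the full network node set as universe; h* is
   the layer maximizing ES, ties broken toward smaller h (parsimony). Raw
   fold at h* is reported next to p so either convention can be compared.
   Maximizing fold itself was evaluated and rejected: fold peaks on tiny
   h = 1 layers where a 4-gene neighborhood with high fold carries no
   usable evidence, and the p computed there squanders the information in
   the deeper layers.
4. The p at h* is corrected across all candidates of the call (Bonferroni
   default; BH available) and gated at α (default 0.05).
5. Driver calls are restricted to network hubs: candidates whose
   out-degree exceeds the network mean by at least one standard deviation
   (`hub_gate="auto"`; a numeric floor or `None` disables it). The gate
   exists because the hypergeometric tail of a 4–6-gene neighborhood that
   happens to sit inside G is extreme, yet such a node is not a credible
   master regulator; restricting drivers to hubs is standard practice in
   key-driver analysis. Gated-out candidates keep their full statistics
   with class `none`.
6. Significant hub candidates with in-degree 0 are *global* drivers;
   the rest are *local*.

The enrichment universe is the full network rather than the projected
subnetwork: a subnetwork universe would shrink |U| non-conservatively and
inflate every enrichment. Output is sorted by (adjusted p, −fold, gene).

A driver's predicted target set ("KDG signature") is its downstream
neighborhood within k layers (default k = 2), excluding the driver.

## Composite ranking

For each disease-evidence gene set, drivers are ranked by the Fisher p of
their predicted target set against the evidence set (average rank on
ties), normalized by the number of ranked drivers. The composite is the
unweighted mean across evidence tracks — relative weights between genetic,
transcriptomic and clinical tracks are not identifiable from first
principles, so equal weighting is the default and a second mode
(`impact_weighted`) adds a network-footprint track (rank by descending
predicted-target count) for analyses that want to favor large-effect
regulators. A driver with an empty predicted set receives the worst
normalized rank in every track, so uninformative drivers are never
rewarded. Final ranks are unique and contiguous; ties on the composite
break by mean raw p, then gene id.

## Perturbation validation

The validation statistic filters the perturbation signature to its
significant genes (BH-adjusted p < α by default; raw-p filtering is a
flag), drops the perturbed gene itself (it is differential by
construction), restricts to the universe, and tests overlap with the
driver's predicted target set. An empty significant signature returns a
p = 1 result with a warning rather than an error, since a failed knockout
is an outcome, not a bug.

## eQTL model and PRS

Per gene–variant pair: y_i = α + β x_i + ε_i, ε ~ N(0, σ²), with y the
rank-based inverse-normal-transformed expression (Blom offset c = 3/8,
average ranks on ties) and x the allele dosage in {0, 1, 2}. β is the OLS
estimator; significance is the Wald t-test with n − 2 df. The scan is
fully vectorized over all pairs. Monomorphic variants are skipped with a
logged count. A pair is *cis* when the variant lies within ±1 Mb (closed
interval, 1-based) of any part of the gene's coordinate span. The
empirical null permutes the expression sample identifiers — one joint
permutation per round across all genes, preserving gene–gene correlation —
and pools the Wald p-values over 3 rounds (default); the empirical FDR at
threshold t is (mean per-round null count ≤ t) / (observed count ≤ t).
No covariates enter the printed model; a hook exists but defaults empty.
The PRS is Σ_j coefficient_j × dosage_js over the panel variants present
in the genotype matrix (the panel is trimmed to the genotyped
intersection, with a logged count); allele orientation is taken as given
in the dosage file — no strand flipping.

## Synthetic generator

The generator emulates the statistical structure the pipeline assumes
about real cohort data, not the data themselves:

- **Topology.** Three node tiers in a fixed topological order — hub roots,
  a shared *program* pool (default 20% of non-hub genes), background —
  with all edges pointing forward, so acyclicity holds by construction.
  Each hub wires to at least ⌈3 × mean_out_degree⌉ program genes; program
  genes cascade among themselves (Poisson(1) out-edges), making hub
  regulons deep and heavily overlapping — a shared disease program under
  several master regulators, which is the regime key driver analysis is
  designed for. Background genes are wired sparsely among themselves to
  bring overall density toward `mean_out_degree` (default 2.0). Edge
  weights are signed (magnitude U(0.4, 1.2), negative with probability
  0.3); intercepts U(4, 8) emulate log2-scale baseline expression;
  noise is homoscedastic Gaussian (sd 1.0). None of these distributions
  is estimated from real networks; they are conventions, chosen once.
- **Expression.** Evaluated gene-by-gene in topological order:
  intercept + Σ weight × parent + noise.
- **Knockouts.** Clamp-to-zero interventions (the do-operator: parents
  ignored, value fixed at 0) rather than edge deletion, matching the
  semantics of a gene knockout. Signatures come from Welch t-tests between
  paired wild-type/knockout cohorts with BH adjustment; the expected
  effect on a descendant equals (sum over directed paths of edge-weight
  products) × the target's wild-type mean, which the tests verify against
  simulation.
- **Genetics.** Dosages are Binomial(2, MAF) draws; genes sit on a
  synthetic linear chromosome (2.5 Mb spacing, 10 kb spans, 1-based);
  cis variants are placed within ±0.9 Mb of their target and add
  β × dosage to its intercept; null variants live on a second chromosome.
  No linkage disequilibrium is simulated.
- **Modules.** Each cohort gets the seed module with a `contamination`
  fraction of members swapped for random non-seed genes, plus decoy
  modules drawn entirely outside the seed (unrelated coexpression modules
  share essentially no genes with a disease program; this also makes
  zero-contamination recovery exact by construction). Universes drop a
  small random fraction of unused genes per cohort (platform differences).

Everything is bit-reproducible from (parameters, rng_seed).

What passing tests on this generator do **not** show: robustness to
heteroscedastic or heavy-tailed noise, to LD between variants, to feedback
loops (real biology is not acyclic), to module detection errors beyond the
uniform contamination model, or to cross-species identifier mapping —
matching is by exact case-sensitive string identity throughout.

## Benchmark conditions

The replicated experiments (`cicnet.evaluation`, also driven by
`scripts/acceptance.py` and the acceptance tests) use: 500-gene networks
with 10 planted hub roots; disease gene sets sampled at 60% of the planted
program; KDA at H = 3, expand_k = 1, Bonferroni α = 0.05, downstream
search; 50 replicates for recovery/validation/ranking and 100 for null
calibration; knockout cohorts of 100 samples per arm; eQTL calibration on
100 genes × 100 variants at n = 100 with 3 permutation rounds. The eQTL
calibration uses mutually independent genes: with network-correlated
expression, the p-values of all pairs sharing a variant are coupled and
the pooled KS uniformity check is itself miscalibrated; the target of the
experiment is the Wald test, so the clean iid null is the right design.
The ranking-placement experiment ranks every network gene (not only called
drivers), since a top-decile criterion is only meaningful against a
population an order of magnitude larger than the planted driver set.

## Numerical choices and degenerate inputs

p-values are clipped to (0, 1]; hypergeometric tails use scipy's survival
function, which the tests hold to an exact rational-arithmetic tail sum at
1e-12. ES ties use a relative 1e-12 tolerance and resolve toward smaller
h. Missing values in matrices are rejected, not imputed. Single-node
graphs, empty HLNs, empty significant signatures, disjoint super-modules
and monomorphic variants all return defined results (documented per
function) rather than raising, except where the input is unusable
(seed disjoint from universe or network, empty universe, all-identical
expression values), which raise with an actionable message.

## Known limitations

Gene identifiers are opaque strings; cross-species or cross-platform
mapping is the caller's job. Networks are inputs — no structure learning.
VCF/BAM ingestion is out of scope (dosage TSVs only). The KDA enrichment
statistic's exact form in the source method family is not published;
−log10 p with reported fold is this package's documented convention. The
hub gate's "auto" threshold (mean + 1 SD out-degree) is a heuristic; on
very small or degree-homogeneous networks it can gate out everything and
should then be set explicitly or disabled.
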