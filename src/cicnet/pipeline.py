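"""End-to-end orchestration: simulate (or ingest) -> core module ->
projection -> key driver analysis -> ranking -> validation.

A single YAML configuration drives the run; every parameter is echoed into
the run log, every intermediate artifact is written to the run directory in
a plain-text format, and a manifest of SHA-256 checksums makes runs
byte-comparable. Stage contracts are file-based, so real cohort networks
and module collections can be substituted for the simulated ones without
code changes (set the corresponding ``inputs`` paths instead of the
``simulate`` block). Stages whose outputs already exist are skipped when
``resume`` is enabled.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .containers import GeneSet
from .enrich import fisher_overlap, validate_prediction
from .keydriver import KdaConfig, kda, kdg_signature
from .modules import derive_core_module
from .projection import project_seed
from .ranking import composite_rank, trait_evidence
from .synthetic import (
    generate_module_collections,
    simulate_knockout,
    synthesize_truth,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "report", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "seed": 1,
    "resume": False,
    "simulate": {
        "n_genes": 500,
        "n_hubs": 10,
        "mean_out_degree": 2.0,
        "n_cohorts": 3,
        "contamination": 0.3,
        "n_decoys": 10,
        "universe_jitter": 0.02,
    },
    "core_module": {"alpha": 0.05, "correction": None},
    "projection": {"k": 2},
    "kda": {
        "h_max": 3,
        "alpha": 0.05,
        "correction": "bonferroni",
        "direction": "downstream",
        "expand_k": 1,
    },
    "ranking": {"k": 2, "n_traits": 3, "trait_fraction": 0.5, "mode": "equal"},
    "validation": {"k": 2, "alpha": 0.05, "n_samples": 100, "top_n": 3},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _kda_frame(results) -> pd.DataFrame:
    from .keydriver import KeyDriverResult

    return pd.DataFrame([r.as_row() for r in results],
                        columns=list(KeyDriverResult.COLUMNS))


class _Run:
    """Bookkeeping for one pipeline run: directory, log, artifacts."""

    def __init__(self, run_dir: Path, resume: bool):
        self.dir = run_dir
        self.dir.mkdir(parents=True, exist_ok=True)
        self.resume = resume
        self.artifacts: list[str] = []
        self._log_lines: list[str] = []

    def log(self, msg: str) -> None:
        logger.info(msg)
        self._log_lines.append(msg)

    def declare(self, name: str) -> Path:
        if name not in self.artifacts:
            self.artifacts.append(name)
        return self.dir / name

    def have(self, *names: str) -> bool:
        ok = all((self.dir / n).exists() for n in names)
        if ok:
            for n in names:
                self.declare(n)
        return self.resume and ok

    def finish(self) -> None:
        log_path = self.dir / "run.log"
        log_path.write_text("\n".join(self._log_lines) + "\n")
        manifest = {
            "artifacts": {name: _sha256(self.dir / name) for name in sorted(self.artifacts)},
        }
        (self.dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def run_pipeline(config, run_dir=None) -> Path:
    """Execute the full analysis under one configuration.

    ``config`` is a path to a YAML file or a dict; unspecified keys fall
    back to :data:`DEFAULT_CONFIG`. Returns the run directory, which holds
    every intermediate artifact, ``run.log`` (full parameter echo) and
    ``manifest.json`` (SHA-256 of each artifact).
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULT_CONFIG, config)
    seed = int(cfg["seed"])
    run_dir = Path(run_dir or cfg.get("run_dir", "cicnet_run"))
    run = _Run(run_dir, resume=bool(cfg.get("resume", False)))
    run.log("config: " + json.dumps(cfg, sort_keys=True, default=str))

    rng = np.random.default_rng(seed)
    stage_seeds = {name: int(s) for name, s in zip(
        ("simulate", "modules", "traits", "validation"),
        rng.integers(0, 2**31, size=4),
    )}

    # --- stage: simulate (or ingest) -------------------------------------
    inputs = cfg.get("inputs") or {}
    sim = cfg["simulate"]
    net_path = run.declare("network.tsv")
    truth_path = run.declare("truth.txt")
    seed_path = run.declare("seed.gmt")
    cohort_names = []
    if inputs:
        raise_if_missing = [k for k in ("network", "seed", "modules") if k not in inputs]
        if raise_if_missing:
            raise ValueError(f"stage simulate/ingest: missing input path(s) {raise_if_missing}")
        net = cio.read_network(inputs["network"])
        seed_set = cio.read_gmt(inputs["seed"])[0]
        collections = [cio.read_module_collection(p) for p in inputs["modules"]]
        truth = None
        cio.write_network(net, net_path, params=f"ingested from {inputs['network']}")
        cio.write_gmt([seed_set], seed_path)
        for coll in collections:
            p = run.declare(f"modules_{coll.cohort}.gmt")
            cio.write_module_collection(coll, p)
            cohort_names.append(coll.cohort)
        run.log(f"simulate: ingested network with {net.n_nodes} nodes, "
                f"{len(collections)} cohort(s)")
    elif not run.have("network.tsv", "truth.txt", "seed.gmt"):
        truth = synthesize_truth(
            n_genes=int(sim["n_genes"]), n_hubs=int(sim["n_hubs"]),
            mean_out_degree=float(sim["mean_out_degree"]),
            rng_seed=stage_seeds["simulate"],
        )
        net = truth.sem.network()
        cio.write_network(net, net_path, params=f"seed={stage_seeds['simulate']}")
        cio.write_truth(truth, truth_path)
        seed_set = GeneSet("planted_seed", truth.seed_module, "planted seed module")
        cio.write_gmt([seed_set], seed_path)
        collections = generate_module_collections(
            truth, n_cohorts=int(sim["n_cohorts"]),
            contamination=float(sim["contamination"]),
            rng_seed=stage_seeds["modules"],
            n_decoys=int(sim["n_decoys"]),
            universe_jitter=float(sim["universe_jitter"]),
        )
        for coll in collections:
            p = run.declare(f"modules_{coll.cohort}.gmt")
            cio.write_module_collection(coll, p)
            cohort_names.append(coll.cohort)
        run.log(f"simulate: {net.n_nodes} genes, {net.n_edges} edges, "
                f"{len(truth.planted_drivers)} planted driver(s), "
                f"seed module of {len(truth.seed_module)}")
    else:
        truth = cio.read_truth(truth_path)
        net = truth.sem.network()
        seed_set = cio.read_gmt(seed_path)[0]
        collections = []
        for p in sorted(run.dir.glob("modules_*.gmt")):
            coll = cio.read_module_collection(p, cohort=p.stem.removeprefix("modules_"))
            collections.append(coll)
            run.declare(p.name)
            cohort_names.append(coll.cohort)
        run.log("simulate: resumed from existing artifacts")

    # --- stage: core module ----------------------------------------------
    cm = cfg["core_module"]
    core_path = run.declare("core_module.gmt")
    try:
        core, _tag_report = derive_core_module(
            collections, seed_set, alpha=float(cm["alpha"]),
            correction=cm.get("correction"),
        )
    except ValueError as exc:
        raise RuntimeError(f"stage core_module failed: {exc}") from exc
    if not core.genes:
        raise RuntimeError("stage core_module failed: empty core module "
                           "(super-modules share no genes)")
    cio.write_gmt([core], core_path, params=f"alpha={cm['alpha']}")
    run.log(f"core_module: {len(core.genes)} genes")

    # --- stage: projection ------------------------------------------------
    k_proj = int(cfg["projection"]["k"])
    sub_path = run.declare("subnetwork.tsv")
    try:
        sub = project_seed(net, core, k=k_proj)
    except ValueError as exc:
        raise RuntimeError(f"stage projection failed: {exc}") from exc
    cio.write_network(sub.as_network(), sub_path,
                      params=f"seed={core.name} k={k_proj}")
    run.log(f"projection: subnetwork with {sub.n_nodes} nodes, {sub.n_edges} edges (k={k_proj})")

    # --- stage: key driver analysis ----------------------------------------
    kd = cfg["kda"]
    kda_cfg = KdaConfig(h_max=int(kd["h_max"]), alpha=float(kd["alpha"]),
                        correction=kd["correction"], direction=kd["direction"],
                        expand_k=int(kd["expand_k"]))
    kda_path = run.declare("kdg.tsv")
    try:
        results = kda(net, core.genes, kda_cfg)
    except ValueError as exc:
        raise RuntimeError(f"stage kda failed: {exc}") from exc
    kda_df = _kda_frame(results)
    with open(kda_path, "w") as fh:
        fh.write(f"# cicnet kda h_max={kd['h_max']} correction={kd['correction']} "
                 f"direction={kd['direction']}\n")
        kda_df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    drivers = [r for r in results if r.driver_class != "none"]
    run.log(f"kda: {len(results)} candidate(s), {len(drivers)} driver(s) "
            f"({sum(r.driver_class == 'global' for r in drivers)} global)")

    # --- stage: ranking -----------------------------------------------------
    rk = cfg["ranking"]
    traits_path = run.declare("traits.gmt")
    ranked_path = run.declare("ranked.tsv")
    trait_cfg = cfg.get("inputs", {}).get("traits") if cfg.get("inputs") else None
    if trait_cfg:
        trait_sets = cio.read_gmt(trait_cfg)
    else:
        trng = np.random.default_rng(stage_seeds["traits"])
        pool = sorted(core.genes & net.nodes)
        trait_sets = []
        for t in range(int(rk["n_traits"])):
            size = max(1, int(round(float(rk["trait_fraction"]) * len(pool))))
            genes = frozenset(map(str, trng.choice(pool, size=size, replace=False)))
            trait_sets.append(GeneSet(f"trait{t + 1}", genes, "disease-evidence set"))
    cio.write_gmt(trait_sets, traits_path)
    universe = net.nodes
    evidence = {
        r.gene: trait_evidence(net, r.gene, trait_sets, universe, k=int(rk["k"]))
        for r in results
    }
    ranked = composite_rank(evidence, mode=rk.get("mode", "equal"))
    trait_names = sorted({t for ev in evidence.values() for t in ev})
    rows = []
    for rd in ranked:
        row = {"gene": rd.gene, "final_rank": rd.final_rank, "composite": rd.composite}
        for t in trait_names:
            row[f"p_{t}"] = rd.per_trait_p.get(t, 1.0)
            row[f"rank_{t}"] = rd.per_trait_rank.get(t, 1.0)
        rows.append(row)
    with open(ranked_path, "w") as fh:
        fh.write(f"# cicnet ranking mode={rk.get('mode', 'equal')} k={rk['k']}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False, lineterminator="\n")
    run.log(f"ranking: {len(ranked)} driver(s) ranked over {len(trait_names)} trait(s)")

    # --- stage: validation --------------------------------------------------
    va = cfg["validation"]
    val_path = run.declare("validation.tsv")
    rank_of = {rd.gene: rd.final_rank for rd in ranked}
    globals_ranked = sorted(
        (r for r in drivers if r.driver_class == "global"),
        key=lambda r: rank_of.get(r.gene, len(ranked) + 1),
    )
    to_validate = globals_ranked[: int(va["top_n"])]
    val_rows = []
    if truth is None:
        run.log("validation: skipped (no generative model available for ingested inputs)")
    else:
        vrng = np.random.default_rng(stage_seeds["validation"])
        for r in to_validate:
            ko_seed = int(vrng.integers(0, 2**31))
            signature = simulate_knockout(truth.sem, r.gene,
                                          n_samples=int(va["n_samples"]),
                                          rng_seed=ko_seed)
            predicted = kdg_signature(net, r.gene, k=int(va["k"]))
            res = validate_prediction(predicted, signature, universe,
                                      alpha=float(va["alpha"]), exclude={r.gene})
            val_rows.append({
                "gene": r.gene, "final_rank": rank_of.get(r.gene),
                "predicted_size": len(predicted), "signature_size": res.set_b_size,
                "overlap": res.overlap, "fold": res.fold, "p": res.p,
                "validated": res.p < float(va["alpha"]),
            })
        run.log(f"validation: {sum(v['validated'] for v in val_rows)} of "
                f"{len(val_rows)} driver(s) validated")
    with open(val_path, "w") as fh:
        fh.write(f"# cicnet validation k={va['k']} alpha={va['alpha']}\n")
        cols = ["gene", "final_rank", "predicted_size", "signature_size",
                "overlap", "fold", "p", "validated"]
        pd.DataFrame(val_rows, columns=cols).to_csv(fh, sep="\t", index=False,
                                                    lineterminator="\n")

    run.finish()
    return run.dir


def report(run_dir) -> pd.DataFrame:
    """Summarize a completed run: one row per called driver.

    Columns: final rank, composite score, KDA statistics, per-trait
    significance flags, and the perturbation-validation outcome where a
    validation was performed.
    """
    run_dir = Path(run_dir)
    needed = ["kdg.tsv", "ranked.tsv", "validation.tsv"]
    missing = [n for n in needed if not (run_dir / n).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run directory {run_dir}: missing {missing}")
    kdg = pd.read_csv(run_dir / "kdg.tsv", sep="\t", comment="#")
    ranked = pd.read_csv(run_dir / "ranked.tsv", sep="\t", comment="#")
    validation = pd.read_csv(run_dir / "validation.tsv", sep="\t", comment="#")

    drivers = kdg[kdg["driver_class"] != "none"].copy()
    if drivers.empty:
        return pd.DataFrame(columns=["gene", "driver_class", "final_rank"])
    out = drivers.merge(ranked, on="gene", how="left")
    p_cols = [c for c in ranked.columns if c.startswith("p_")]
    for c in p_cols:
        out[f"sig{c.removeprefix('p')}"] = out[c] < 0.05
    if not validation.empty:
        out = out.merge(validation[["gene", "validated", "p"]]
                        .rename(columns={"p": "validation_p"}),
                        on="gene", how="left")
    else:
        out["validated"] = pd.NA
        out["validation_p"] = pd.NA
    out = out.sort_values(["final_rank", "gene"]).reset_index(drop=True)
    return out
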