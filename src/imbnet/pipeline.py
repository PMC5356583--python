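"""End-to-end pipeline: simulate -> preprocess -> learn -> consensus ->
evaluate -> survival screen -> subnetworks -> drivers -> mediators -> tissue.

A run is driven by a nested configuration (defaults below, unknown keys
rejected), writes every stage artifact under one output directory, records
a manifest (inputs, outputs, parameter hash, wall time, warnings) and a
resolved copy of the configuration. Each stage derives its own seed from
the global seed keyed by the stage name, so stages are independently
reproducible. A stage whose parameter hash matches a previous manifest and
whose outputs are still present is skipped on re-run.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
import warnings
import zlib
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import bayesnet, io, neteval, preprocess, survival, synthetic, tissue, topology

__all__ = ["DEFAULT_CONFIG", "RunManifest", "load_config", "stage_seed", "run_pipeline"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "outdir": "imbnet_run",
    "stages": {
        "simulate": True,
        "preprocess": True,
        "learn": True,
        "consensus": True,
        "evaluate": True,
        "survival": True,
        "subnet": True,
        "drivers": True,
        "mediators": True,
        "tissue": True,
    },
    "simulate": {
        "n_genes": 50,
        "n_hubs": 3,
        "mean_out_degree": 1.5,
        "frac_cis": 0.2,
        "n_samples": 200,
        "segment_sd": 1.0,
        "mean_block_len": 5.0,
        "noise_sd": 1.0,
        "n_drivers": 3,
        "log_hr": 1.0,
        "baseline_rate": 0.02,
        "censor_rate": 0.01,
    },
    "preprocess": {"top_frac": 1.0, "fdr_threshold": 0.05},
    "learn": {
        "n_restarts": 20,
        "max_parents": 3,
        "n_steps": 30000,
        "t_initial": 2.0,
        "t_final": 0.05,
        "ess": 1.0,
        "use_priors": True,
        "k_bonus": 10.0,
        "k_penalty": 0.1,
    },
    "consensus": {"threshold": 0.3},
    "evaluate": {"n_perm": 200},
    "survival": {"alpha": 0.05},
    "subnet": {"min_component_seeds": 3, "max_seed_genes": 25},
    "drivers": {"hops": 3, "sd_mult": 2.0},
    "mediators": {"frac": 0.1, "n_drivers": 3},
    "tissue": {
        "n_genes": 120,
        "tissues": [
            "prostate",
            "prefrontal_cortex",
            "skeletal_muscle",
            "cardiac_muscle",
            "adipose",
            "uterus",
            "ovary",
            "liver",
            "lung",
            "kidney",
            "colon",
            "skin",
        ],
        "n_specific_per_tissue": 3,
        "fold": 10.0,
        "z_threshold": 2.0,
    },
}


class RunManifest(dict):
    """stage -> {inputs, outputs, params_hash, wall_time, warnings, checksums}"""


def _merge_validate(defaults: dict, override: dict, path: str = "") -> dict:
    merged = copy.deepcopy(defaults)
    for key, value in override.items():
        if key not in defaults:
            raise ValueError(f"unknown config key: {path + key}")
        if isinstance(defaults[key], dict) and not path + key == "stages":
            if not isinstance(value, dict):
                raise ValueError(f"config key {path + key} must be a mapping")
            merged[key] = _merge_validate(defaults[key], value, path + key + ".")
        elif key == "stages":
            for s, flag in value.items():
                if s not in defaults["stages"]:
                    raise ValueError(f"unknown stage: {s}")
                merged["stages"][s] = bool(flag)
        else:
            merged[key] = value
    return merged


def load_config(config: dict | str | Path | None = None) -> dict:
    """Merge a user config (mapping or YAML path) over the defaults,
    rejecting unknown keys."""
    if config is None:
        override: dict = {}
    elif isinstance(config, (str, Path)):
        with open(config) as fh:
            override = yaml.safe_load(fh) or {}
    else:
        override = config
    return _merge_validate(DEFAULT_CONFIG, override)


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: global seed keyed by the stage name (stable)."""
    return (int(global_seed) * 100_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _params_hash(params: Any) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict | str | Path | None = None) -> RunManifest:
    """Execute the enabled stages in dependency order. Returns the manifest."""
    cfg = load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)

    manifest_path = outdir / "manifest.json"
    previous: dict = {}
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
    manifest = RunManifest()
    state: dict[str, Any] = {}

    def run_stage(
        name: str,
        params: dict,
        inputs: list[str],
        outputs: list[str],
        fn: Callable[[], None],
        needs_state: bool = False,
    ) -> None:
        if not cfg["stages"].get(name, False):
            return
        for dep in inputs:
            if not (outdir / dep).exists():
                raise FileNotFoundError(
                    f"stage {name!r} requires missing upstream output {dep!r}"
                )
        phash = _params_hash({"params": params, "seed": cfg["seed"]})
        prev = previous.get(name)
        resumable = (
            not needs_state
            and prev is not None
            and prev.get("params_hash") == phash
            and all((outdir / o).exists() for o in outputs)
        )
        start = time.time()
        caught: list[str] = []
        if not resumable:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                fn()
                caught = [str(w.message) for w in wlist]
        manifest[name] = {
            "inputs": inputs,
            "outputs": outputs,
            "params_hash": phash,
            "wall_time": round(time.time() - start, 3),
            "warnings": caught,
            "skipped": resumable,
            "checksums": {o: _checksum(outdir / o) for o in outputs},
        }

    def get_samples() -> list[bayesnet.StructureSample]:
        if "samples" not in state:
            samples_dir = outdir / "structure_samples"
            files = sorted(samples_dir.glob("sample_*.tsv"))
            if not files:
                raise FileNotFoundError(
                    "no structure samples found; run the learn stage first"
                )
            state["samples"] = [
                bayesnet.StructureSample(
                    edges=frozenset(io.read_edge_list(f).keys()), seed=k, score=0.0
                )
                for k, f in enumerate(files)
            ]
        return state["samples"]

    def get_cis_genes() -> list[str]:
        if "cis_genes" not in state:
            cis_tab = pd.read_csv(outdir / "cis_results.tsv", sep="\t")
            state["cis_genes"] = (
                cis_tab.loc[cis_tab["is_cis"], "gene"].astype(str).tolist()
            )
        return state["cis_genes"]

    def get_network() -> bayesnet.ConsensusNetwork:
        if "network" not in state:
            import networkx as nx

            disc = io.read_matrix_tsv(outdir / "discrete.tsv")
            g = nx.DiGraph()
            g.add_nodes_from(disc.index)
            for (u, v), f in io.read_edge_list(outdir / "consensus_edges.tsv").items():
                g.add_edge(u, v, frequency=f)
            net = bayesnet.ConsensusNetwork(graph=g)
            net.cis_genes = frozenset(get_cis_genes())
            state["network"] = net
        return state["network"]

    # ---------------- simulate ----------------
    sim = cfg["simulate"]

    def do_simulate() -> None:
        seed = stage_seed(cfg["seed"], "simulate")
        truth = synthetic.generate_ground_truth_dag(
            sim["n_genes"], sim["n_hubs"], sim["mean_out_degree"], sim["frac_cis"], seed
        )
        cna = synthetic.simulate_cna(
            truth, sim["n_samples"], sim["segment_sd"], seed,
            mean_block_len=sim["mean_block_len"],
        )
        expr = synthetic.simulate_expression(truth, cna, sim["noise_sd"], seed + 7)
        # driver module: the planted hub regulators, largest fan-out first
        outdeg: dict[str, int] = {}
        for u, _v in truth.edges:
            outdeg[u] = outdeg.get(u, 0) + 1
        drivers = sorted(truth.hubs, key=lambda g: (-outdeg.get(g, 0), g))
        drivers = drivers[: sim["n_drivers"]]
        surv = synthetic.simulate_bcr(
            expr, drivers, sim["log_hr"], sim["baseline_rate"], sim["censor_rate"],
            seed + 13,
        )
        io.write_edge_list(truth.edges, outdir / "truth_edges.tsv")
        io.write_gene_list(truth.cis_genes, outdir / "truth_cis_genes.txt")
        io.write_gene_list(drivers, outdir / "truth_drivers.txt")
        io.write_matrix_tsv(expr, outdir / "expression.tsv")
        io.write_matrix_tsv(cna, outdir / "cna.tsv")
        io.write_survival_tsv(surv, outdir / "survival.tsv")

    run_stage(
        "simulate",
        sim,
        [],
        [
            "truth_edges.tsv",
            "truth_cis_genes.txt",
            "truth_drivers.txt",
            "expression.tsv",
            "cna.tsv",
            "survival.tsv",
        ],
        do_simulate,
    )

    # ---------------- preprocess ----------------
    pre = cfg["preprocess"]

    def do_preprocess() -> None:
        expr = io.read_matrix_tsv(outdir / "expression.tsv")
        cna = io.read_matrix_tsv(outdir / "cna.tsv")
        cis = preprocess.detect_cis_cna(expr, cna, fdr_threshold=pre["fdr_threshold"])
        informative = preprocess.select_informative_genes(
            expr, cis, top_frac=pre["top_frac"]
        )
        disc = preprocess.discretize_expression(expr.loc[informative])
        pd.DataFrame(
            [
                {"gene": c.gene, "rho": c.correlation, "p": c.p, "q": c.q,
                 "is_cis": c.is_cis}
                for c in cis
            ]
        ).to_csv(outdir / "cis_results.tsv", sep="\t", index=False)
        io.write_gene_list(informative, outdir / "informative_genes.txt")
        io.write_matrix_tsv(disc, outdir / "discrete.tsv")

    run_stage(
        "preprocess",
        pre,
        ["expression.tsv", "cna.tsv"],
        ["cis_results.tsv", "informative_genes.txt", "discrete.tsv"],
        do_preprocess,
    )

    # ---------------- learn + consensus ----------------
    lrn = cfg["learn"]

    def do_learn() -> None:
        disc = io.read_matrix_tsv(outdir / "discrete.tsv")
        cis_tab = pd.read_csv(outdir / "cis_results.tsv", sep="\t")
        cis_genes = cis_tab.loc[cis_tab["is_cis"], "gene"].astype(str).tolist()
        seed = stage_seed(cfg["seed"], "learn")
        samples_dir = outdir / "structure_samples"
        samples_dir.mkdir(exist_ok=True)
        samples = []
        for k in range(lrn["n_restarts"]):
            s = bayesnet.search_structure(
                disc,
                cis_flags=cis_genes,
                max_parents=lrn["max_parents"],
                n_steps=lrn["n_steps"],
                t_initial=lrn["t_initial"],
                t_final=lrn["t_final"],
                seed=seed + k,
                ess=lrn["ess"],
                use_priors=lrn["use_priors"],
                k_bonus=lrn["k_bonus"],
                k_penalty=lrn["k_penalty"],
            )
            samples.append(s)
            io.write_edge_list(
                {e: 1.0 for e in sorted(s.edges)}, samples_dir / f"sample_{k:03d}.tsv"
            )
        state["samples"] = samples
        state["cis_genes"] = cis_genes
        scores = pd.DataFrame(
            {"restart": range(len(samples)), "score": [s.score for s in samples]}
        )
        scores.to_csv(outdir / "restart_scores.tsv", sep="\t", index=False)

    run_stage(
        "learn",
        lrn,
        ["discrete.tsv", "cis_results.tsv"],
        ["restart_scores.tsv"],
        do_learn,
        needs_state=True,
    )

    con = cfg["consensus"]

    def do_consensus() -> None:
        disc = io.read_matrix_tsv(outdir / "discrete.tsv")
        net = bayesnet.build_consensus(
            get_samples(),
            consensus_threshold=con["threshold"],
            nodes=list(disc.index),
            cis_flags=get_cis_genes(),
        )
        state["network"] = net
        io.write_edge_list(net.edges, outdir / "consensus_edges.tsv", "frequency")
        io.write_graphml(net.graph, outdir / "consensus.graphml")

    run_stage(
        "consensus",
        con,
        ["restart_scores.tsv", "discrete.tsv"],
        ["consensus_edges.tsv", "consensus.graphml"],
        do_consensus,
        needs_state=True,
    )

    # ---------------- evaluate (vs simulation truth) ----------------
    ev = cfg["evaluate"]

    def do_evaluate() -> None:
        net = get_network()
        truth_edges = io.read_edge_list(outdir / "truth_edges.tsv")
        reference = neteval.ReferenceCollection.from_pairs("truth", truth_edges.keys())
        rows = []
        if net.edges:
            obs = neteval.edge_accuracy(net, reference)
            mean, sd, p = neteval.permutation_null(
                net, reference, n_perm=ev["n_perm"],
                seed=stage_seed(cfg["seed"], "evaluate"),
            )
            prec, rec = neteval.skeleton_precision_recall(
                net.edges.keys(), truth_edges.keys()
            )
            rows.append(
                {"reference": "truth", "accuracy": obs, "null_mean": mean,
                 "null_sd": sd, "p": p, "skeleton_precision": prec,
                 "skeleton_recall": rec}
            )
        pd.DataFrame(rows).to_csv(outdir / "evaluation.tsv", sep="\t", index=False)

    run_stage(
        "evaluate",
        ev,
        ["consensus_edges.tsv", "truth_edges.tsv"],
        ["evaluation.tsv"],
        do_evaluate,
        needs_state=True,
    )

    # ---------------- survival screen ----------------
    sv = cfg["survival"]

    def do_survival() -> None:
        expr = io.read_matrix_tsv(outdir / "expression.tsv")
        surv = io.read_survival_tsv(outdir / "survival.tsv")
        screen = survival.cox_screen(expr, surv, alpha=sv["alpha"])
        pd.DataFrame(
            [
                {"gene": r.gene, "coef": r.coefficient, "hr": r.hr, "p": r.p,
                 "q": r.q, "direction": r.direction, "significant": r.significant}
                for r in screen
            ]
        ).to_csv(outdir / "cox_screen.tsv", sep="\t", index=False)

    run_stage(
        "survival",
        sv,
        ["expression.tsv", "survival.tsv"],
        ["cox_screen.tsv"],
        do_survival,
    )

    # ---------------- BCR subnetwork projection ----------------
    sb = cfg["subnet"]

    def do_subnet() -> None:
        net = get_network()
        screen = pd.read_csv(outdir / "cox_screen.tsv", sep="\t")
        sig = screen.loc[screen["significant"]]
        if sig.empty:  # fall back to the strongest associations
            sig = screen.nsmallest(sb["max_seed_genes"], "q")
        seeds = set(sig["gene"].astype(str))
        try:
            result = topology.project_seed_subnetwork(
                net, seeds, min_component_seeds=sb["min_component_seeds"]
            )
            members = sorted(result.members)
        except ValueError:
            members = []
        io.write_gene_list(sorted(seeds), outdir / "bcr_seed_genes.txt")
        io.write_gene_list(members, outdir / "bcr_subnetwork.txt")

    run_stage(
        "subnet",
        sb,
        ["cox_screen.tsv", "consensus_edges.tsv"],
        ["bcr_seed_genes.txt", "bcr_subnetwork.txt"],
        do_subnet,
        needs_state=True,
    )

    # ---------------- key regulators / distinct drivers ----------------
    dr = cfg["drivers"]

    def do_drivers() -> None:
        net = get_network()
        calls = topology.call_key_regulators(
            net, hops=dr["hops"], sd_mult=dr["sd_mult"]
        )
        pd.DataFrame(
            [
                {"gene": c.gene, "downstream_count": c.downstream_count,
                 "threshold": c.threshold, "is_key": c.is_key, "degree": c.degree}
                for c in calls
            ]
        ).to_csv(outdir / "key_regulators.tsv", sep="\t", index=False)
        distinct = topology.distinct_key_drivers(net, calls)
        io.write_gene_list(distinct, outdir / "distinct_key_drivers.txt")
        state["key_calls"] = calls
        state["distinct"] = distinct

    run_stage(
        "drivers",
        dr,
        ["consensus_edges.tsv"],
        ["key_regulators.tsv", "distinct_key_drivers.txt"],
        do_drivers,
        needs_state=True,
    )

    # ---------------- mediators ----------------
    md = cfg["mediators"]

    def do_mediators() -> None:
        net = get_network()
        drivers = state.get("distinct")
        if drivers is None:
            drivers = io.read_gene_list(outdir / "distinct_key_drivers.txt")
        drivers = drivers[: md["n_drivers"]]
        if not drivers:  # degenerate network: rank from the highest-reach genes
            kr = pd.read_csv(outdir / "key_regulators.tsv", sep="\t")
            kr = kr.sort_values(["downstream_count", "gene"],
                                ascending=[False, True])
            drivers = kr["gene"].astype(str).head(md["n_drivers"]).tolist()
        ranking = topology.mean_distance_to_drivers(net, set(drivers))
        common = topology.common_downstream_genes(ranking, frac=md["frac"])
        pd.DataFrame(
            [
                {"gene": r.gene, "mean_distance": r.mean_distance,
                 "reachable_from": r.reachable_from,
                 "is_common_downstream": r.is_common_downstream}
                for r in ranking
            ]
        ).to_csv(outdir / "mediator_ranking.tsv", sep="\t", index=False)
        io.write_gene_list(common, outdir / "common_downstream.txt")
        state["common_downstream"] = common

    run_stage(
        "mediators",
        md,
        ["key_regulators.tsv", "distinct_key_drivers.txt"],
        ["mediator_ranking.tsv", "common_downstream.txt"],
        do_mediators,
        needs_state=True,
    )

    # ---------------- tissue ----------------
    ts = cfg["tissue"]

    def do_tissue() -> None:
        atlas = synthetic.make_tissue_fixture(
            ts["n_genes"], ts["tissues"], ts["n_specific_per_tissue"], ts["fold"],
            stage_seed(cfg["seed"], "tissue"),
        )
        calls = tissue.preferential_tissues(atlas, z_threshold=ts["z_threshold"])
        interest = state.get("common_downstream") or list(atlas.expression.index)
        tally = tissue.tally_by_tissue(calls, interest)
        io.write_matrix_tsv(atlas.expression, outdir / "tissue_atlas.tsv")
        pd.DataFrame(
            [{"gene": c.gene, "tissue": c.tissue, "z": c.zscore} for c in calls]
        ).to_csv(outdir / "tissue_calls.tsv", sep="\t", index=False)
        pd.DataFrame(tally, columns=["tissue", "count"]).to_csv(
            outdir / "tissue_tally.tsv", sep="\t", index=False
        )

    run_stage(
        "tissue",
        ts,
        [],
        ["tissue_atlas.tsv", "tissue_calls.tsv", "tissue_tally.tsv"],
        do_tissue,
        needs_state=True,
    )

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
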