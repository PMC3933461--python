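"""End-to-end orchestration: config, stage wiring, manifests, determinism.

A run is driven by a single YAML config with one section per stage.  Every
stochastic stage receives a sub-seed derived from the global seed (and
logged in the manifest), so rerunning the same config reproduces
byte-identical tables.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ExpressionMatrix, ProbeMatrix
from .diffexp import moderated_t_test, write_de_table
from .downstream import directional_concordance, hypergeometric_enrichment, read_gmt
from .hotspot import AnnealSchedule, HotspotConfig, detect_hotspots, write_module_table
from .interactome import integrate, read_interactome, weight_edges, write_weighted_edges
from .preprocess import preprocess_chain
from .synthetic_data import (
    NetworkSimConfig,
    SimulationConfig,
    gene_ids,
    simulate_expression,
    simulate_interactome,
    simulate_validation_stats,
)

logger = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

#: Stage defaults.  The analysis constants mirror the published protocol:
#: detection threshold 0.05, 100 seeds, gamma 0.5, minimum module size 10,
#: 1000 permutations, 5% significance.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "expmods_run",
    "log_level": "INFO",
    "synthetic": {
        "enabled": False,
        "expression": {
            "n_genes": 300,
            "n_case": 7,
            "n_control": 5,
            "effect_size": 4.0,
            "noise_sd": 1.0,
            "baseline_mean": 8.0,
        },
        "network": {
            "n_nodes": 300,
            "topology": "preferential_attachment",
            "attachment_or_density": 3,
            "planted_module_size": 10,
            "planted_internal_density": 0.9,
        },
        "validation": {"concordant_frac": 0.8},
    },
    "inputs": {
        "expression": None,
        "groups": None,
        "detection": None,
        "annotation": None,
        "interactome": None,
        "interactome_format": "edge-list",
        "gene_sets": None,
        "validation_stats": None,
    },
    "preprocess": {"p_thresh": 0.05, "min_samples": None},
    "diffexp": {"pi0": None},
    "hotspot": {
        "n_seeds": 100,
        "gamma": 0.5,
        "min_module_size": 10,
        "n_perm": 1000,
        "alpha": 0.05,
        "bonferroni": True,
        "dedup_jaccard": None,
    },
    "downstream": {"alpha": 0.05},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in (override or {}).items():
        if key in out and isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    _validate(cfg)
    return cfg


def _validate(cfg: dict) -> None:
    """Fail fast on invalid stage parameters, before any computation."""
    hs = cfg["hotspot"]
    HotspotConfig(
        n_seeds=hs["n_seeds"], gamma=hs["gamma"], min_module_size=hs["min_module_size"],
        n_perm=hs["n_perm"], alpha=hs["alpha"], bonferroni=hs["bonferroni"],
        dedup_jaccard=hs.get("dedup_jaccard"),
    )
    pp = cfg["preprocess"]
    if not 0.0 < pp["p_thresh"] <= 1.0:
        raise ValueError("preprocess.p_thresh must be in (0, 1]")
    if not cfg["synthetic"]["enabled"] and cfg["inputs"]["expression"] is None:
        raise ValueError("either synthetic.enabled or inputs.expression is required")


def _stage_seeds(global_seed: int) -> dict[str, int]:
    names = ["sim_expression", "sim_network", "sim_validation", "hotspot"]
    state = np.random.SeedSequence(int(global_seed)).generate_state(len(names)) % (2**31)
    return dict(zip(names, (int(s) for s in state)))


def _config_hash(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def run_pipeline(config: str | Path | dict, output_dir: str | Path | None = None,
                 seed: int | None = None) -> Path:
    """Run every configured stage; returns the artifact directory.

    Stages: (optional) synthetic generation -> (optional) probe-level
    preprocessing -> moderated t / q-values -> interactome integration and
    weighting -> hotspot detection -> (optional) concordance validation and
    enrichment.  Each stage writes a tab-separated table; a run manifest
    records the config hash, stage seeds and row counts.
    """
    overrides: dict = {}
    if seed is not None:
        overrides["seed"] = int(seed)
    if output_dir is not None:
        overrides["output_dir"] = str(output_dir)
    if isinstance(config, dict):
        cfg = _merge(DEFAULT_CONFIG, _merge(config, overrides))
        _validate(cfg)
    else:
        cfg = load_config(config, overrides)

    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(), logging.INFO))
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg["seed"])
    manifest: dict[str, object] = {
        "expmods_version": __version__,
        "config_hash": _config_hash({k: v for k, v in cfg.items() if k != "output_dir"}),
        "global_seed": cfg["seed"],
        **{f"seed_{k}": v for k, v in seeds.items()},
    }

    # ---- stage 1: inputs (synthetic or files) -------------------------------
    planted: list[str] = []
    if cfg["synthetic"]["enabled"]:
        net_cfg = NetworkSimConfig(**cfg["synthetic"]["network"], rng_seed=seeds["sim_network"])
        planted = gene_ids(net_cfg.n_nodes)[: net_cfg.planted_module_size]
        expr_cfg = SimulationConfig(
            **cfg["synthetic"]["expression"], planted_genes=planted,
            rng_seed=seeds["sim_expression"],
        )
        if expr_cfg.n_genes < net_cfg.n_nodes:
            raise ValueError("synthetic expression must cover every network node")
        expr = simulate_expression(expr_cfg)
        graph = simulate_interactome(net_cfg)
        expr.write(out / "expression.tsv", out / "groups.tsv")
        nx.write_edgelist(graph, out / "interactome.tsv", delimiter="\t", data=False)
        manifest["planted_module"] = ",".join(planted)
    else:
        inputs = cfg["inputs"]
        if inputs["detection"] is not None or inputs["annotation"] is not None:
            probes = ProbeMatrix.read(
                inputs["expression"], inputs["detection"], inputs["annotation"],
                groups_path=inputs["groups"],
            )
            expr, pp_log = preprocess_chain(
                probes, p_thresh=cfg["preprocess"]["p_thresh"],
                min_samples=cfg["preprocess"]["min_samples"],
            )
            manifest.update({f"preprocess_{k}": v for k, v in pp_log.items()})
            expr.write(out / "expression.tsv", out / "groups.tsv")
        else:
            expr = ExpressionMatrix.read(inputs["expression"], inputs["groups"])
        if inputs["interactome"] is None:
            raise ValueError("inputs.interactome is required when synthetic data is disabled")
        graph = read_interactome(inputs["interactome"], fmt=inputs["interactome_format"])
    manifest["n_genes"] = int(expr.values.shape[0])
    manifest["n_samples"] = int(expr.values.shape[1])

    # ---- stage 2: differential expression -----------------------------------
    de = moderated_t_test(expr, qvalue_pi0=cfg["diffexp"]["pi0"])
    write_de_table(de.sort_values("p"), out / "diffexp.tsv")
    manifest["n_de_q05"] = int((de["q"] < 0.05).sum())

    # ---- stage 3: network integration + weighting ---------------------------
    sub = integrate(graph, set(expr.genes))
    wnet = weight_edges(sub, de)
    write_weighted_edges(wnet, out / "weighted_edges.tsv")
    manifest["n_network_nodes"] = wnet.graph.number_of_nodes()
    manifest["n_network_edges"] = wnet.graph.number_of_edges()

    # ---- stage 4: hotspot detection -----------------------------------------
    hs = cfg["hotspot"]
    hs_cfg = HotspotConfig(
        n_seeds=hs["n_seeds"], gamma=hs["gamma"], min_module_size=hs["min_module_size"],
        n_perm=hs["n_perm"], alpha=hs["alpha"], bonferroni=hs["bonferroni"],
        dedup_jaccard=hs.get("dedup_jaccard"), anneal=AnnealSchedule(),
        rng_seed=seeds["hotspot"],
    )
    result = detect_hotspots(wnet, de, hs_cfg)
    write_module_table(result, out / "modules.tsv")
    result.jaccard.to_csv(out / "module_jaccard.tsv", sep="\t")
    for mod in result.modules:
        sub_w = wnet.graph.subgraph(mod.members)
        with open(out / f"module_{mod.seed}_edges.tsv", "w") as fh:
            for a, b, w in sub_w.edges.data("weight"):
                fh.write(f"{a}\t{b}\t{w:.6f}\n")
    manifest.update({f"hotspot_{k}": v for k, v in result.log.items()})

    # ---- stage 5: validation + enrichment -----------------------------------
    if result.modules:
        top = result.modules[0]
        stats_v = None
        if cfg["synthetic"]["enabled"]:
            stats_v = simulate_validation_stats(
                sorted(top.members), de["t"],
                cfg["synthetic"]["validation"]["concordant_frac"],
                rng_seed=seeds["sim_validation"],
            )
        elif cfg["inputs"]["validation_stats"] is not None:
            stats_v = pd.read_csv(cfg["inputs"]["validation_stats"], sep="\t", index_col=0)
        if stats_v is not None:
            conc = directional_concordance(
                sorted(top.members), de, stats_v, alpha=cfg["downstream"]["alpha"]
            )
            conc.per_gene.to_csv(out / "concordance.tsv", sep="\t")
            manifest["concordance_n_same"] = conc.n_same
            manifest["concordance_n_opposite"] = conc.n_opposite
            manifest["concordance_fisher_p"] = conc.fisher_p
        if cfg["inputs"]["gene_sets"] is not None:
            sets = read_gmt(cfg["inputs"]["gene_sets"])
            enr = hypergeometric_enrichment(set(top.members), sets, set(expr.genes))
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    with open(out / "manifest.txt", "w") as fh:
        for key in sorted(manifest):
            fh.write(f"{key}={manifest[key]}\n")
    logger.info("pipeline complete: %s", out)
    return out
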