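"""End-to-end orchestration: simulate/load -> DE -> enrichment ->
similarity -> assays, with provenance and a machine-readable report.

A single YAML config drives every stage; one top-level seed is fanned out
into per-stage seeds (stable hash of ``"{seed}:{stage}"``), so each stage
is independently reproducible and a rerun with the same config and seed
produces an identical ``report.json`` apart from its timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .assays import lactate_kinetics
from .compendium import ExpressionCompendium
from .de import PROFILES, apply_de_filters, compute_gene_stats, de_gene_sets
from .enrichment import DEFAULT_ITERATIONS, run_enrichment_scenarios
from .genesets import GeneSet, read_gmt, write_gmt
from .similarity import hierarchical_cluster, pca_scores, spearman_matrix
from .simulate import (SimulationConfig, TraceConfig, simulate_cellline_panel,
                       simulate_compendium, simulate_ph_trace)

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out_dir": "pipeline_out",
    "simulation": {"compendium": {}, "panel": {}, "trace": {}},
    "inputs": {},  # optional paths overriding simulation: matrix, samples,
                   # sig_epc_gmt, sig_enc_gmt, trace_csv
    "de": {"group_a": "disease", "group_b": "control", "profile": "ppcd"},
    "enrichment": {"iterations": DEFAULT_ITERATIONS, "call_on": "empirical"},
    "similarity": {"metric": "correlation", "linkage": "average",
                   "n_components": 2, "n_groups": 4, "n_clones": 3},
    "trace": {"resting_window_s": 30.0},
}


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the top-level seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge defaults <- YAML file <- explicit overrides."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("pipeline config must be a YAML mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def validate_config(cfg: dict) -> None:
    """Dry-run validation: stage configs well-formed, referenced paths exist."""
    if cfg["de"]["profile"] not in PROFILES:
        raise ValueError(f"unknown threshold profile {cfg['de']['profile']!r}; "
                         f"known: {sorted(PROFILES)}")
    SimulationConfig(**cfg["simulation"]["compendium"]).validate()
    TraceConfig(**cfg["simulation"]["trace"]).validate()
    if int(cfg["enrichment"]["iterations"]) < 100:
        raise ValueError("enrichment iterations must be >= 100")
    for key, p in (cfg.get("inputs") or {}).items():
        if p and not Path(p).exists():
            raise FileNotFoundError(f"configured input {key!r} does not exist: {p}")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: dict, out_dir: str | Path | None = None) -> dict:
    """Execute every stage and write all artifacts plus ``report.json``.

    Returns the report dict. Any stage error is re-raised as
    :class:`StageError` naming the stage.
    """
    validate_config(cfg)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    chash = config_hash(cfg)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("cenckit")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": seed,
            "config_hash": chash,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    }
    inputs = cfg.get("inputs") or {}

    def _log(stage: str, msg: str) -> None:
        log.info("[stage=%s seed=%s config=%s] %s", stage, seed, chash, msg)

    try:
        stage = "compendium"
        if inputs.get("matrix"):
            compendium = ExpressionCompendium.read(inputs["matrix"], inputs["samples"])
            sig_epc = read_gmt(inputs["sig_epc_gmt"])[0]
            sig_enc = read_gmt(inputs["sig_enc_gmt"])[0]
            truth = None
            _log(stage, f"loaded compendium from {inputs['matrix']}")
        else:
            sim_cfg = SimulationConfig(**{
                **cfg["simulation"]["compendium"],
                "seed": stage_seed(seed, "compendium")})
            compendium, truth, sig_epc, sig_enc = simulate_compendium(sim_cfg)
            _log(stage, f"simulated {len(compendium.gene_ids)} genes x "
                        f"{len(compendium.sample_ids)} samples")
        compendium.write(out / "matrix.tsv", out / "samples.tsv")
        write_gmt([sig_epc, sig_enc], out / "signatures.gmt")
        if truth is not None:
            truth.table.to_csv(out / "truth.tsv", sep="\t")
            report["truth_overlap_counts"] = truth.overlap_counts()

        stage = "de"
        de_cfg = cfg["de"]
        profile = PROFILES[de_cfg["profile"]]
        stats = compute_gene_stats(compendium, de_cfg["group_a"], de_cfg["group_b"])
        table = apply_de_filters(stats, profile)
        up, down = de_gene_sets(table)
        table.table.to_csv(out / "de_table.tsv", sep="\t", index=False,
                           float_format="%.6g")
        write_gmt([up, down], out / "de_sets.gmt")
        report["de"] = {"profile": profile.name, "n_pass": table.n_pass,
                        "n_up": len(up), "n_down": len(down)}
        _log(stage, f"{table.n_pass} DE genes ({len(up)} up, {len(down)} down) "
                    f"under profile {profile.name}")

        stage = "enrichment"
        universe = GeneSet("universe", compendium.gene_ids)
        en_cfg = cfg["enrichment"]
        results = run_enrichment_scenarios(
            up, down, sig_epc, sig_enc, universe,
            r=int(en_cfg["iterations"]), seed=stage_seed(seed, "enrichment"),
            call_on=en_cfg["call_on"])
        rows = [r.to_dict() for r in results]
        with open(out / "enrichment.json", "w") as fh:
            json.dump(rows, fh, indent=2)
        _write_tsv(out / "enrichment.tsv", rows)
        report["enrichment"] = rows
        _log(stage, "; ".join(f"{r.name}: k={r.k_obs} call={r.call}" for r in results))

        stage = "similarity"
        sim = cfg["similarity"]
        panel_cfg = SimulationConfig(**{
            **cfg["simulation"]["compendium"],
            **cfg["simulation"].get("panel", {}),
            "seed": stage_seed(seed, "panel")})
        panel = simulate_cellline_panel(panel_cfg, n_groups=int(sim["n_groups"]),
                                        n_clones=int(sim["n_clones"]))
        corr = spearman_matrix(panel)
        corr.write(out / "spearman.tsv")
        pca = pca_scores(panel, n_components=int(sim["n_components"]))
        pca.write(out / "pca_scores.tsv")
        tree = hierarchical_cluster(corr_features(panel), metric=sim["metric"],
                                    linkage=sim["linkage"])
        (out / "samples_tree.newick").write_text(tree.to_newick() + "\n")
        cut = tree.cut(int(sim["n_groups"]))
        report["similarity"] = {
            "pca_variance_ratio": [float(v) for v in pca.variance_ratio],
            "cluster_assignment": cut,
            "n_clusters_cut": int(sim["n_groups"]),
        }
        _log(stage, f"panel {sim['n_groups']}x{sim['n_clones']} clustered")

        stage = "assays"
        if inputs.get("trace_csv"):
            import pandas as pd
            df = pd.read_csv(inputs["trace_csv"])
            time_s, ph = df["time_s"].to_numpy(), df["ph"].to_numpy()
            t_on = float(cfg["trace"].get("t_on", 60.0))
            t_off = float(cfg["trace"].get("t_off", 180.0))
            truth_metrics = None
        else:
            trace_cfg = TraceConfig(**{**cfg["simulation"]["trace"],
                                       "seed": stage_seed(seed, "trace")})
            trace = simulate_ph_trace(trace_cfg)
            trace.write_csv(out / "trace.csv", sidecar=out / "trace_truth.json")
            time_s, ph = trace.time_s, trace.ph
            t_on, t_off = trace_cfg.t_on, trace_cfg.t_off
            truth_metrics = trace.ground_truth
        metrics = lactate_kinetics(time_s, ph, t_on=t_on, t_off=t_off,
                                   resting_window_s=float(cfg["trace"]["resting_window_s"]))
        with open(out / "kinetics.json", "w") as fh:
            json.dump(metrics.to_dict(), fh, indent=2)
        report["assays"] = {"kinetics": metrics.to_dict()}
        if truth_metrics is not None:
            report["assays"]["kinetics_ground_truth"] = truth_metrics
        _log(stage, f"kinetics: max d[H]/dt = {metrics.max_dh_dt:.3g} nM/s")
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        root.removeHandler(handler)
        handler.close()
        raise StageError(stage, exc) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    root.removeHandler(handler)
    handler.close()
    return report


def corr_features(compendium: ExpressionCompendium):
    """Samples x genes log2(TPM+1) frame for sample-level clustering."""
    import numpy as np
    return np.log2(compendium.tpm.T + 1.0)


def _write_tsv(path: Path, rows: list[dict]) -> None:
    import pandas as pd
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
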