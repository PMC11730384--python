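"""End-to-end pipeline orchestration.

A pipeline run executes simulate -> analyze-activity -> analyze-connectivity
-> reduce for one parameter setting, writing every stage's artifacts under a
run directory together with a manifest (config hash, master seed, artifact
checksums).  Re-running with an unchanged config skips completed stages
unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import connectivity as conn
from .activity import summarize_activity
from .layers import StructuralLayers, load_layer, normalize_layer, surrogate_layers
from .params import ModelParameters, default_parameters, load_parameters
from .simulate import SimulationConfig, calibrate_then_batch

__all__ = ["load_pipeline_config", "run_pipeline"]

_DEFAULTS = {
    "n_nodes": 8,
    "layer_seed": 0,
    "omega_Glu": None,
    "omega_GABA": None,
    "duration": 20.0,
    "calibration_duration": 20.0,
    "batch_duration": 20.0,
    "n_batches": 1,
    "dt": 1e-4,
    "record_stride": 10,
    "threshold_fraction": 0.25,
    "parameters": None,       # path to a YAML registry; None -> packaged defaults
    "omega_pyr_layer": None,  # path to a neuronal layer matrix
    "omega_ast_layer": None,  # path to an astrocytic layer matrix
}


def load_pipeline_config(path: str | Path | None) -> dict:
    cfg = dict(_DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = sorted(set(user) - set(_DEFAULTS))
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {unknown}")
        cfg.update(user)
    return cfg


def _config_hash(cfg: dict, seed: int) -> str:
    blob = json.dumps({**cfg, "seed": seed}, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _file_checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _resolve_layers(cfg: dict) -> StructuralLayers:
    if cfg["omega_pyr_layer"] and cfg["omega_ast_layer"]:
        pyr = normalize_layer(load_layer(cfg["omega_pyr_layer"]))
        ast = normalize_layer(load_layer(cfg["omega_ast_layer"]))
        return StructuralLayers(Omega_Pyr=pyr, Omega_Ast=ast)
    return surrogate_layers(int(cfg["n_nodes"]), seed=int(cfg["layer_seed"]))


def _resolve_params(cfg: dict) -> ModelParameters:
    if cfg["parameters"]:
        return load_parameters(cfg["parameters"])
    return default_parameters()


def run_pipeline(cfg: dict, out_dir: str | Path, seed: int = 0,
                 force: bool = False) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg, seed)
    manifest_path = out / "manifest.json"
    manifest = {"config_hash": chash, "seed": seed, "stages": {}, "config": cfg}
    if manifest_path.exists() and not force:
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == chash:
            ok = all(
                (out / f).exists() and _file_checksum(out / f) == cs
                for stage in old.get("stages", {}).values()
                for f, cs in stage.items())
            if ok and old.get("stages"):
                return out
            if old.get("stages"):
                raise RuntimeError(
                    f"run directory {out} has a matching manifest but corrupted "
                    "or missing artifacts; re-run with force=True")

    layers = _resolve_layers(cfg)
    p = _resolve_params(cfg)
    sim_cfg = SimulationConfig(
        duration=float(cfg["batch_duration"]),
        dt=float(cfg["dt"]),
        calibration_duration=float(cfg["calibration_duration"]),
        batch_duration=float(cfg["batch_duration"]),
        n_batches=int(cfg["n_batches"]),
        seed=seed,
        record_stride=int(cfg["record_stride"]),
        omega_Glu=cfg["omega_Glu"],
        omega_GABA=cfg["omega_GABA"],
    )

    # --- simulate ------------------------------------------------------
    sim_dir = out / "simulate"
    sim_dir.mkdir(exist_ok=True)
    results = calibrate_then_batch(sim_cfg, layers, p)
    stage_files: dict[str, str] = {}
    for i, res in enumerate(results):
        f = sim_dir / f"batch{i:02d}.h5"
        res.save(f)
        stage_files[str(f.relative_to(out))] = _file_checksum(f)
    manifest["stages"]["simulate"] = stage_files

    # --- activity ------------------------------------------------------
    act_dir = out / "activity"
    act_dir.mkdir(exist_ok=True)
    stage_files = {}
    rows = []
    for i, res in enumerate(results):
        s = summarize_activity(res)
        rows.append({"batch": i, **s.whole_brain})
    import pandas as pd
    f = act_dir / "whole_brain.csv"
    pd.DataFrame(rows).to_csv(f, index=False)
    stage_files[str(f.relative_to(out))] = _file_checksum(f)
    manifest["stages"]["activity"] = stage_files

    # --- connectivity --------------------------------------------------
    con_dir = out / "connectivity"
    con_dir.mkdir(exist_ok=True)
    stage_files = {}
    nets = [conn.build_multiplex(res, float(cfg["threshold_fraction"]))
            for res in results]
    summaries = []
    for i, net in enumerate(nets):
        t = conn.summarize_topology(net, seed=seed)
        summaries.append({
            "batch": i,
            "clustering_coefficient": t.clustering_coefficient,
            "path_length": t.path_length,
            "edge_overlap": t.edge_overlap,
            "code_length": t.code_length,
            "n_communities": int(t.communities.max() + 1),
            "versatility": t.versatility.tolist(),
            "communities": t.communities.tolist(),
        })
    f = con_dir / "topology.json"
    f.write_text(json.dumps(summaries, indent=1))
    stage_files[str(f.relative_to(out))] = _file_checksum(f)
    manifest["stages"]["connectivity"] = stage_files

    # --- reduce --------------------------------------------------------
    red_dir = out / "reduce"
    red_dir.mkdir(exist_ok=True)
    stage_files = {}
    red = conn.structural_reducibility(nets[0])
    f = red_dir / "reducibility.json"
    f.write_text(json.dumps({
        "quality_curve": red.quality_curve,
        "best_n_merges": red.best_n_merges,
        "groups": red.reduced_members,
        "layer_names": [l.name for l in nets[0].layers],
    }, indent=1))
    stage_files[str(f.relative_to(out))] = _file_checksum(f)
    manifest["stages"]["reduce"] = stage_files

    manifest_path.write_text(json.dumps(manifest, indent=1))
    return out
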