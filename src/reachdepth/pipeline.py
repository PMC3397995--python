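"""End-to-end experiment orchestration.

``run_pipeline`` runs generate -> train -> evaluate -> analyze with one
artifact per stage in the output directory.  A stage whose artifact
already exists (same config hash) is skipped, so a partially failed run
resumes from the last completed stage.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import analysis, geometry3d as g3d, io, network as nw
from .config import ExperimentConfig
from .encoding import encode_dataset

__all__ = ["run_pipeline", "analysis_battery"]

log = logging.getLogger("reachdepth")


def _stage_fresh(path: Path, cfg_hash: str) -> bool:
    """True if the artifact exists and was produced under this config."""
    marker = path.with_suffix(path.suffix + ".json")
    if not (path.exists() and marker.exists()):
        return False
    try:
        return json.loads(marker.read_text()).get("config_hash") == cfg_hash
    except (json.JSONDecodeError, OSError):
        return False


def _mark(path: Path, cfg_hash: str, **extra) -> None:
    meta = {"config_hash": cfg_hash, "timestamp": time.time(), **extra}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, sort_keys=True, indent=1)
    )


def run_pipeline(config: ExperimentConfig, outdir: str | Path) -> Path:
    """Run the full experiment; returns the artifact directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    config.to_file(outdir / "config.yaml")
    seeds = {
        "train_set": config.seed,
        "test_set": config.seed + 1,
        "network": config.seed + 2,
    }
    (outdir / "seeds.json").write_text(json.dumps(seeds, indent=1))

    train_path = outdir / "train_set.h5"
    test_path = outdir / "test_set.h5"
    net_path = outdir / "network.h5"
    metrics_path = outdir / "metrics.json"

    t0 = time.perf_counter()
    if not _stage_fresh(train_path, cfg_hash):
        log.info("generating %d training samples", config.n_train)
        train_set = g3d.generate_training_set(
            config.n_train, seeds["train_set"], config.geometry
        )
        io.save_training_set(train_path, train_set,
                             {"config_hash": cfg_hash, "role": "train"})
        _mark(train_path, cfg_hash, seconds=time.perf_counter() - t0)
    train_set = io.load_training_set(train_path)

    t0 = time.perf_counter()
    if not _stage_fresh(test_path, cfg_hash):
        log.info("generating %d test samples", config.n_test)
        test_set = g3d.generate_training_set(
            config.n_test, seeds["test_set"], config.geometry
        )
        io.save_training_set(test_path, test_set,
                             {"config_hash": cfg_hash, "role": "test"})
        _mark(test_path, cfg_hash, seconds=time.perf_counter() - t0)
    test_set = io.load_training_set(test_path)

    t0 = time.perf_counter()
    if not _stage_fresh(net_path, cfg_hash):
        log.info("training %d-HLU network on %d samples",
                 config.training.n_hlu, len(train_set))
        result = nw.train(train_set, config.training, seeds["network"])
        io.save_network(net_path, result.params, {
            "config_hash": cfg_hash,
            "history": result.history[-50:],
            "converged": result.converged,
            "message": result.message,
        })
        _mark(net_path, cfg_hash, seconds=time.perf_counter() - t0)
    net = io.load_network(net_path)

    if not _stage_fresh(metrics_path, cfg_hash):
        log.info("evaluating on %d held-out samples", len(test_set))
        metrics = nw.evaluate(net, test_set)
        metrics["config_hash"] = cfg_hash
        metrics_path.write_text(json.dumps(metrics, indent=1, sort_keys=True))
        _mark(metrics_path, cfg_hash)

    tables_dir = outdir / "tables"
    if not _stage_fresh(tables_dir / "shift_indices.csv", cfg_hash):
        log.info("running analysis battery")
        tables = analysis_battery(net, config)
        tables_dir.mkdir(exist_ok=True)
        for name, df in tables.items():
            df.to_csv(tables_dir / f"{name}.csv", index=False)
        _mark(tables_dir / "shift_indices.csv", cfg_hash)
    return outdir


def analysis_battery(net: nw.NetworkParams, config: ExperimentConfig) -> dict:
    """Shift, gain and separability index tables for both layers."""
    import pandas as pd

    acfg = config.analysis
    n_hlu, n_pou = net.n_hlu, net.n_pou
    units = {
        "hlu": list(range(n_hlu if acfg.n_units == 0 else min(acfg.n_units, n_hlu))),
        "pou": list(range(n_pou if acfg.n_units == 0 else min(acfg.n_units, n_pou))),
    }
    shift_frames = []
    sweeps = [
        ("target_rf", "vergence", acfg.vergence_levels_deg),
        ("target_rf", "target_disparity_h", acfg.disparity_levels_deg),
        ("hand_rf", "hand_disparity_h", acfg.disparity_levels_deg),
        ("target_rd", "vergence", acfg.vergence_levels_deg),
        ("target_rd", "hand_depth_cm", analysis.GAIN_DEPTHS_CM),
        ("hand_rd", "target_depth_cm", analysis.GAIN_DEPTHS_CM),
        ("target_rd", "eye_horizontal", acfg.eye_levels_deg),
        ("target_rd", "eye_vertical", acfg.eye_levels_deg),
        ("target_rd", "head_horizontal", acfg.head_levels_deg),
        ("target_rd", "head_vertical", acfg.head_levels_deg),
    ]
    for layer in ("hlu", "pou"):
        for fld, modulator, levels in sweeps:
            shift_frames.append(analysis.shift_index_table(
                net, layer, units[layer], fld, modulator,
                np.asarray(levels, dtype=float),
            ))
    gain_frames = [
        analysis.gain_index_table(net, layer, units[layer])
        for layer in ("hlu", "pou")
    ]
    sep_frames = []
    for layer in ("hlu", "pou"):
        for pair in (("hand", "target"), ("hand", "vergence"),
                     ("target", "vergence")):
            sep_frames.append(analysis.separability_table(
                net, layer, units[layer], pair,
                np.asarray(acfg.separability_levels_cm, dtype=float),
            ))
    return {
        "shift_indices": pd.concat(shift_frames, ignore_index=True),
        "gain_indices": pd.concat(gain_frames, ignore_index=True),
        "separability": pd.concat(sep_frames, ignore_index=True),
        "ferraina": analysis.ferraina_protocol(net),
    }
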