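"""Serialisation: training sets and networks in HDF5 (arrays + JSON
metadata attribute), index tables in CSV."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np

from .geometry3d import GeometryParams, TrainingSet
from .network import NetworkParams, OLEWeights, POUSet

__all__ = [
    "save_training_set",
    "load_training_set",
    "save_network",
    "load_network",
]

_FORMAT_VERSION = 1


def _geometry_to_json(params: GeometryParams) -> str:
    return json.dumps(asdict(params), sort_keys=True)


def _geometry_from_json(text: str) -> GeometryParams:
    data = json.loads(text)
    data = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    return GeometryParams(**data)


def save_training_set(path: str | Path, dataset: TrainingSet,
                      metadata: dict | None = None) -> None:
    meta = {
        "version": _FORMAT_VERSION,
        "seed": dataset.seed,
        "n": len(dataset),
    }
    if metadata:
        meta.update(metadata)
    with h5py.File(path, "w") as f:
        for name in ("hand_obs", "target_obs", "eye", "head", "vergence_deg",
                     "motor_cm", "hand_cm", "target_cm", "fixation_cm"):
            f.create_dataset(name, data=getattr(dataset, name))
        f.attrs["metadata"] = json.dumps(meta, sort_keys=True)
        f.attrs["geometry"] = _geometry_to_json(dataset.params)


def load_training_set(path: str | Path) -> TrainingSet:
    with h5py.File(path, "r") as f:
        arrays = {
            name: np.asarray(f[name])
            for name in ("hand_obs", "target_obs", "eye", "head",
                         "vergence_deg", "motor_cm", "hand_cm", "target_cm",
                         "fixation_cm")
        }
        meta = json.loads(f.attrs["metadata"])
        params = _geometry_from_json(f.attrs["geometry"])
    return TrainingSet(seed=meta.get("seed"), params=params, **arrays)


def save_network(path: str | Path, net: NetworkParams,
                 metadata: dict | None = None) -> None:
    meta = {"version": _FORMAT_VERSION}
    if metadata:
        meta.update(metadata)
    with h5py.File(path, "w") as f:
        f.create_dataset("w_in", data=net.w_in)
        f.create_dataset("b_hlu", data=net.b_hlu)
        f.create_dataset("w_out", data=net.w_out)
        f.create_dataset("b_pou", data=net.b_pou)
        f.create_dataset("ole_w", data=net.ole.w)
        f.create_dataset("ole_L", data=net.ole.L)
        f.create_dataset("ole_Q", data=net.ole.Q)
        f.create_dataset("pou_directions", data=net.pou.directions)
        f.attrs["ole_sigma_k"] = net.ole.sigma_k
        f.attrs["metadata"] = json.dumps(meta, sort_keys=True)


def load_network(path: str | Path) -> NetworkParams:
    with h5py.File(path, "r") as f:
        ole = OLEWeights(
            w=np.asarray(f["ole_w"]),
            L=np.asarray(f["ole_L"]),
            Q=np.asarray(f["ole_Q"]),
            sigma_k=float(f.attrs["ole_sigma_k"]),
        )
        pou = POUSet(directions=np.asarray(f["pou_directions"]))
        return NetworkParams(
            w_in=np.asarray(f["w_in"]),
            b_hlu=np.asarray(f["b_hlu"]),
            w_out=np.asarray(f["w_out"]),
            b_pou=np.asarray(f["b_pou"]),
            ole=ole,
            pou=pou,
        )
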