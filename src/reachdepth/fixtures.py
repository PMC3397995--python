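"""Deterministic test fixtures: tiny scenes, toy networks and
constructed synthetic units with known analytic behaviour.

These are regular library code (not test-only helpers) so downstream
users can reproduce the constructions when validating the analysis
battery on their own networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry3d as g3d
from .encoding import N_INPUTS, input_layout
from .network import NetworkParams, OLEWeights, POUSet, sample_pou_directions

__all__ = [
    "make_fixtures",
    "toy_single_path_network",
    "identity_readout_network",
    "translating_field",
    "gain_only_field",
    "difference_field",
]


def translating_field(grid: np.ndarray, modulator: float,
                      width: float = 5.0, gain_per_unit: float = 1.0) -> np.ndarray:
    """1-D Gaussian field whose centre translates ``gain_per_unit``
    grid units per unit of the modulator (shift index oracle = gain)."""
    return np.exp(-0.5 * ((grid - gain_per_unit * modulator) / width) ** 2)


def gain_only_field(grid: np.ndarray, modulator: float,
                    width: float = 5.0) -> np.ndarray:
    """1-D Gaussian field at a fixed centre whose amplitude scales with
    the modulator (shift index oracle = 0)."""
    return (1.0 + 0.5 * np.tanh(modulator / 10.0)) * np.exp(
        -0.5 * (grid / width) ** 2
    )


def difference_field(a_levels: np.ndarray, b_levels: np.ndarray,
                     width: float = 15.0) -> np.ndarray:
    """2-D field depending only on ``b - a`` (separability oracle:
    -90 deg, subtractive interaction)."""
    a, b = np.meshgrid(a_levels, b_levels, indexing="ij")
    return np.exp(-0.5 * ((b - a) / width) ** 2)


def toy_single_path_network(
    w_in_value: float = 0.7, w_out_value: float = -0.4
) -> NetworkParams:
    """One-HLU, one-POU network for hand computation of forward passes
    and sensitivity vectors: every input weight equals ``w_in_value``,
    the single between-layer weight equals ``w_out_value``."""
    pou = POUSet(directions=np.array([[0.0, 1.0, 0.0]]))
    ole = OLEWeights(
        w=np.array([[0.0, 1.0, 0.0]]), L=np.zeros((1, 3)),
        Q=np.eye(1), sigma_k=0.01,
    )
    return NetworkParams(
        w_in=np.full((1, N_INPUTS), w_in_value),
        b_hlu=np.zeros(1),
        w_out=np.full((1, 1), w_out_value),
        b_pou=np.zeros(1),
        ole=ole,
        pou=pou,
    )


def identity_readout_network(seed: int = 0, n_hlu: int = 4) -> NetworkParams:
    """Small random network with a frozen random OLE (no training);
    used where only architectural behaviour matters."""
    rng = np.random.default_rng(seed)
    pou = sample_pou_directions(8, rng)
    ole = OLEWeights(
        w=rng.normal(scale=0.1, size=(8, 3)), L=np.zeros((8, 3)),
        Q=np.eye(8), sigma_k=0.01,
    )
    return NetworkParams(
        w_in=rng.normal(scale=0.05, size=(n_hlu, N_INPUTS)),
        b_hlu=rng.normal(scale=0.05, size=n_hlu),
        w_out=rng.normal(scale=0.05, size=(8, n_hlu)),
        b_pou=rng.normal(scale=0.05, size=8),
        ole=ole,
        pou=pou,
    )


@dataclass
class FixtureSet:
    scenes: list[g3d.Scene]
    tiny_set: g3d.TrainingSet
    toy_net: NetworkParams
    layout: dict[str, slice]


def make_fixtures(seed: int = 0) -> FixtureSet:
    """Small deterministic fixture set used across the test suites.

    Regeneration with the same seed is idempotent.
    """
    tiny = g3d.generate_training_set(8, seed)
    scenes = list(tiny.scenes())
    return FixtureSet(
        scenes=scenes,
        tiny_set=tiny,
        toy_net=toy_single_path_network(),
        layout=input_layout(),
    )
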