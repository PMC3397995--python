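"""Population input codes (network layer 1).

Four code families feed the network:

* a topographic retinal-position map per object (hand, target): 253
  Gaussian units (sigma = 20 deg) on a 10-deg grid within 90 deg
  eccentricity;
* a topographic retinal-disparity map per object: 67 units on a graded
  lattice inside a (45 deg, 30 deg) ellipse, with tuning width growing
  with the preferred disparity magnitude;
* a 6-unit push-pull code per rotation plant (eye, head), pairs of
  antagonistic units whose activations are linear in the angular-vector
  components, the eye frame rotated 45 deg about the vertical axis;
* one vergence unit, linear in the vergence angle, zero at zero.

All activations are bounded in [0, 1].  The full input vector
concatenates hand/target position maps, hand/target disparity maps, the
eye and head push-pull codes and the vergence unit (653 inputs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry3d import GeometryParams, TrainingSet

__all__ = [
    "PositionLattice",
    "DisparityLattice",
    "build_position_lattice",
    "build_disparity_lattice",
    "encode_position",
    "encode_disparity",
    "encode_eye_head",
    "encode_vergence",
    "input_layout",
    "encode_dataset",
    "N_POSITION_UNITS",
    "N_DISPARITY_UNITS",
    "N_INPUTS",
]

N_POSITION_UNITS = 253
N_DISPARITY_UNITS = 67
N_INPUTS = 2 * N_POSITION_UNITS + 2 * N_DISPARITY_UNITS + 2 * 6 + 1

POSITION_SIGMA_DEG = 20.0
POSITION_SPACING_DEG = 10.0
POSITION_RANGE_DEG = 90.0

DISPARITY_ELLIPSE_DEG = (45.0, 30.0)
DISPARITY_SIGMA_FLOOR_DEG = 10.0 / 60.0  # 10 arcmin
DISPARITY_A0 = 1.0
DISPARITY_A1 = 0.35


@dataclass(frozen=True)
class PositionLattice:
    """Preferred directions (deg) and common width of the position map."""

    x: np.ndarray
    z: np.ndarray
    sigma_deg: float = POSITION_SIGMA_DEG

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit": np.arange(len(self)), "pref_x_deg": self.x,
             "pref_z_deg": self.z, "sigma_deg": self.sigma_deg}
        )


@dataclass(frozen=True)
class DisparityLattice:
    """Preferred disparities and per-axis widths of the disparity map."""

    x: np.ndarray
    z: np.ndarray
    sigma_x_deg: np.ndarray
    sigma_z_deg: np.ndarray

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit": np.arange(len(self)), "pref_dh_deg": self.x,
             "pref_dv_deg": self.z, "sigma_h_deg": self.sigma_x_deg,
             "sigma_v_deg": self.sigma_z_deg}
        )


def build_position_lattice() -> PositionLattice:
    """10-deg grid of preferred directions within 90 deg eccentricity.

    Direct enumeration of the 19 x 19 grid clipped to the disk yields
    253 nodes.
    """
    grid = np.arange(-POSITION_RANGE_DEG, POSITION_RANGE_DEG + 1,
                     POSITION_SPACING_DEG)
    xx, zz = np.meshgrid(grid, grid, indexing="ij")
    keep = xx**2 + zz**2 <= POSITION_RANGE_DEG**2
    x, z = xx[keep], zz[keep]
    order = np.lexsort((x, z))
    return PositionLattice(x=x[order], z=z[order])


def build_disparity_lattice() -> DisparityLattice:
    """Graded disparity lattice: 67 nodes inside the (45, 30) ellipse.

    Construction (frozen): a 10-deg grid over the ellipse (43 nodes),
    refined with a 5-deg grid on [-10, 10]^2 (16 new nodes) and a 1-deg
    grid on [-1, 1]^2 (8 new nodes), realising the band rule of 1-deg
    spacing below 2 deg, 5-deg spacing up to 10 deg and 10-deg spacing
    elsewhere.
    """
    a, b = DISPARITY_ELLIPSE_DEG
    nodes: set[tuple[float, float]] = set()
    for x in np.arange(-40.0, 41.0, 10.0):
        for z in np.arange(-30.0, 31.0, 10.0):
            if (x / a) ** 2 + (z / b) ** 2 <= 1.0 + 1e-12:
                nodes.add((x, z))
    for x in np.arange(-10.0, 11.0, 5.0):
        for z in np.arange(-10.0, 11.0, 5.0):
            nodes.add((x, z))
    for x in (-1.0, 0.0, 1.0):
        for z in (-1.0, 0.0, 1.0):
            nodes.add((x, z))
    arr = np.array(sorted(nodes, key=lambda p: (p[1], p[0])))
    x, z = arr[:, 0], arr[:, 1]
    sig_x = np.maximum(DISPARITY_SIGMA_FLOOR_DEG, DISPARITY_A0 + DISPARITY_A1 * np.abs(x))
    sig_z = np.maximum(DISPARITY_SIGMA_FLOOR_DEG, DISPARITY_A0 + DISPARITY_A1 * np.abs(z))
    return DisparityLattice(x=x, z=z, sigma_x_deg=sig_x, sigma_z_deg=sig_z)


def encode_position(
    p_x, p_z, lattice: PositionLattice | None = None
) -> np.ndarray:
    """Gaussian population activation for retinal position(s) in deg.

    Scalars give a ``(253,)`` vector; arrays of shape ``(n,)`` give
    ``(n, 253)``.  Raises ``ValueError`` beyond 90 deg eccentricity.
    """
    lattice = lattice if lattice is not None else _POSITION_LATTICE
    p_x = np.asarray(p_x, dtype=float)
    p_z = np.asarray(p_z, dtype=float)
    if np.any(np.hypot(p_x, p_z) > POSITION_RANGE_DEG + 1e-9):
        raise ValueError("retinal position outside the 90 deg field")
    dx = p_x[..., None] - lattice.x
    dz = p_z[..., None] - lattice.z
    return np.exp(-(dx**2 + dz**2) / (2.0 * lattice.sigma_deg**2))


def encode_disparity(
    d_h, d_v, lattice: DisparityLattice | None = None
) -> np.ndarray:
    """Disparity population activation: separable Gaussian per unit with
    axis widths ``max(10 arcmin, 1 + 0.35 |preferred component|)`` deg.

    The width rule makes the population tuning non-symmetric: units
    preferring eccentric disparities are broader than the fine units
    near zero.
    """
    lattice = lattice if lattice is not None else _DISPARITY_LATTICE
    d_h = np.asarray(d_h, dtype=float)
    d_v = np.asarray(d_v, dtype=float)
    ex = (d_h[..., None] - lattice.x) / lattice.sigma_x_deg
    ez = (d_v[..., None] - lattice.z) / lattice.sigma_z_deg
    return np.exp(-0.5 * (ex**2 + ez**2))


_EYE_FRAME_ANGLE_DEG = 45.0


def encode_eye_head(
    r, r0_deg: float, rotate_frame_45: bool = False
) -> np.ndarray:
    """Push-pull 6-vector for an angular vector ``r`` (deg).

    Component ``k`` drives an antagonistic pair at
    ``0.5 +- r_k / (2 r0)``; pairs are ordered (X+, X-, Y+, Y-, Z+, Z-).
    For the eye, the (torsional, vertical) = (X, Y) axis pair is first
    rotated 45 deg about the vertical axis, mimicking the mixed
    vertical-torsional coordinates of the brainstem integrator; the
    horizontal (Z) component is untouched.

    Raises ``ValueError`` if the rotation magnitude exceeds ``r0``.
    """
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 1
    r = np.atleast_2d(r)
    if np.any(np.linalg.norm(r, axis=-1) > r0_deg + 1e-9):
        raise ValueError(f"rotation magnitude exceeds r0 = {r0_deg} deg")
    if rotate_frame_45:
        c = np.cos(np.radians(_EYE_FRAME_ANGLE_DEG))
        s = np.sin(np.radians(_EYE_FRAME_ANGLE_DEG))
        r = np.column_stack(
            [c * r[:, 0] - s * r[:, 1], s * r[:, 0] + c * r[:, 1], r[:, 2]]
        )
    half = r / (2.0 * r0_deg)
    out = np.empty((len(r), 6))
    out[:, 0::2] = 0.5 + half
    out[:, 1::2] = 0.5 - half
    return out[0] if scalar else out


def encode_vergence(
    vergence_deg, max_vergence_deg: float | None = None
) -> np.ndarray:
    """Linear vergence unit: 0 at zero vergence, 1 at the vergence of
    the nearest fixation in the data range (25 cm)."""
    if max_vergence_deg is None:
        max_vergence_deg = GeometryParams().max_vergence_deg
    v = np.asarray(vergence_deg, dtype=float)
    if np.any(v < -1e-12):
        raise ValueError("vergence must be non-negative")
    return v / max_vergence_deg


def input_layout() -> dict[str, slice]:
    """Slices of the concatenated 653-element input vector by group."""
    np_, nd = N_POSITION_UNITS, N_DISPARITY_UNITS
    ofs = 0
    layout = {}
    for name, size in (
        ("hand_position", np_), ("target_position", np_),
        ("hand_disparity", nd), ("target_disparity", nd),
        ("eye", 6), ("head", 6), ("vergence", 1),
    ):
        layout[name] = slice(ofs, ofs + size)
        ofs += size
    return layout


def encode_sample(
    hand_obs: np.ndarray,
    target_obs: np.ndarray,
    eye: np.ndarray,
    head: np.ndarray,
    vergence_deg,
    params: GeometryParams = GeometryParams(),
) -> np.ndarray:
    """Input vector(s) from raw observation arrays.

    ``hand_obs``/``target_obs`` are ``(..., 4)`` arrays of
    ``(p_x, p_z, d_h, d_v)``; ``eye``/``head`` are ``(..., 3)`` angular
    vectors; all in degrees.
    """
    hand_obs = np.atleast_2d(np.asarray(hand_obs, dtype=float))
    target_obs = np.atleast_2d(np.asarray(target_obs, dtype=float))
    eye = np.atleast_2d(np.asarray(eye, dtype=float))
    head = np.atleast_2d(np.asarray(head, dtype=float))
    verg = np.atleast_1d(np.asarray(vergence_deg, dtype=float))
    parts = [
        encode_position(hand_obs[:, 0], hand_obs[:, 1]),
        encode_position(target_obs[:, 0], target_obs[:, 1]),
        encode_disparity(hand_obs[:, 2], hand_obs[:, 3]),
        encode_disparity(target_obs[:, 2], target_obs[:, 3]),
        encode_eye_head(eye, params.pushpull_r0_eye_deg, rotate_frame_45=True),
        encode_eye_head(head, params.pushpull_r0_head_deg),
        encode_vergence(verg, params.max_vergence_deg)[:, None],
    ]
    x = np.concatenate(parts, axis=1)
    return x[0] if x.shape[0] == 1 and np.asarray(vergence_deg).ndim == 0 else x


def encode_dataset(dataset: TrainingSet) -> np.ndarray:
    """Encode a whole training set into an ``(n, 653)`` input matrix."""
    return encode_sample(
        dataset.hand_obs,
        dataset.target_obs,
        dataset.eye,
        dataset.head,
        dataset.vergence_deg,
        dataset.params,
    )


_POSITION_LATTICE = build_position_lattice()
_DISPARITY_LATTICE = build_disparity_lattice()


def position_lattice() -> PositionLattice:
    """The module-level frozen position lattice."""
    return _POSITION_LATTICE


def disparity_lattice() -> DisparityLattice:
    """The module-level frozen disparity lattice."""
    return _DISPARITY_LATTICE
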