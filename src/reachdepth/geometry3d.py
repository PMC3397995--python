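"""Exact 3D eye-head-shoulder kinematics for reach planning.

Coordinate conventions
----------------------
Right-handed, body-fixed frame with origin at the cyclopean eye:
``+X`` rightward, ``+Y`` anterior (straight-ahead gaze), ``+Z`` upward.
Rotations are represented as *angular vectors* in degrees: the unit
rotation axis scaled by the rotation angle, so the zero vector is the
identity and the norm equals the rotation angle.  Rotations are active;
the eye-in-head rotation is composed onto the head-on-body rotation.

Component meaning of an angular vector ``(r_X, r_Y, r_Z)``:

* ``r_X`` -- rotation about the lateral axis (vertical gaze / pitch),
* ``r_Y`` -- rotation about the anterior axis (torsion / roll),
* ``r_Z`` -- rotation about the vertical axis (horizontal gaze / yaw).

The module provides binocular eye orientations obeying binocular
Listing's law (L2: each eye's Listing plane rotates temporally with
vergence) modulated by the static VOR (ocular counter-roll with head
roll, Listing-plane pitch tilt with head pitch), per-eye and cyclopean
projections, signed retinal disparities (near-positive convention), the
geometric training-set generator and the default-context ("ignore all
extra-retinal signals") motor-vector reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "GeometryParams",
    "BodyPose",
    "RetinalObservation",
    "Scene",
    "TrainingSet",
    "DegenerateGeometryError",
    "ProjectionError",
    "rotvec_to_matrix",
    "matrix_to_rotvec",
    "vergence_from_distance",
    "distance_from_vergence",
    "midline_disparity",
    "binocular_eye_rotations",
    "make_pose",
    "project_point",
    "compute_disparity",
    "observe_point",
    "generate_training_set",
    "no_compensation_vector",
    "validate_scene",
]

_Y = np.array([0.0, 1.0, 0.0])


class DegenerateGeometryError(ValueError):
    """Fixation point at or behind the eye plane."""


class ProjectionError(ValueError):
    """Point at or behind an eye; no retinal projection exists."""


@dataclass(frozen=True)
class GeometryParams:
    """Fixed body geometry and oculomotor gains.

    Attributes
    ----------
    iod_cm:
        Interocular distance (cm).  Standard adult value.
    shoulder_offset_cm:
        Right-shoulder position relative to the cyclopean eye, body
        frame (cm): 15 cm rightward, 30 cm below, not behind.
    l2_gain:
        Binocular Listing (L2) gain: each eye's Listing plane rotates
        temporally about the vertical axis by ``l2_gain * vergence / 2``.
    counter_roll_gain:
        Static VOR ocular counter-roll gain against head roll.
    pitch_tilt_gain:
        Listing-plane tilt gain against head pitch.
    eye_range_deg, head_range_deg:
        Maximum sampled eye / head rotation magnitudes.
    pushpull_r0_eye_deg, pushpull_r0_head_deg:
        Push-pull reference amplitudes (encoder normalisation).
    fixation_range_cm:
        Admissible fixation distances (25 cm to 5 m).
    reach_radius_cm:
        Hand / target must lie within this distance of the shoulder.
    max_eccentricity_deg:
        Maximum cyclopean eccentricity of hand / target.
    disparity_range_deg:
        (horizontal, vertical) retinal-disparity bounds of the data set.
    default_fixation_cm:
        Fixation distance of the default context used both for probe
        contexts and for the no-compensation reconstruction.
    """

    iod_cm: float = 6.5
    shoulder_offset_cm: tuple[float, float, float] = (15.0, 0.0, -30.0)
    l2_gain: float = 1.0
    counter_roll_gain: float = 0.1
    pitch_tilt_gain: float = 0.5
    eye_range_deg: float = 45.0
    head_range_deg: float = 65.0
    pushpull_r0_eye_deg: float = 50.0
    pushpull_r0_head_deg: float = 70.0
    fixation_range_cm: tuple[float, float] = (25.0, 500.0)
    reach_radius_cm: float = 85.0
    max_eccentricity_deg: float = 70.0
    disparity_range_deg: tuple[float, float] = (25.0, 10.0)
    default_fixation_cm: float = 50.0

    @property
    def vergence_range_deg(self) -> tuple[float, float]:
        """(min, max) vergence over the fixation-distance range."""
        near, far = self.fixation_range_cm
        return (
            vergence_from_distance(far, self.iod_cm),
            vergence_from_distance(near, self.iod_cm),
        )

    @property
    def max_vergence_deg(self) -> float:
        return self.vergence_range_deg[1]


def rotvec_to_matrix(r: np.ndarray) -> np.ndarray:
    """Rotation matrix for an angular vector in degrees (active)."""
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite rotation vector")
    return Rotation.from_rotvec(r, degrees=True).as_matrix()


def matrix_to_rotvec(mat: np.ndarray) -> np.ndarray:
    """Angular vector (degrees) of a rotation matrix."""
    return Rotation.from_matrix(mat).as_rotvec(degrees=True)


def _axis_angle_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues formula for a unit axis and angle in radians."""
    return Rotation.from_rotvec(np.asarray(axis) * angle_rad).as_matrix()


def _minimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Shortest rotation mapping unit vector ``a`` onto unit vector ``b``.

    Its axis is orthogonal to ``a``, hence lies in the plane orthogonal
    to ``a`` -- exactly the Listing constraint when ``a`` is the primary
    direction.
    """
    c = np.cross(a, b)
    s = np.linalg.norm(c)
    d = float(np.dot(a, b))
    if s < 1e-15:
        if d > 0:
            return np.eye(3)
        raise DegenerateGeometryError("target direction opposite to primary")
    return _axis_angle_matrix(c / s, float(np.arctan2(s, d)))


def vergence_from_distance(distance_cm: float, iod_cm: float = 6.5) -> float:
    """Vergence angle (deg) for symmetric midline fixation at a distance."""
    return float(np.degrees(2.0 * np.arctan2(iod_cm / 2.0, distance_cm)))


def distance_from_vergence(vergence_deg: float, iod_cm: float = 6.5) -> float:
    """Symmetric midline fixation distance (cm) for a vergence angle."""
    if vergence_deg <= 0:
        raise ValueError("vergence must be positive")
    return float(iod_cm / 2.0 / np.tan(np.radians(vergence_deg) / 2.0))


def midline_disparity(
    object_cm: float, fixation_cm: float, iod_cm: float = 6.5
) -> float:
    """Horizontal disparity (deg) of a midline point at ``object_cm``
    while fixating the midline at ``fixation_cm``; positive = nearer."""
    return vergence_from_distance(object_cm, iod_cm) - vergence_from_distance(
        fixation_cm, iod_cm
    )


@dataclass(frozen=True)
class BodyPose:
    """One eye-head configuration with its fixation point.

    ``eye`` is the cyclopean (gaze-defining) eye-in-head angular vector,
    ``head`` the head-on-body angular vector, both in degrees.
    ``left`` / ``right`` are the per-eye eye-in-head rotations derived
    from binocular Listing's law, frozen at construction.
    """

    eye: np.ndarray
    head: np.ndarray
    vergence_deg: float
    fixation_point_cm: np.ndarray
    left: np.ndarray
    right: np.ndarray

    def eye_positions(self, params: GeometryParams) -> tuple[np.ndarray, np.ndarray]:
        """Left / right eye positions in the body frame (cm)."""
        rh = rotvec_to_matrix(self.head)
        half = np.array([params.iod_cm / 2.0, 0.0, 0.0])
        return -rh @ half, rh @ half

    def eye_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (head-then-eye) rotation matrices of both eyes."""
        rh = rotvec_to_matrix(self.head)
        return rh @ rotvec_to_matrix(self.left), rh @ rotvec_to_matrix(self.right)

    def cyclopean_matrix(self) -> np.ndarray:
        return rotvec_to_matrix(self.head) @ rotvec_to_matrix(self.eye)


@dataclass(frozen=True)
class RetinalObservation:
    """Cyclopean direction and binocular disparity of one point (deg)."""

    p_x: float
    p_z: float
    d_h: float
    d_v: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_x, self.p_z, self.d_h, self.d_v])


@dataclass(frozen=True)
class Scene:
    """One geometric configuration: hand, target and body pose.

    Hand / target are in shoulder-centred coordinates (cm).
    """

    hand_cm: np.ndarray
    target_cm: np.ndarray
    pose: BodyPose


def _vergence_of_point(
    point: np.ndarray, eye_l: np.ndarray, eye_r: np.ndarray
) -> float:
    """Exact angle (deg) between the two eye-to-point gaze lines."""
    gl = point - eye_l
    gr = point - eye_r
    c = np.cross(gl, gr)
    return float(
        np.degrees(np.arctan2(np.linalg.norm(c), float(np.dot(gl, gr))))
    )


def binocular_eye_rotations(
    fixation_point_cm: np.ndarray,
    head: np.ndarray,
    params: GeometryParams = GeometryParams(),
) -> tuple[np.ndarray, np.ndarray, float]:
    """Eye-in-head angular vectors of both eyes fixating a point.

    Each eye's orientation is the minimal (Listing) rotation from its
    own primary direction to the eye-to-fixation direction.  The primary
    direction is straight-ahead rotated (i) temporally about the
    vertical axis by ``l2_gain * vergence / 2`` (binocular Listing's
    law) and (ii) about the lateral axis by ``pitch_tilt_gain`` times
    the head pitch (static VOR tilt of the Listing plane).  An ocular
    counter-roll of ``-counter_roll_gain`` times the head roll about the
    gaze line is composed on top (static torsional VOR).

    Returns ``(left, right, vergence_deg)``; rotation vectors are in the
    head frame, degrees.

    Raises
    ------
    DegenerateGeometryError
        If the fixation point is not strictly in front of both eyes.
    """
    fixation_point_cm = np.asarray(fixation_point_cm, dtype=float)
    head = np.asarray(head, dtype=float)
    rh = rotvec_to_matrix(head)
    half = np.array([params.iod_cm / 2.0, 0.0, 0.0])
    rolls = []
    # exact vergence from the two gaze lines (space frame)
    pos_l, pos_r = -rh @ half, rh @ half
    vergence = _vergence_of_point(fixation_point_cm, pos_l, pos_r)
    eta = np.radians(params.l2_gain * vergence / 2.0)
    pitch_tilt = np.radians(params.pitch_tilt_gain * head[0])
    counter_roll = -np.radians(params.counter_roll_gain * head[1])
    for sign, offset in ((+1.0, -half), (-1.0, half)):
        # head-frame direction from this eye to the fixation point
        d = rh.T @ fixation_point_cm - offset
        dist = np.linalg.norm(d)
        if dist < 1e-9 or d[1] <= 0:
            raise DegenerateGeometryError("fixation point behind the eye plane")
        d = d / dist
        # temporal L2 rotation: left eye leftward (+z), right eye rightward
        tilt = _axis_angle_matrix(np.array([0.0, 0.0, 1.0]), sign * eta)
        tilt = tilt @ _axis_angle_matrix(np.array([1.0, 0.0, 0.0]), pitch_tilt)
        primary = tilt @ _Y
        r_eye = _minimal_rotation(primary, d) @ tilt
        r_eye = _axis_angle_matrix(d, counter_roll) @ r_eye
        rolls.append(matrix_to_rotvec(r_eye))
    return rolls[0], rolls[1], vergence


def make_pose(
    gaze_direction: np.ndarray,
    fixation_distance_cm: float,
    head: np.ndarray = (0.0, 0.0, 0.0),
    params: GeometryParams = GeometryParams(),
) -> BodyPose:
    """Build a :class:`BodyPose` from a head-frame gaze direction and a
    fixation distance along it (cyclopean ray)."""
    head = np.asarray(head, dtype=float)
    g = np.asarray(gaze_direction, dtype=float)
    g = g / np.linalg.norm(g)
    rh = rotvec_to_matrix(head)
    fix = rh @ (g * float(fixation_distance_cm))
    left, right, vergence = binocular_eye_rotations(fix, head, params)
    # cyclopean eye: same Listing/VOR construction without the L2 tilt
    pitch_tilt = np.radians(params.pitch_tilt_gain * head[0])
    tilt = _axis_angle_matrix(np.array([1.0, 0.0, 0.0]), pitch_tilt)
    d = rh.T @ fix
    d = d / np.linalg.norm(d)
    r_cyc = _minimal_rotation(tilt @ _Y, d) @ tilt
    r_cyc = (
        _axis_angle_matrix(d, -np.radians(params.counter_roll_gain * head[1]))
        @ r_cyc
    )
    return BodyPose(
        eye=matrix_to_rotvec(r_cyc),
        head=head,
        vergence_deg=vergence,
        fixation_point_cm=fix,
        left=left,
        right=right,
    )


def project_point(
    point_cm: np.ndarray,
    eye_position_cm: np.ndarray,
    eye_rotation: np.ndarray,
) -> tuple[float, float]:
    """Angular (azimuth, elevation) coordinates of a point in a rotated
    eye's frame, degrees.

    Azimuth is positive rightward, elevation positive upward; (0, 0) iff
    the point lies on the gaze line.  ``eye_rotation`` may be a rotation
    matrix or an angular vector (degrees) in the body frame.

    Raises
    ------
    ProjectionError
        If the point is at or behind the rotated eye's frontal plane.
    """
    eye_rotation = np.asarray(eye_rotation, dtype=float)
    mat = eye_rotation if eye_rotation.shape == (3, 3) else rotvec_to_matrix(eye_rotation)
    v = mat.T @ (np.asarray(point_cm, dtype=float) - np.asarray(eye_position_cm, dtype=float))
    if v[1] <= 1e-9:
        raise ProjectionError("point at or behind the eye")
    azimuth = np.degrees(np.arctan2(v[0], v[1]))
    elevation = np.degrees(np.arctan2(v[2], np.hypot(v[0], v[1])))
    return float(azimuth), float(elevation)


def compute_disparity(
    point_cm: np.ndarray,
    pose: BodyPose,
    params: GeometryParams = GeometryParams(),
) -> tuple[float, float]:
    """Signed (horizontal, vertical) retinal disparity of a point, deg.

    ``d_h = azimuth_left - azimuth_right``: positive for points nearer
    than fixation, negative for farther (near-positive convention).
    ``d_v`` analogous with elevations.
    """
    pos_l, pos_r = pose.eye_positions(params)
    mat_l, mat_r = pose.eye_matrices()
    az_l, el_l = project_point(point_cm, pos_l, mat_l)
    az_r, el_r = project_point(point_cm, pos_r, mat_r)
    return az_l - az_r, el_l - el_r


def observe_point(
    point_cm: np.ndarray,
    pose: BodyPose,
    params: GeometryParams = GeometryParams(),
) -> RetinalObservation:
    """Cyclopean projection plus binocular disparity of a point."""
    p_x, p_z = project_point(point_cm, np.zeros(3), pose.cyclopean_matrix())
    d_h, d_v = compute_disparity(point_cm, pose, params)
    return RetinalObservation(p_x=p_x, p_z=p_z, d_h=d_h, d_v=d_v)


def validate_scene(scene: Scene, params: GeometryParams = GeometryParams()) -> None:
    """Raise ``ValueError`` if a scene violates the sampling constraints."""
    shoulder = np.asarray(params.shoulder_offset_cm)
    gaze = scene.pose.cyclopean_matrix() @ _Y
    for name, p_shoulder in (("hand", scene.hand_cm), ("target", scene.target_cm)):
        p = np.asarray(p_shoulder) + shoulder  # body frame
        if np.linalg.norm(np.asarray(p_shoulder)) > params.reach_radius_cm + 1e-9:
            raise ValueError(f"{name} outside reach radius")
        cosang = float(np.dot(p, gaze) / np.linalg.norm(p))
        ecc = np.degrees(np.arccos(np.clip(cosang / 1.0, -1, 1)))
        if ecc > params.max_eccentricity_deg + 1e-9:
            raise ValueError(f"{name} eccentricity {ecc:.1f} deg out of range")
    lo, hi = params.fixation_range_cm
    dist = float(np.linalg.norm(scene.pose.fixation_point_cm))
    if not (lo - 1e-6 <= dist <= hi + 1e-6):
        raise ValueError(f"fixation distance {dist:.1f} cm out of range")
    if np.linalg.norm(scene.pose.eye) > params.eye_range_deg + 2.0:
        raise ValueError("eye rotation out of range")
    if np.linalg.norm(scene.pose.head) > params.head_range_deg + 1e-9:
        raise ValueError("head rotation out of range")


# ---------------------------------------------------------------------------
# Training-set generation
# ---------------------------------------------------------------------------


@dataclass
class TrainingSet:
    """Column-oriented set of training samples.

    All angular quantities in degrees, positions in cm.  ``motor_cm`` is
    the ideal movement vector ``target - hand`` in shoulder coordinates.
    """

    hand_obs: np.ndarray      # (n, 4): p_x, p_z, d_h, d_v
    target_obs: np.ndarray    # (n, 4)
    eye: np.ndarray           # (n, 3) cyclopean eye-in-head angular vectors
    head: np.ndarray          # (n, 3)
    vergence_deg: np.ndarray  # (n,)
    motor_cm: np.ndarray      # (n, 3)
    hand_cm: np.ndarray       # (n, 3) shoulder frame
    target_cm: np.ndarray     # (n, 3)
    fixation_cm: np.ndarray   # (n, 3) body frame
    seed: int | None = None
    params: GeometryParams = field(default_factory=GeometryParams)

    def __len__(self) -> int:
        return len(self.vergence_deg)

    def __getitem__(self, idx) -> "TrainingSet":
        if isinstance(idx, (int, np.integer)):
            idx = np.array([idx])
        return TrainingSet(
            hand_obs=self.hand_obs[idx],
            target_obs=self.target_obs[idx],
            eye=self.eye[idx],
            head=self.head[idx],
            vergence_deg=self.vergence_deg[idx],
            motor_cm=self.motor_cm[idx],
            hand_cm=self.hand_cm[idx],
            target_cm=self.target_cm[idx],
            fixation_cm=self.fixation_cm[idx],
            seed=self.seed,
            params=self.params,
        )

    def scenes(self) -> Iterator[Scene]:
        for i in range(len(self)):
            head = self.head[i]
            left, right, _ = binocular_eye_rotations(
                self.fixation_cm[i], head, self.params
            )
            pose = BodyPose(
                eye=self.eye[i],
                head=head,
                vergence_deg=float(self.vergence_deg[i]),
                fixation_point_cm=self.fixation_cm[i],
                left=left,
                right=right,
            )
            yield Scene(
                hand_cm=self.hand_cm[i], target_cm=self.target_cm[i], pose=pose
            )


def _sample_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# -- batched rotation helpers (generator hot path) --------------------------


def _batch_matrices(rotvec_deg: np.ndarray) -> np.ndarray:
    return Rotation.from_rotvec(rotvec_deg, degrees=True).as_matrix()


def _batch_axis_angle(axis: np.ndarray, angle_rad: np.ndarray) -> np.ndarray:
    return Rotation.from_rotvec(axis * angle_rad[:, None]).as_matrix()


def _rx(angle_rad: np.ndarray) -> np.ndarray:
    n = len(angle_rad)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    out = np.zeros((n, 3, 3))
    out[:, 0, 0] = 1.0
    out[:, 1, 1] = c; out[:, 1, 2] = -s
    out[:, 2, 1] = s; out[:, 2, 2] = c
    return out


def _rz(angle_rad: np.ndarray) -> np.ndarray:
    n = len(angle_rad)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    out = np.zeros((n, 3, 3))
    out[:, 0, 0] = c; out[:, 0, 1] = -s
    out[:, 1, 0] = s; out[:, 1, 1] = c
    out[:, 2, 2] = 1.0
    return out


def _batch_minimal_rotation(p: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Batched shortest rotation mapping unit rows of ``p`` onto ``d``."""
    axis = np.cross(p, d)
    s = np.linalg.norm(axis, axis=1)
    ang = np.arctan2(s, np.einsum("ij,ij->i", p, d))
    safe = np.where(s > 1e-15, s, 1.0)
    return _batch_axis_angle(axis / safe[:, None], np.where(s > 1e-15, ang, 0.0))


def _batch_vergence(points: np.ndarray, pos_l: np.ndarray,
                    pos_r: np.ndarray) -> np.ndarray:
    gl = points - pos_l
    gr = points - pos_r
    c = np.linalg.norm(np.cross(gl, gr), axis=1)
    d = np.einsum("ij,ij->i", gl, gr)
    return np.degrees(np.arctan2(c, d))


def _batch_eye_rotation(
    d: np.ndarray,
    eta_rad: np.ndarray,
    pitch_tilt_rad: np.ndarray,
    counter_roll_rad: np.ndarray,
    l2_sign: float,
) -> np.ndarray:
    """Batched Listing/L2/VOR eye orientation matrices for unit gaze
    targets ``d`` in the head frame (see binocular_eye_rotations)."""
    tilt = np.einsum(
        "nij,njk->nik", _rz(l2_sign * eta_rad), _rx(pitch_tilt_rad)
    )
    primary = tilt[:, :, 1]  # tilt @ y
    r_list = _batch_minimal_rotation(primary, d)
    r_eye = np.einsum("nij,njk->nik", r_list, tilt)
    r_cr = _batch_axis_angle(d, counter_roll_rad)
    return np.einsum("nij,njk->nik", r_cr, r_eye)


def _batch_project(points: np.ndarray, eye_pos: np.ndarray,
                   eye_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched azimuth/elevation (deg) plus a validity mask."""
    v = np.einsum("nji,nj->ni", eye_mat, points - eye_pos)
    ok = v[:, 1] > 1e-9
    az = np.degrees(np.arctan2(v[:, 0], np.where(ok, v[:, 1], 1.0)))
    el = np.degrees(np.arctan2(v[:, 2], np.hypot(v[:, 0], v[:, 1])))
    return az, el, ok


def _sample_gaze_directions(rng: np.random.Generator, n: int, max_deg: float) -> np.ndarray:
    """Directions within ``max_deg`` of straight ahead: polar angle
    uniform in [0, max], azimuth uniform (matches uniform rotation-
    magnitude sampling of Listing-plane eye orientations)."""
    ecc = np.radians(rng.uniform(0.0, max_deg, size=n))
    phase = rng.uniform(0.0, 2 * np.pi, size=n)
    s = np.sin(ecc)
    return np.column_stack(
        [s * np.sin(phase), np.cos(ecc), s * np.cos(phase)]
    )


def _solve_fixation_distance(
    vergence_deg: float,
    gaze_space: np.ndarray,
    pos_l: np.ndarray,
    pos_r: np.ndarray,
    lo: float = 2.0,
    hi: float = 5000.0,
    iters: int = 60,
) -> float:
    """Distance along the cyclopean gaze ray at which the exact two-eye
    vergence equals ``vergence_deg`` (bisection; vergence is monotone
    decreasing in distance)."""
    a, b = lo, hi
    for _ in range(iters):
        m = 0.5 * (a + b)
        v = _vergence_of_point(m * gaze_space, pos_l, pos_r)
        if v > vergence_deg:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


def _sample_pose_batch(
    rng: np.random.Generator, m: int, params: GeometryParams,
    gaze_tries: int = 40,
) -> dict[str, np.ndarray]:
    """Vectorised pose sampling: heads, gazes, exact vergences and the
    per-eye / cyclopean rotation matrices for ``m`` poses."""
    vmin, vmax = params.vergence_range_deg
    lo_fix, hi_fix = params.fixation_range_cm
    half = np.array([params.iod_cm / 2.0, 0.0, 0.0])

    head = _sample_sphere(rng, m) * rng.uniform(
        0.0, params.head_range_deg, size=(m, 1)
    )
    rh = _batch_matrices(head)
    pos_r = np.einsum("nij,j->ni", rh, half)
    pos_l = -pos_r
    vergence = rng.uniform(vmin, vmax, size=m)

    g_head = np.empty((m, 3))
    dist = np.empty(m)
    unresolved = np.ones(m, dtype=bool)
    for _ in range(gaze_tries):
        idx = np.flatnonzero(unresolved)
        if idx.size == 0:
            break
        g = _sample_gaze_directions(rng, idx.size, params.eye_range_deg)
        g_space = np.einsum("nij,nj->ni", rh[idx], g)
        # bisection for the gaze-ray distance of the drawn vergence
        a = np.full(idx.size, 2.0)
        b = np.full(idx.size, 5000.0)
        for _ in range(60):
            mid = 0.5 * (a + b)
            v = _batch_vergence(mid[:, None] * g_space, pos_l[idx], pos_r[idx])
            hi = v > vergence[idx]
            a = np.where(hi, mid, a)
            b = np.where(hi, b, mid)
        d = 0.5 * (a + b)
        # near the vergence maximum only near-sagittal gazes reach the
        # 25 cm bound; accept up to 1 cm short, clip, and recompute the
        # exact vergence from the clipped geometry below
        ok = (d >= lo_fix - 1.0) & (d <= hi_fix + 1e-6)
        sel = idx[ok]
        g_head[sel] = g[ok]
        dist[sel] = np.clip(d[ok], lo_fix, hi_fix)
        unresolved[sel] = False
    if unresolved.any():  # pragma: no cover - ranges make this unreachable
        raise RuntimeError("infeasible pose configuration")

    g_space = np.einsum("nij,nj->ni", rh, g_head)
    fix = dist[:, None] * g_space
    vergence_exact = _batch_vergence(fix, pos_l, pos_r)

    eta = np.radians(params.l2_gain * vergence_exact / 2.0)
    pitch_tilt = np.radians(params.pitch_tilt_gain * head[:, 0])
    counter_roll = -np.radians(params.counter_roll_gain * head[:, 1])
    fix_head = np.einsum("nji,nj->ni", rh, fix)

    mats = {}
    for name, sign, offset in (("left", +1.0, -half), ("right", -1.0, half)):
        d = fix_head - offset
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        mats[name] = _batch_eye_rotation(d, eta, pitch_tilt, counter_roll, sign)
    d = fix_head / np.linalg.norm(fix_head, axis=1, keepdims=True)
    mats["cyc"] = _batch_eye_rotation(
        d, np.zeros(m), pitch_tilt, counter_roll, 0.0
    )

    return {
        "head": head,
        "rh": rh,
        "pos_l": pos_l,
        "pos_r": pos_r,
        "fix": fix,
        "vergence": vergence_exact,
        "mat_left": np.einsum("nij,njk->nik", rh, mats["left"]),
        "mat_right": np.einsum("nij,njk->nik", rh, mats["right"]),
        "mat_cyc": np.einsum("nij,njk->nik", rh, mats["cyc"]),
        "eye": Rotation.from_matrix(mats["cyc"]).as_rotvec(degrees=True),
    }


def _sample_object_batch(
    rng: np.random.Generator,
    poses: dict[str, np.ndarray],
    params: GeometryParams,
    tries: int = 40,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One object per pose: shoulder-frame position, observation array
    (p_x, p_z, d_h, d_v) and a validity mask."""
    m = len(poses["vergence"])
    shoulder = np.asarray(params.shoulder_offset_cm)
    dh_max, dv_max = params.disparity_range_deg
    gaze = poses["mat_cyc"][:, :, 1]
    pos = np.empty((m, 3))
    obs = np.empty((m, 4))
    unresolved = np.ones(m, dtype=bool)
    for _ in range(tries):
        idx = np.flatnonzero(unresolved)
        if idx.size == 0:
            break
        # uniform in the reach ball
        p_sh = _sample_sphere(rng, idx.size) * (
            params.reach_radius_cm * rng.uniform(0, 1, size=(idx.size, 1)) ** (1 / 3)
        )
        p_body = p_sh + shoulder
        r = np.linalg.norm(p_body, axis=1)
        cosang = np.einsum("ij,ij->i", p_body, gaze[idx]) / np.maximum(r, 1e-12)
        ecc_ok = (r >= 1.0) & (
            np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            <= params.max_eccentricity_deg
        )
        az_c, el_c, ok_c = _batch_project(
            p_body, np.zeros(3), poses["mat_cyc"][idx])
        az_l, el_l, ok_l = _batch_project(
            p_body, poses["pos_l"][idx], poses["mat_left"][idx])
        az_r, el_r, ok_r = _batch_project(
            p_body, poses["pos_r"][idx], poses["mat_right"][idx])
        d_h = az_l - az_r
        d_v = el_l - el_r
        ok = (
            ecc_ok & ok_c & ok_l & ok_r
            & (np.abs(d_h) <= dh_max) & (np.abs(d_v) <= dv_max)
        )
        sel = idx[ok]
        pos[sel] = p_sh[ok]
        obs[sel] = np.column_stack([az_c, el_c, d_h, d_v])[ok]
        unresolved[sel] = False
    return pos, obs, ~unresolved


def generate_training_set(
    n: int,
    seed: int,
    params: GeometryParams = GeometryParams(),
) -> TrainingSet:
    """Generate ``n`` geometric training samples (vectorised).

    Sampling scheme (all streams from one seeded generator):

    * head angular vector: uniform axis on the sphere, magnitude uniform
      in [0, 65 deg];
    * cyclopean gaze direction: eccentricity uniform in [0, 45 deg];
    * vergence: exactly uniform between the vergences of 5 m and 25 cm
      fixation; the fixation distance along the gaze ray is solved from
      the exact two-eye geometry (bisection), and the gaze direction is
      resampled if that distance leaves [25 cm, 5 m] (keeps the
      vergence marginal uniform by construction);
    * hand and target: uniform in the 85 cm reach ball around the right
      shoulder, rejected against cyclopean eccentricity <= 70 deg,
      frontal placement in both eyes and the disparity data range.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    chunks: list[dict[str, np.ndarray]] = []
    filled = 0
    while filled < n:
        m = min(max(int((n - filled) * 1.3) + 16, 64), 200_000)
        poses = _sample_pose_batch(rng, m, params)
        hand_pos, hand_obs, hand_ok = _sample_object_batch(rng, poses, params)
        tgt_pos, tgt_obs, tgt_ok = _sample_object_batch(rng, poses, params)
        keep = np.flatnonzero(hand_ok & tgt_ok)[: n - filled]
        chunks.append({
            "hand_obs": hand_obs[keep],
            "target_obs": tgt_obs[keep],
            "eye": poses["eye"][keep],
            "head": poses["head"][keep],
            "vergence": poses["vergence"][keep],
            "motor": tgt_pos[keep] - hand_pos[keep],
            "hand": hand_pos[keep],
            "target": tgt_pos[keep],
            "fix": poses["fix"][keep],
        })
        filled += len(keep)

    def cat(key: str) -> np.ndarray:
        return np.concatenate([c[key] for c in chunks])

    return TrainingSet(
        hand_obs=cat("hand_obs"),
        target_obs=cat("target_obs"),
        eye=cat("eye"),
        head=cat("head"),
        vergence_deg=cat("vergence"),
        motor_cm=cat("motor"),
        hand_cm=cat("hand"),
        target_cm=cat("target"),
        fixation_cm=cat("fix"),
        seed=seed,
        params=params,
    )


# ---------------------------------------------------------------------------
# Default-context reconstruction (no extra-retinal compensation)
# ---------------------------------------------------------------------------


def default_pose(params: GeometryParams = GeometryParams()) -> BodyPose:
    """Zero eye/head rotation, fixation straight ahead at the default
    distance (50 cm)."""
    return make_pose(_Y, params.default_fixation_cm, np.zeros(3), params)


def _invert_observation(
    obs: RetinalObservation,
    pose: BodyPose,
    params: GeometryParams,
    lo: float = 2.0,
    hi: float = 300.0,
    iters: int = 60,
) -> np.ndarray:
    """Body-frame point whose cyclopean direction and horizontal
    disparity under ``pose`` match the observation.

    The distance along the cyclopean ray is solved from ``d_h`` by
    bisection (disparity is monotone decreasing in distance) and
    restricted to the plausible workspace depth range [2, 300] cm: a
    disparity more negative than the context's point-at-infinity limit
    has no geometric preimage at all, so the reconstruction saturates
    at the workspace bound instead of diverging.  Vertical disparity is
    redundant and ignored.
    """
    az, el = np.radians(obs.p_x), np.radians(obs.p_z)
    v_eye = np.array(
        [np.cos(el) * np.sin(az), np.cos(el) * np.cos(az), np.sin(el)]
    )
    ray = pose.cyclopean_matrix() @ v_eye
    pos_l, pos_r = pose.eye_positions(params)
    mat_l, mat_r = pose.eye_matrices()

    def dh_at(t: float) -> float:
        p = t * ray
        az_l, _ = project_point(p, pos_l, mat_l)
        az_r, _ = project_point(p, pos_r, mat_r)
        return az_l - az_r

    a, b = lo, hi
    if obs.d_h >= dh_at(a):
        t = a
    elif obs.d_h <= dh_at(b):
        t = b
    else:
        for _ in range(iters):
            m = 0.5 * (a + b)
            if dh_at(m) > obs.d_h:
                a = m
            else:
                b = m
        t = 0.5 * (a + b)
    return t * ray


def no_compensation_vector(
    hand_obs: RetinalObservation,
    target_obs: RetinalObservation,
    params: GeometryParams = GeometryParams(),
    context: BodyPose | None = None,
) -> np.ndarray:
    """Movement vector that results if all extra-retinal signals are
    ignored: both observations are re-interpreted under the default
    context (primary eye/head position, 50 cm fixation)."""
    pose = context if context is not None else default_pose(params)
    p_hand = _invert_observation(hand_obs, pose, params)
    p_target = _invert_observation(target_obs, pose, params)
    return p_target - p_hand


def _batch_invert_observations(
    obs: np.ndarray,
    pose: BodyPose,
    params: GeometryParams,
    lo: float = 2.0,
    hi: float = 300.0,
    iters: int = 60,
) -> np.ndarray:
    """Vectorised :func:`_invert_observation` for an ``(n, 4)`` array of
    observations under a single context pose."""
    az = np.radians(obs[:, 0])
    el = np.radians(obs[:, 1])
    v_eye = np.column_stack(
        [np.cos(el) * np.sin(az), np.cos(el) * np.cos(az), np.sin(el)]
    )
    rays = v_eye @ pose.cyclopean_matrix().T
    pos_l, pos_r = pose.eye_positions(params)
    mat_l, mat_r = pose.eye_matrices()

    def dh_at(t: np.ndarray) -> np.ndarray:
        p = t[:, None] * rays
        vl = (p - pos_l) @ mat_l
        vr = (p - pos_r) @ mat_r
        return np.degrees(
            np.arctan2(vl[:, 0], vl[:, 1]) - np.arctan2(vr[:, 0], vr[:, 1])
        )

    a = np.full(len(obs), lo)
    b = np.full(len(obs), hi)
    target = obs[:, 2]
    for _ in range(iters):
        mid = 0.5 * (a + b)
        near = dh_at(mid) > target
        a = np.where(near, mid, a)
        b = np.where(near, b, mid)
    return (0.5 * (a + b))[:, None] * rays


def no_compensation_vectors(
    dataset: TrainingSet,
    params: GeometryParams | None = None,
    context: BodyPose | None = None,
) -> np.ndarray:
    """Vectorised :func:`no_compensation_vector` over a training set."""
    params = params if params is not None else dataset.params
    pose = context if context is not None else default_pose(params)
    p_hand = _batch_invert_observations(dataset.hand_obs, pose, params)
    p_target = _batch_invert_observations(dataset.target_obs, pose, params)
    return p_target - p_hand
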