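"""Post-training probe battery.

Probes single hidden-layer units (HLUs) or population output units
(POUs) with systematically varied retinal / extra-retinal inputs while
all other inputs are clamped to a fixed context, and quantifies:

* response fields (receptive fields over retinal position, retinal
  disparity fields) with centre-of-mass / extremum statistics;
* shift indices: regression slope of the field centre of mass against a
  modulating variable (vergence, hand/target depth, eye/head rotation);
* gain-modulation indices ``(a_max - a_min) / (a_max + a_min)`` averaged
  over the unrelated depth parameters, thresholded at 0.2;
* separability angles: doubled mean response-field gradient direction,
  0/180 deg for single-variable coding, -90/+90 deg for subtractive /
  additive joint coding;
* weight-derived sensitivity vectors per input group;
* the compensation index: pooled regression slope of observed vs
  geometrically predicted compensation for extra-retinal context;
* a simulation of the classic reach-in-depth protocol (5 target x 3
  hand x 3 fixation distances).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import geometry3d as g3d
from .encoding import encode_sample, input_layout
from .network import NetworkParams, forward

__all__ = [
    "ProbeContext",
    "ResponseField",
    "ShiftIndex",
    "GainIndex",
    "SeparabilityAngle",
    "FieldStatsError",
    "probe_layer",
    "probe_response_field",
    "field_stats",
    "shift_index",
    "shift_index_table",
    "gain_index",
    "gain_index_table",
    "sensitivity_vector",
    "separability_angle",
    "separability_index",
    "separability_table",
    "compensation_slope",
    "compensation_index",
    "ferraina_protocol",
    "variance_ratio_test",
    "GAIN_THRESHOLD",
]

GAIN_THRESHOLD = 0.2

RF_GRID_DEG = np.arange(-45.0, 45.1, 5.0)
RD_GRID_H_DEG = np.arange(-15.0, 15.1, 1.5)
RD_GRID_V_DEG = np.arange(-7.5, 7.6, 1.5)


class FieldStatsError(ValueError):
    """Raised for degenerate (all-zero / flat) response fields."""


@dataclass(frozen=True)
class ProbeContext:
    """Fully specified clamp of every network input.

    Defaults follow the standard probe context: zero eye and head
    rotation, fixation at 50 cm straight ahead, hand and target foveal
    at 50 cm distance.  Object disparities default to the true midline
    geometry (objects nearer than fixation give positive disparity) but
    can be overridden directly in degrees.
    """

    eye: tuple[float, float, float] = (0.0, 0.0, 0.0)
    head: tuple[float, float, float] = (0.0, 0.0, 0.0)
    fixation_cm: float = 50.0
    hand_position_deg: tuple[float, float] = (0.0, 0.0)
    target_position_deg: tuple[float, float] = (0.0, 0.0)
    hand_distance_cm: float = 50.0
    target_distance_cm: float = 50.0
    hand_disparity_deg: tuple[float, float] | None = None
    target_disparity_deg: tuple[float, float] | None = None
    # overrides the vergence *input* without touching the disparities
    # derived from the object distances (the probe analogue of varying
    # fixation while stimulus disparity stays retinally controlled)
    vergence_deg: float | None = None

    def resolve(self, params: g3d.GeometryParams) -> dict[str, np.ndarray]:
        """Raw input quantities (degrees) implied by the context."""
        def disparity(override, dist):
            if override is not None:
                return np.asarray(override, dtype=float)
            return np.array(
                [g3d.midline_disparity(dist, self.fixation_cm, params.iod_cm), 0.0]
            )

        vergence = (
            self.vergence_deg if self.vergence_deg is not None
            else g3d.vergence_from_distance(self.fixation_cm, params.iod_cm)
        )
        return {
            "hand_obs": np.concatenate(
                [np.asarray(self.hand_position_deg, dtype=float),
                 disparity(self.hand_disparity_deg, self.hand_distance_cm)]
            ),
            "target_obs": np.concatenate(
                [np.asarray(self.target_position_deg, dtype=float),
                 disparity(self.target_disparity_deg, self.target_distance_cm)]
            ),
            "eye": np.asarray(self.eye, dtype=float),
            "head": np.asarray(self.head, dtype=float),
            "vergence": np.array(vergence),
        }


# field variable -> (observation column offset for the probed object)
_FIELDS = {
    "hand_rf": ("hand_obs", 0),
    "target_rf": ("target_obs", 0),
    "hand_rd": ("hand_obs", 2),
    "target_rd": ("target_obs", 2),
}

_LAYERS = {"hlu": 0, "pou": 1}


@dataclass(frozen=True)
class ResponseField:
    """Unit activation over a 1-D or 2-D probe grid in a fixed context."""

    axes: tuple[np.ndarray, ...]
    values: np.ndarray
    field: str
    context: ProbeContext

    def com(self) -> np.ndarray:
        return field_stats(self)[0]


def _context_batch(
    context: ProbeContext,
    overrides: dict[str, np.ndarray],
    params: g3d.GeometryParams,
) -> np.ndarray:
    """Encode a batch of inputs: the context with per-row overrides of
    selected observation columns."""
    base = context.resolve(params)
    n = len(next(iter(overrides.values()))) if overrides else 1
    batch = {
        "hand_obs": np.tile(base["hand_obs"], (n, 1)),
        "target_obs": np.tile(base["target_obs"], (n, 1)),
        "eye": np.tile(base["eye"], (n, 1)),
        "head": np.tile(base["head"], (n, 1)),
        "vergence": np.full(n, float(base["vergence"])),
    }
    for (key, col), vals in overrides.items():
        if key == "vergence":
            batch["vergence"] = np.asarray(vals, dtype=float)
        elif key in ("eye", "head"):
            batch[key][:, col] = vals
        else:
            batch[key][:, col] = vals
    return encode_sample(
        batch["hand_obs"], batch["target_obs"], batch["eye"],
        batch["head"], batch["vergence"], params,
    )


def probe_layer(
    net: NetworkParams,
    field: str,
    context: ProbeContext = ProbeContext(),
    axes: tuple[np.ndarray, np.ndarray] | None = None,
    params: g3d.GeometryParams = g3d.GeometryParams(),
) -> tuple[tuple[np.ndarray, np.ndarray], np.ndarray, np.ndarray]:
    """Activations of every HLU and POU over a 2-D probe grid.

    Returns ``(axes, hlu, pou)`` where the activation arrays have shape
    ``(len(ax0), len(ax1), n_units)``.
    """
    if field not in _FIELDS:
        raise ValueError(f"unknown field {field!r}")
    obs_key, ofs = _FIELDS[field]
    if axes is None:
        axes = (
            (RF_GRID_DEG, RF_GRID_DEG) if field.endswith("rf")
            else (RD_GRID_H_DEG, RD_GRID_V_DEG)
        )
    g0, g1 = np.meshgrid(axes[0], axes[1], indexing="ij")
    overrides = {
        (obs_key, ofs): g0.ravel(),
        (obs_key, ofs + 1): g1.ravel(),
    }
    x = _context_batch(context, overrides, params)
    h, p, _ = forward(x, net)
    shape = (len(axes[0]), len(axes[1]))
    return axes, h.reshape(*shape, -1), p.reshape(*shape, -1)


def probe_response_field(
    net: NetworkParams,
    layer: str,
    unit: int,
    field: str,
    context: ProbeContext = ProbeContext(),
    axes: tuple[np.ndarray, np.ndarray] | None = None,
    params: g3d.GeometryParams = g3d.GeometryParams(),
) -> ResponseField:
    """Response field of one unit over a 2-D probe grid."""
    axes, h, p = probe_layer(net, field, context, axes, params)
    values = (h if layer == "hlu" else p)[..., unit]
    return ResponseField(axes=axes, values=values, field=field, context=context)


def field_stats(
    field: ResponseField,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(centre of mass, argmax location, argmin location) of a field.

    The COM is the activation-weighted mean grid location (raw
    activations, no baseline subtraction); extremum ties break at the
    lowest flat grid index.
    """
    v = np.asarray(field.values, dtype=float)
    total = v.sum()
    if total <= 0:
        raise FieldStatsError("all-zero response field: COM undefined")
    grids = np.meshgrid(*field.axes, indexing="ij")
    com = np.array([(g * v).sum() / total for g in grids])
    imax = np.unravel_index(np.argmax(v), v.shape)
    imin = np.unravel_index(np.argmin(v), v.shape)
    amax = np.array([ax[i] for ax, i in zip(field.axes, imax)])
    amin = np.array([ax[i] for ax, i in zip(field.axes, imin)])
    return com, amax, amin


# ---------------------------------------------------------------------------
# Modulators
# ---------------------------------------------------------------------------


def _apply_modulator(
    context: ProbeContext, name: str, value: float, params: g3d.GeometryParams
) -> ProbeContext:
    if name == "vergence":
        # input-referred: only the vergence signal moves; disparities
        # stay at the values implied by the clamped object distances
        return replace(context, vergence_deg=value)
    if name == "fixation_distance_cm":
        # physically coupled alternative: moving the fixation point also
        # recomputes every object disparity from the true geometry
        return replace(context, fixation_cm=value, vergence_deg=None)
    if name == "hand_depth_cm":
        return replace(context, hand_distance_cm=value)
    if name == "target_depth_cm":
        return replace(context, target_distance_cm=value)
    if name == "movement_depth_cm":
        # movement depth = target distance - hand distance; vary the
        # target around the clamped hand distance
        return replace(
            context, target_distance_cm=context.hand_distance_cm + value
        )
    if name == "hand_disparity_h":
        return replace(context, hand_disparity_deg=(value, 0.0))
    if name == "target_disparity_h":
        return replace(context, target_disparity_deg=(value, 0.0))
    if name == "eye_horizontal":
        return replace(context, eye=(0.0, 0.0, value))
    if name == "eye_vertical":
        return replace(context, eye=(value, 0.0, 0.0))
    if name == "head_horizontal":
        return replace(context, head=(0.0, 0.0, value))
    if name == "head_vertical":
        return replace(context, head=(value, 0.0, 0.0))
    raise ValueError(f"unknown modulator {name!r}")


@dataclass(frozen=True)
class ShiftIndex:
    """Regression of field centre of mass on a modulating variable."""

    layer: str
    unit: int
    field: str
    modulator: str
    slope_h: float
    slope_v: float
    r2_h: float
    r2_v: float
    p_h: float
    p_v: float
    degenerate: bool = False


def _com_regression(
    coms: np.ndarray, levels: np.ndarray
) -> tuple[float, float, float]:
    """Slope, R^2, p of one COM coordinate against modulator levels."""
    if np.ptp(coms) < 1e-12:
        return 0.0, 0.0, 1.0
    res = stats.linregress(levels, coms)
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)


def shift_index(
    net: NetworkParams,
    layer: str,
    unit: int,
    field: str,
    modulator: str,
    levels: np.ndarray,
    context: ProbeContext = ProbeContext(),
    axes: tuple[np.ndarray, np.ndarray] | None = None,
    params: g3d.GeometryParams = g3d.GeometryParams(),
) -> ShiftIndex:
    """Field-shift index of one unit: OLS slope of the response-field
    centre of mass against the modulator, per grid axis."""
    table = shift_index_table(
        net, layer, [unit], field, modulator, levels, context, axes, params
    )
    row = table.iloc[0]
    return ShiftIndex(
        layer=layer, unit=unit, field=field, modulator=modulator,
        slope_h=row.slope_h, slope_v=row.slope_v, r2_h=row.r2_h,
        r2_v=row.r2_v, p_h=row.p_h, p_v=row.p_v,
        degenerate=bool(row.degenerate),
    )


def shift_index_table(
    net: NetworkParams,
    layer: str,
    units: list[int] | None,
    field: str,
    modulator: str,
    levels: np.ndarray,
    context: ProbeContext = ProbeContext(),
    axes: tuple[np.ndarray, np.ndarray] | None = None,
    params: g3d.GeometryParams = g3d.GeometryParams(),
) -> pd.DataFrame:
    """Shift indices for many units of one layer (one probe sweep)."""
    levels = np.asarray(levels, dtype=float)
    if len(levels) < 3:
        raise ValueError("need at least 3 modulator levels")
    acts = []
    for lv in levels:
        ctx = _apply_modulator(context, modulator, float(lv), params)
        ax, h, p = probe_layer(net, field, ctx, axes, params)
        acts.append(h if layer == "hlu" else p)
    acts = np.stack(acts)  # (n_levels, n0, n1, n_units)
    if units is None:
        units = list(range(acts.shape[-1]))
    g0, g1 = np.meshgrid(ax[0], ax[1], indexing="ij")
    rows = []
    for u in units:
        v = acts[..., u]
        totals = v.sum(axis=(1, 2))
        degenerate = bool(np.any(totals <= 0))
        if degenerate:
            rows.append((u, 0.0, 0.0, 0.0, 0.0, 1.0, 1.0, True))
            continue
        com_h = (v * g0).sum(axis=(1, 2)) / totals
        com_v = (v * g1).sum(axis=(1, 2)) / totals
        sh, r2h, ph = _com_regression(com_h, levels)
        sv, r2v, pv = _com_regression(com_v, levels)
        rows.append((u, sh, sv, r2h, r2v, ph, pv, False))
    return pd.DataFrame(
        rows,
        columns=["unit", "slope_h", "slope_v", "r2_h", "r2_v", "p_h",
                 "p_v", "degenerate"],
    ).assign(layer=layer, field=field, modulator=modulator)


# ---------------------------------------------------------------------------
# Gain modulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GainIndex:
    layer: str
    unit: int
    variable: str
    value: float
    modulated: bool


GAIN_VERGENCE_FIX_CM = (30.0, 45.0, 60.0, 80.0)   # 4 vergence angles
GAIN_DEPTHS_CM = (30.0, 40.0, 50.0, 60.0, 70.0)    # 5 hand / target depths

_GAIN_AXES = {"vergence": 0, "hand_depth": 1, "target_depth": 2}


def _gain_cube(
    net: NetworkParams,
    context: ProbeContext,
    params: g3d.GeometryParams,
    fixations=GAIN_VERGENCE_FIX_CM,
    depths=GAIN_DEPTHS_CM,
) -> tuple[np.ndarray, np.ndarray]:
    """Layer activations over the (vergence x hand depth x target depth)
    probe cube; shapes ``(4, 5, 5, n_units)``."""
    combos = [
        (f, h, t) for f in fixations for h in depths for t in depths
    ]
    ctxs = [
        replace(context, fixation_cm=f, hand_distance_cm=h,
                target_distance_cm=t)
        for f, h, t in combos
    ]
    base = [c.resolve(params) for c in ctxs]
    x = encode_sample(
        np.array([b["hand_obs"] for b in base]),
        np.array([b["target_obs"] for b in base]),
        np.array([b["eye"] for b in base]),
        np.array([b["head"] for b in base]),
        np.array([float(b["vergence"]) for b in base]),
        params,
    )
    h, p, _ = forward(x, net)
    shape = (len(fixations), len(depths), len(depths))
    return h.reshape(*shape, -1), p.reshape(*shape, -1)


def gain_index(
    net: NetworkParams,
    layer: str,
    unit: int,
    variable: str,
    context: ProbeContext = ProbeContext(),
    params: g3d.GeometryParams = g3d.GeometryParams(),
) -> GainIndex:
    """Gain-modulation index of one unit for one depth variable.

    ``(a_max - a_min) / (a_max + a_min)`` across the probed variable,
    evaluated for every fixed combination of the two unrelated depth
    parameters and averaged; a unit counts as modulated above 0.2.
    """
    table = gain_index_table(net, layer, [unit], (variable,), context, params)
    row = table.iloc[0]
    return GainIndex(layer=layer, unit=unit, variable=variable,
                     value=float(row.value), modulated=bool(row.modulated))


def gain_index_table(
    net: NetworkParams,
    layer: str,
    units: list[int] | None = None,
    variables: tuple[str, ...] = ("vergence", "hand_depth", "target_depth"),
    context: ProbeContext = ProbeContext(),
    params: g3d.GeometryParams = g3d.GeometryParams(),
) -> pd.DataFrame:
    hc, pc = _gain_cube(net, context, params)
    acts = hc if layer == "hlu" else pc
    if units is None:
        units = list(range(acts.shape[-1]))
    rows = []
    for var in variables:
        ax = _GAIN_AXES[var]
        a = np.moveaxis(acts[..., units], ax, 0)  # (var, other, other, units)
        amax = a.max(axis=0)
        amin = a.min(axis=0)
        denom = amax + amin
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(denom > 0, (amax - amin) / denom, np.nan)
        value = np.nanmean(g, axis=(0, 1))
        for u, val in zip(units, value):
            rows.append((u, var, float(val), bool(val > GAIN_THRESHOLD)))
    return pd.DataFrame(
        rows, columns=["unit", "variable", "value", "modulated"]
    ).assign(layer=layer)


# ---------------------------------------------------------------------------
# Sensitivity vectors
# ---------------------------------------------------------------------------


def sensitivity_vector(
    net: NetworkParams, layer: str, unit: int, input_group: str
) -> np.ndarray:
    """Weight-derived sensitivity of a unit to an input group.

    For an HLU this is the slice of ``w_in`` for the group; for a POU
    the slice is contracted with the unit's ``w_out`` row, i.e. the
    linearised derivative path through the hidden layer.
    """
    layout = input_layout()
    if input_group not in layout:
        raise ValueError(f"unknown input group {input_group!r}")
    sl = layout[input_group]
    if layer == "hlu":
        return net.w_in[unit, sl].copy()
    if layer == "pou":
        return net.w_out[unit] @ net.w_in[:, sl]
    raise ValueError(f"unknown layer {layer!r}")


# ---------------------------------------------------------------------------
# Separability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeparabilityAngle:
    layer: str
    unit: int
    pair: tuple[str, str]
    angle_deg: float
    resultant: float
    degenerate: bool = False


def separability_angle(field: np.ndarray, eps: float = 1e-12) -> float:
    """Doubled mean gradient direction of a 2-D response field, degrees.

    Central-difference gradients at interior points; direction angles
    ``atan2(d/d axis1, d/d axis0)`` are doubled, averaged circularly
    with gradient-magnitude weights, and reported in (-180, 180].  A
    field varying only along axis 0 gives 0, only along axis 1 gives
    180, along the difference axis1 - axis0 gives -90 (subtractive) and
    along the sum +90 (additive).

    Raises :class:`FieldStatsError` for a flat field.
    """
    f = np.asarray(field, dtype=float)
    if f.ndim != 2 or min(f.shape) < 3:
        raise ValueError("need a 2-D field with at least 3 points per axis")
    g0, g1 = np.gradient(f)
    g0 = g0[1:-1, 1:-1].ravel()
    g1 = g1[1:-1, 1:-1].ravel()
    mag = np.hypot(g0, g1)
    if mag.sum() < eps:
        raise FieldStatsError("flat response field: separability undefined")
    theta2 = 2.0 * np.arctan2(g1, g0)
    z = np.sum(mag * np.exp(1j * theta2))
    ang = float(np.degrees(np.angle(z)))
    if ang <= -180.0:
        ang += 360.0
    return ang


_SEP_VARS = {"hand": "hand_distance_cm", "target": "target_distance_cm",
             "vergence": "fixation_cm"}


def separability_index(
    net: NetworkParams,
    layer: str,
    unit: int,
    pair: tuple[str, str] = ("hand", "target"),
    levels: np.ndarray = np.arange(30.0, 71.0, 5.0),
    context: ProbeContext = ProbeContext(),
    params: g3d.GeometryParams = g3d.GeometryParams(),
) -> SeparabilityAngle:
    """Separability angle of one unit for a depth-variable pair.

    The unit's activity is mapped over a 2-D grid of the two distances
    (cm, identical levels per axis, first pair member on axis 0) and the
    doubled-gradient circular mean is computed.
    """
    table = separability_table(net, layer, [unit], pair, levels, context, params)
    row = table.iloc[0]
    return SeparabilityAngle(
        layer=layer, unit=unit, pair=pair, angle_deg=float(row.angle_deg),
        resultant=float(row.resultant), degenerate=bool(row.degenerate),
    )


def separability_table(
    net: NetworkParams,
    layer: str,
    units: list[int] | None,
    pair: tuple[str, str] = ("hand", "target"),
    levels: np.ndarray = np.arange(30.0, 71.0, 5.0),
    context: ProbeContext = ProbeContext(),
    params: g3d.GeometryParams = g3d.GeometryParams(),
) -> pd.DataFrame:
    for v in pair:
        if v not in _SEP_VARS:
            raise ValueError(f"unknown depth variable {v!r}")
    levels = np.asarray(levels, dtype=float)
    n = len(levels)
    combos = [(a, b) for a in levels for b in levels]
    ctxs = [
        replace(context, **{_SEP_VARS[pair[0]]: a, _SEP_VARS[pair[1]]: b})
        for a, b in combos
    ]
    base = [c.resolve(params) for c in ctxs]
    x = encode_sample(
        np.array([b["hand_obs"] for b in base]),
        np.array([b["target_obs"] for b in base]),
        np.array([b["eye"] for b in base]),
        np.array([b["head"] for b in base]),
        np.array([float(b["vergence"]) for b in base]),
        params,
    )
    h, p, _ = forward(x, net)
    acts = (h if layer == "hlu" else p).reshape(n, n, -1)
    if units is None:
        units = list(range(acts.shape[-1]))
    rows = []
    for u in units:
        try:
            ang = separability_angle(acts[..., u])
            g0, g1 = np.gradient(acts[..., u])
            res = float(np.hypot(g0, g1)[1:-1, 1:-1].sum())
            rows.append((u, ang, res, False))
        except FieldStatsError:
            rows.append((u, np.nan, 0.0, True))
    return pd.DataFrame(
        rows, columns=["unit", "angle_deg", "resultant", "degenerate"]
    ).assign(layer=layer, pair="-".join(pair))


# ---------------------------------------------------------------------------
# Compensation index
# ---------------------------------------------------------------------------


def compensation_slope(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pooled OLS slope of observed on predicted compensation."""
    x = np.asarray(predicted, dtype=float).ravel()
    y = np.asarray(observed, dtype=float).ravel()
    if np.ptp(x) < 1e-12:
        raise ValueError(
            "predicted compensation is constant: slope undefined "
            "(all samples at the default context?)"
        )
    return float(stats.linregress(x, y).slope)


def compensation_index(
    net: NetworkParams,
    testset: g3d.TrainingSet,
    x: np.ndarray | None = None,
    no_comp: np.ndarray | None = None,
    component: slice = slice(None),
) -> float:
    """Compensation index of a network on a test set.

    Observed compensation is the decoded movement vector minus the
    no-compensation vector; predicted compensation is the ideal vector
    minus the no-compensation vector; the index is their pooled OLS
    slope (1 = full use of extra-retinal signals).
    """
    from .encoding import encode_dataset

    if x is None:
        x = encode_dataset(testset)
    _, _, m_hat = forward(x, net)
    if no_comp is None:
        no_comp = g3d.no_compensation_vectors(testset)
    observed = (m_hat - no_comp)[:, component]
    predicted = (testset.motor_cm - no_comp)[:, component]
    return compensation_slope(observed, predicted)


# ---------------------------------------------------------------------------
# Reach-in-depth protocol simulation
# ---------------------------------------------------------------------------


FERRAINA_TARGETS_CM = (30.0, 40.0, 50.0, 60.0, 70.0)
FERRAINA_HANDS_CM = (35.0, 50.0, 65.0)
FERRAINA_FIXATIONS_CM = (30.0, 50.0, 80.0)


def ferraina_protocol(
    net: NetworkParams,
    targets_cm=FERRAINA_TARGETS_CM,
    hands_cm=FERRAINA_HANDS_CM,
    fixations_cm=FERRAINA_FIXATIONS_CM,
    context: ProbeContext = ProbeContext(),
    params: g3d.GeometryParams = g3d.GeometryParams(),
) -> pd.DataFrame:
    """Simulated reach-in-depth protocol: 5 target x 3 hand x 3 fixation
    midline distances.

    Returns a tidy table with one row per (unit, condition): columns
    ``layer, unit, target_cm, hand_cm, fixation_cm, activation`` --
    tuning curves across target distance grouped by vergence or by
    initial hand distance.
    """
    combos = [
        (t, h, f) for t in targets_cm for h in hands_cm for f in fixations_cm
    ]
    ctxs = [
        replace(context, target_distance_cm=t, hand_distance_cm=h,
                fixation_cm=f)
        for t, h, f in combos
    ]
    base = [c.resolve(params) for c in ctxs]
    x = encode_sample(
        np.array([b["hand_obs"] for b in base]),
        np.array([b["target_obs"] for b in base]),
        np.array([b["eye"] for b in base]),
        np.array([b["head"] for b in base]),
        np.array([float(b["vergence"]) for b in base]),
        params,
    )
    h, p, _ = forward(x, net)
    frames = []
    for layer, acts in (("hlu", h), ("pou", p)):
        n_units = acts.shape[1]
        cond = np.array(combos)
        frames.append(pd.DataFrame({
            "layer": layer,
            "unit": np.repeat(np.arange(n_units), len(combos)),
            "target_cm": np.tile(cond[:, 0], n_units),
            "hand_cm": np.tile(cond[:, 1], n_units),
            "fixation_cm": np.tile(cond[:, 2], n_units),
            "activation": acts.T.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def variance_ratio_test(wide: np.ndarray, narrow: np.ndarray) -> tuple[float, float]:
    """One-sided F-test that ``wide`` has larger variance than
    ``narrow``.  Returns (F statistic, p value)."""
    wide = np.asarray(wide, dtype=float)
    narrow = np.asarray(narrow, dtype=float)
    f = float(np.var(wide, ddof=1) / np.var(narrow, ddof=1))
    p = float(stats.f.sf(f, len(wide) - 1, len(narrow) - 1))
    return f, p
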