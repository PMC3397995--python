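"""The 4-layer feed-forward transformation network.

Architecture: 653 linear inputs -> fully connected sigmoid hidden layer
(HLUs) -> fully connected sigmoid population output layer (POUs) ->
fixed linear read-out of the 3-component movement vector.  The read-out
weights are an optimal linear estimator (OLE) computed once from the
assumption of cosine tuning in the POU layer and never updated during
training; only ``w_in``, ``w_out`` and the two bias vectors are learned
by batch minimisation of the mean squared read-out error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import geometry3d as g3d
from .encoding import N_INPUTS, encode_dataset

__all__ = [
    "POUSet",
    "OLEWeights",
    "NetworkParams",
    "TrainConfig",
    "sample_pou_directions",
    "cosine_response",
    "compute_ole_weights",
    "init_params",
    "forward",
    "train",
    "evaluate",
]

A_MAX_CM = 200.0
BASELINE = 0.5


@dataclass(frozen=True)
class POUSet:
    """Preferred movement directions of the population output units."""

    directions: np.ndarray  # (n, 3) unit vectors
    a0: float = BASELINE
    a_max_cm: float = A_MAX_CM

    def __len__(self) -> int:
        return len(self.directions)


@dataclass(frozen=True)
class OLEWeights:
    """Fixed optimal-linear-estimator read-out.

    ``w`` solves ``Q w = L`` where ``Q`` is the tuning-curve
    cross-correlation matrix (plus the expected-noise diagonal) and
    ``L`` the tuning-curve centre-of-mass matrix.
    """

    w: np.ndarray  # (n_pou, 3)
    L: np.ndarray  # (n_pou, 3)
    Q: np.ndarray  # (n_pou, n_pou)
    sigma_k: float

    def decode(self, pou_activity: np.ndarray) -> np.ndarray:
        return np.asarray(pou_activity) @ self.w


def sample_pou_directions(n: int, seed: int | np.random.Generator) -> POUSet:
    """``n`` preferred directions uniform on the unit sphere.

    Uses the Marsaglia (1972) rejection construction: a point in the
    unit disk maps to the sphere.
    """
    if n < 4:
        raise ValueError("need at least 4 output units")
    rng = np.random.default_rng(seed)
    dirs = np.empty((n, 3))
    filled = 0
    while filled < n:
        u = rng.uniform(-1, 1, size=(2 * (n - filled), 2))
        s = np.sum(u**2, axis=1)
        u = u[s < 1.0]
        s = s[s < 1.0]
        root = np.sqrt(1.0 - s)
        cand = np.column_stack(
            [2 * u[:, 0] * root, 2 * u[:, 1] * root, 1.0 - 2.0 * s]
        )
        take = min(len(cand), n - filled)
        dirs[filled:filled + take] = cand[:take]
        filled += take
    return POUSet(directions=dirs)


def cosine_response(motor_cm: np.ndarray, pou: POUSet) -> np.ndarray:
    """Ideal cosine-tuned activations for movement vector(s) in cm.

    ``a_i = a0 + |M| / (2 A_max) * cos(angle(M, p_i))`` which lies in
    [0, 1] for movements up to ``A_max`` (2 m).
    """
    m = np.atleast_2d(np.asarray(motor_cm, dtype=float))
    amp = np.linalg.norm(m, axis=1)
    if np.any(amp > pou.a_max_cm + 1e-9):
        raise ValueError("movement amplitude exceeds A_max")
    a = pou.a0 + (m @ pou.directions.T) / (2.0 * pou.a_max_cm)
    return a[0] if np.asarray(motor_cm).ndim == 1 else a


def compute_ole_weights(
    pou: POUSet,
    sigma_k: float = 0.01,
    n_mc: int = 1_000_000,
    amp_max_cm: float = 175.0,
    seed: int | np.random.Generator = 0,
    chunk: int = 100_000,
) -> OLEWeights:
    """Optimal linear read-out weights for the cosine-tuned population.

    The centre-of-mass matrix ``L = E[a M^T]`` and cross-correlation
    matrix ``Q = E[a a^T] + sigma_k^2 I`` are evaluated by Monte-Carlo
    integration over movements with uniform direction and amplitude
    uniform in [0, ``amp_max_cm``] (the training movement distribution;
    the closed forms are equivalent for this symmetric case).
    """
    rng = np.random.default_rng(seed)
    n = len(pou)
    Q = np.zeros((n, n))
    L = np.zeros((n, 3))
    done = 0
    while done < n_mc:
        k = min(chunk, n_mc - done)
        v = rng.normal(size=(k, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        m = v * rng.uniform(0.0, amp_max_cm, size=(k, 1))
        a = cosine_response(m, pou)
        Q += a.T @ a
        L += a.T @ m
        done += k
    Q /= n_mc
    L /= n_mc
    Q_noise = Q + sigma_k**2 * np.eye(n)
    w = np.linalg.solve(Q_noise, L)
    return OLEWeights(w=w, L=L, Q=Q_noise, sigma_k=sigma_k)


@dataclass
class NetworkParams:
    """Trainable weights plus the frozen read-out."""

    w_in: np.ndarray    # (n_hlu, n_inputs)
    b_hlu: np.ndarray   # (n_hlu,)
    w_out: np.ndarray   # (n_pou, n_hlu)
    b_pou: np.ndarray   # (n_pou,)
    ole: OLEWeights
    pou: POUSet

    @property
    def n_hlu(self) -> int:
        return self.w_in.shape[0]

    @property
    def n_pou(self) -> int:
        return self.w_out.shape[0]

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [self.w_in.ravel(), self.b_hlu, self.w_out.ravel(), self.b_pou]
        )

    def unpack(self, theta: np.ndarray) -> None:
        nh, ni = self.w_in.shape
        npou = self.w_out.shape[0]
        ofs = 0
        self.w_in = theta[ofs:ofs + nh * ni].reshape(nh, ni); ofs += nh * ni
        self.b_hlu = theta[ofs:ofs + nh]; ofs += nh
        self.w_out = theta[ofs:ofs + npou * nh].reshape(npou, nh); ofs += npou * nh
        self.b_pou = theta[ofs:ofs + npou]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def init_params(
    n_hlu: int,
    pou: POUSet,
    ole: OLEWeights,
    seed: int | np.random.Generator = 0,
    n_inputs: int = N_INPUTS,
    scale: float = 0.1,
) -> NetworkParams:
    """Small-uniform random initialisation of the trainable weights."""
    rng = np.random.default_rng(seed)
    n_pou = len(pou)
    return NetworkParams(
        w_in=rng.uniform(-scale, scale, size=(n_hlu, n_inputs)),
        b_hlu=rng.uniform(-scale, scale, size=n_hlu),
        w_out=rng.uniform(-scale, scale, size=(n_pou, n_hlu)),
        b_pou=rng.uniform(-scale, scale, size=n_pou),
        ole=ole,
        pou=pou,
    )


def forward(
    x: np.ndarray, params: NetworkParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full forward pass.

    Returns ``(hlu, pou, decoded)`` with activations in (0, 1) and the
    decoded movement vector in cm.  ``x`` may be a single input vector
    or an ``(n, n_inputs)`` batch.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xb = np.atleast_2d(x)
    if xb.shape[1] != params.w_in.shape[1]:
        raise ValueError(
            f"input dimension {xb.shape[1]} != {params.w_in.shape[1]}"
        )
    h = _sigmoid(xb @ params.w_in.T + params.b_hlu)
    p = _sigmoid(h @ params.w_out.T + params.b_pou)
    m = params.ole.decode(p)
    if single:
        return h[0], p[0], m[0]
    return h, p, m


def _loss_grad(
    theta: np.ndarray,
    x: np.ndarray,
    m_target: np.ndarray,
    params: NetworkParams,
    dtype=np.float64,
) -> tuple[float, np.ndarray]:
    """Mean squared read-out error and its gradient (backprop)."""
    params.unpack(theta.astype(dtype, copy=False))
    n = len(x)
    h = _sigmoid(x @ params.w_in.T + params.b_hlu)
    p = _sigmoid(h @ params.w_out.T + params.b_pou)
    m_hat = p @ params.ole.w.astype(dtype, copy=False)
    err = m_hat - m_target
    loss = float(np.sum(err**2)) / n
    d_p = (2.0 / n) * (err @ params.ole.w.T)
    d_zp = d_p * p * (1.0 - p)
    d_wout = d_zp.T @ h
    d_bpou = d_zp.sum(axis=0)
    d_h = d_zp @ params.w_out
    d_zh = d_h * h * (1.0 - h)
    d_win = d_zh.T @ x
    d_bhlu = d_zh.sum(axis=0)
    grad = np.concatenate(
        [d_win.ravel(), d_bhlu, d_wout.ravel(), d_bpou]
    ).astype(np.float64, copy=False)
    return loss, grad


@dataclass
class TrainConfig:
    """Batch-training settings.

    ``dtype`` controls the arithmetic of the loss/gradient evaluation;
    single precision roughly halves the wall time of the dense matrix
    products and is accurate to far below the stopping resolution.
    """

    n_hlu: int = 200
    max_iter: int = 1000
    init_scale: float | None = None  # None -> 1/sqrt(fan-in)
    tol: float = 0.0  # run to max_iter unless the line search stalls
    dtype: str = "float32"
    standardize: bool = True


@dataclass
class TrainResult:
    params: NetworkParams
    history: list[float] = field(default_factory=list)
    converged: bool = False
    message: str = ""


def train(
    dataset: g3d.TrainingSet,
    config: TrainConfig,
    seed: int,
    ole: OLEWeights | None = None,
    pou: POUSet | None = None,
    x: np.ndarray | None = None,
) -> TrainResult:
    """Train the network on a generated dataset.

    The OLE read-out is computed (or passed in) first and frozen; only
    ``w_in``, ``w_out`` and the biases are optimised, by L-BFGS on the
    full batch with analytic gradients.  ``seed`` controls the POU
    directions, OLE Monte-Carlo stream and weight initialisation.
    """
    rng = np.random.default_rng(seed)
    if pou is None:
        pou = sample_pou_directions(125, rng)
    if ole is None:
        ole = compute_ole_weights(pou, seed=rng)
    if x is None:
        x = encode_dataset(dataset)
    dtype = np.dtype(config.dtype)
    if config.standardize:
        # standardise inputs for optimizer conditioning only; the affine
        # map is folded back into the weights afterwards (exact)
        mu = x.mean(axis=0)
        sd = np.maximum(x.std(axis=0), 1e-3)
        xt = np.ascontiguousarray((x - mu) / sd, dtype=dtype)
    else:
        mu = sd = None
        xt = np.ascontiguousarray(x, dtype=dtype)
    m = np.ascontiguousarray(dataset.motor_cm, dtype=dtype)
    scale = (
        config.init_scale if config.init_scale is not None
        else 1.0 / np.sqrt(x.shape[1])
    )
    params = init_params(
        config.n_hlu, pou, ole, seed=rng, n_inputs=x.shape[1], scale=scale,
    )
    history: list[float] = []

    def fun(theta: np.ndarray) -> tuple[float, np.ndarray]:
        loss, grad = _loss_grad(theta, xt, m, params, dtype)
        history.append(loss)
        return loss, grad

    res = minimize(
        fun,
        params.pack(),
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": config.max_iter,
            "maxfun": 10 * config.max_iter,
            "ftol": config.tol,
            "gtol": 0.0,
            "maxcor": 20,
        },
    )
    params.unpack(res.x)
    if config.standardize:
        params.w_in = params.w_in / sd
        params.b_hlu = params.b_hlu - params.w_in @ mu
    history.append(float(res.fun))
    return TrainResult(
        params=params, history=history, converged=bool(res.success),
        message=str(res.message),
    )


def evaluate(
    params: NetworkParams,
    testset: g3d.TrainingSet,
    x: np.ndarray | None = None,
    no_comp: np.ndarray | None = None,
) -> dict:
    """Held-out performance metrics.

    Returns mean/SD absolute 3-D movement error (cm), the depth
    (anterior-posterior) component error (cm), and 3-D and depth
    compensation indices: pooled regression slopes of observed
    compensation (decoded minus no-compensation vector) on predicted
    compensation (ideal minus no-compensation vector).
    """
    from .analysis import compensation_slope

    if x is None:
        x = encode_dataset(testset)
    _, _, m_hat = forward(x, params)
    err = m_hat - testset.motor_cm
    abs_err = np.linalg.norm(err, axis=1)
    depth_err = np.abs(err[:, 1])
    if no_comp is None:
        no_comp = g3d.no_compensation_vectors(testset)
    observed = m_hat - no_comp
    predicted = testset.motor_cm - no_comp
    slope_3d = compensation_slope(observed, predicted)
    slope_depth = compensation_slope(observed[:, 1:2], predicted[:, 1:2])
    return {
        "mean_abs_error_cm": float(abs_err.mean()),
        "sd_abs_error_cm": float(abs_err.std()),
        "mean_depth_error_cm": float(depth_err.mean()),
        "sd_depth_error_cm": float(depth_err.std()),
        "compensation_index_3d": slope_3d,
        "compensation_index_depth": slope_depth,
        "n": int(len(testset)),
    }
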