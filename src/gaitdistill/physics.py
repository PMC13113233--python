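"""Physics-guided compensation: rigid-body consistency of torque estimates.

For a single body segment rotating with angular velocity w(t), the
Newton-Euler equation links kinematics to the mass-normalized joint torque:

    tau(t) = I_eff w_dot(t) + w(t) x (I_eff w(t)) + G(theta(t))        [N*m/kg]

``I_eff`` is an *equivalent* inertia tensor expressed in sensor coordinates:
it absorbs the unknown sensor-to-segment rotation and the segment inertia and
is learned, not measured.  To keep it in the physically admissible set for
every parameter value, it is represented through its Cholesky factor
I_eff = L L^T with a softplus-positive diagonal, so unconstrained optimization
can never produce an indefinite tensor.  The gravity term G(theta) is modelled
pendulum-like, linear in its learnable coefficients:
G(theta) = a_sin * sin(theta) + a_cos * cos(theta), per axis.

Angular acceleration is never taken from raw differences: a Savitzky-Golay
smoothing differentiator filters w and produces w_dot, and the residual loss
excludes half a filter window at each cycle edge where the polynomial fit is
extrapolating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.signal import savgol_filter

from .autodiff import Tensor, stack

__all__ = [
    "SGConfig",
    "KinematicCycle",
    "InertiaCholesky",
    "GravityModel",
    "sg_smooth_derivative",
    "spd_from_cholesky",
    "raw_for_factor",
    "gravity_torque",
    "newton_euler_torque",
    "physics_loss",
    "fit_inertia",
]

_EPS_DIAG = 1e-6
SAGITTAL_AXIS = 2  # default supervised/evaluated torque component


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SGConfig:
    """Savitzky-Golay smoothing/differentiation settings.

    Defaults: window 11 (110 ms at 100 Hz), polyorder 5.  The 11-sample window
    suits 101-sample gait cycles; polyorder 5 keeps the filter transparent to
    gait's 3-4 Hz harmonics, which a cubic fit over the same window visibly
    attenuates (biasing the differentiated angular acceleration).
    """

    window: int = 11
    polyorder: int = 5
    deriv_order: int = 0

    def __post_init__(self):
        if self.window < 5 or self.window % 2 == 0:
            raise ValueError(f"SG window must be an odd integer >= 5, got {self.window}")
        if not (2 <= self.polyorder < self.window):
            raise ValueError(
                f"polyorder must satisfy 2 <= polyorder < window, got {self.polyorder}"
            )
        if self.deriv_order not in (0, 1):
            raise ValueError("deriv_order must be 0 or 1")


@dataclass
class KinematicCycle:
    """Per-cycle joint kinematics: angle theta (T,), angular velocity omega
    (T, 3) and angular acceleration omega_dot (T, 3), with sample interval dt.

    ``omega_filt`` / ``omega_dot_filt`` hold Savitzky-Golay-filtered versions
    when populated by :func:`physics_loss` or the caller.
    """

    theta: np.ndarray
    omega: np.ndarray
    omega_dot: np.ndarray | None
    dt: float
    omega_filt: np.ndarray | None = None
    omega_dot_filt: np.ndarray | None = None

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=np.float64)
        self.omega = np.asarray(self.omega, dtype=np.float64)
        if self.omega.ndim != 2 or self.omega.shape[1] != 3:
            raise ValueError(f"omega must be (T, 3), got {self.omega.shape}")
        if self.theta.shape[0] != self.omega.shape[0]:
            raise ValueError("theta and omega lengths differ")
        if self.omega_dot is not None:
            self.omega_dot = np.asarray(self.omega_dot, dtype=np.float64)
            if self.omega_dot.shape != self.omega.shape:
                raise ValueError("omega and omega_dot shapes differ")
        for name in ("theta", "omega", "omega_dot"):
            v = getattr(self, name)
            if v is not None and not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in {name}")

    @property
    def n_samples(self) -> int:
        return self.theta.shape[0]


class InertiaCholesky:
    """SPD equivalent inertia via its Cholesky factor.

    ``raw`` holds 6 unconstrained parameters ordered
    (d0, d1, d2, l10, l20, l21): the first three map through
    softplus(.) + eps to the strictly positive diagonal of L, the rest are the
    free sub-diagonal entries.  ``I_eff = L L^T`` is therefore symmetric with
    eigenvalues bounded away from zero for *every* raw value, and the map
    raw -> I_eff is smooth, so the tensor can sit directly in a gradient
    optimizer.  Units are mass-normalized (kg*m^2/kg), matching N*m/kg torques.
    """

    def __init__(self, raw: np.ndarray | Tensor | None = None, trainable: bool = True):
        if raw is None:
            raw = np.full(6, raw_for_diag_value(0.1))
            raw[3:] = 0.0
        if isinstance(raw, Tensor):
            self.raw = raw
        else:
            raw = np.asarray(raw, dtype=np.float64)
            if raw.shape != (6,):
                raise ValueError(f"raw must have shape (6,), got {raw.shape}")
            if not np.all(np.isfinite(raw)):
                raise ValueError("non-finite raw Cholesky parameters")
            self.raw = Tensor(raw, requires_grad=trainable)

    @property
    def factor(self) -> np.ndarray:
        return _cholesky_factor(Tensor(self.raw.data)).data

    @property
    def i_eff(self) -> np.ndarray:
        return spd_from_cholesky(self.raw.data)

    def i_eff_tensor(self) -> Tensor:
        """Differentiable I_eff for use inside a training graph."""
        L = _cholesky_factor(self.raw)
        return L @ L.T

    def report(self) -> dict:
        i = self.i_eff
        return {
            "i_eff": i.tolist(),
            "eigenvalues": np.linalg.eigvalsh(i).tolist(),
            "raw": self.raw.data.tolist(),
        }


def raw_for_diag_value(d: float) -> float:
    """Inverse of softplus(x) + eps = d, for initializing diagonal entries."""
    t = d - _EPS_DIAG
    if t <= 0:
        raise ValueError("target diagonal must exceed eps")
    return float(np.log(np.expm1(t)))


def raw_for_factor(L: np.ndarray) -> np.ndarray:
    """Raw parameters reproducing a given lower-triangular factor."""
    L = np.asarray(L, dtype=np.float64)
    return np.array(
        [
            raw_for_diag_value(L[0, 0]),
            raw_for_diag_value(L[1, 1]),
            raw_for_diag_value(L[2, 2]),
            L[1, 0],
            L[2, 0],
            L[2, 1],
        ]
    )


_BASIS_DIAG = np.stack([np.diag(e) for e in np.eye(3)])  # (3, 3, 3)
_BASIS_OFF = np.zeros((3, 3, 3))
_BASIS_OFF[0, 1, 0] = 1.0
_BASIS_OFF[1, 2, 0] = 1.0
_BASIS_OFF[2, 2, 1] = 1.0


def _cholesky_factor(raw: Tensor) -> Tensor:
    d = raw[0:3].softplus() + _EPS_DIAG
    o = raw[3:6]
    L = (d.reshape(3, 1, 1) * _BASIS_DIAG).sum(axis=0) + (
        o.reshape(3, 1, 1) * _BASIS_OFF
    ).sum(axis=0)
    return L


def spd_from_cholesky(raw: np.ndarray) -> np.ndarray:
    """Map 6 unconstrained parameters to a symmetric positive-definite 3x3."""
    raw = np.asarray(raw, dtype=np.float64)
    if raw.shape != (6,):
        raise ValueError(f"raw must have shape (6,), got {raw.shape}")
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite raw Cholesky parameters")
    L = _cholesky_factor(Tensor(raw)).data
    return L @ L.T


@dataclass
class GravityModel:
    """Pendulum-like gravity torque G(theta) = a_sin sin(theta) + a_cos cos(theta)."""

    a_sin: np.ndarray | Tensor = field(default_factory=lambda: np.zeros(3))
    a_cos: np.ndarray | Tensor = field(default_factory=lambda: np.zeros(3))
    enabled: bool = True

    def __post_init__(self):
        if not isinstance(self.a_sin, Tensor):
            self.a_sin = Tensor(np.asarray(self.a_sin, dtype=np.float64))
        if not isinstance(self.a_cos, Tensor):
            self.a_cos = Tensor(np.asarray(self.a_cos, dtype=np.float64))

    @classmethod
    def trainable(cls, rng: np.random.Generator | None = None) -> "GravityModel":
        init_s = np.zeros(3) if rng is None else 0.01 * rng.standard_normal(3)
        init_c = np.zeros(3) if rng is None else 0.01 * rng.standard_normal(3)
        return cls(
            Tensor(init_s, requires_grad=True), Tensor(init_c, requires_grad=True)
        )

    @classmethod
    def disabled(cls) -> "GravityModel":
        return cls(enabled=False)

    def parameters(self) -> list[Tensor]:
        return [p for p in (self.a_sin, self.a_cos) if p.requires_grad]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def sg_smooth_derivative(x: np.ndarray, cfg: SGConfig, dt: float) -> np.ndarray:
    """Savitzky-Golay smoothing (deriv_order 0) or smoothed d/dt (deriv_order 1).

    Exact on polynomials of degree <= polyorder at interior points (edges use
    the boundary polynomial fit).
    """
    x = np.asarray(x, dtype=np.float64)
    T = x.shape[0]
    if T < cfg.window:
        raise ValueError(
            f"trajectory length {T} shorter than SG window {cfg.window}; "
            f"need at least {cfg.window} samples"
        )
    return savgol_filter(
        x,
        window_length=cfg.window,
        polyorder=cfg.polyorder,
        deriv=cfg.deriv_order,
        delta=dt,
        axis=0,
        mode="interp",
    )


def _cross3(a, b):
    """Cross product along the last axis for (T, 3) operands (Tensor-aware)."""

    def col(m, i):
        return m[:, i] if isinstance(m, Tensor) else m[:, i]

    ax, ay, az = col(a, 0), col(a, 1), col(a, 2)
    bx, by, bz = col(b, 0), col(b, 1), col(b, 2)
    cx = ay * bz - az * by
    cy = az * bx - ax * bz
    cz = ax * by - ay * bx
    if isinstance(cx, Tensor):
        return stack([cx, cy, cz], axis=1)
    return np.stack([cx, cy, cz], axis=1)


def gravity_torque(theta: np.ndarray, g: GravityModel):
    """Evaluate G(theta) for a (T,) angle trajectory; (T, 3) output.

    Returns a ``Tensor`` when the gravity coefficients are trainable, else an
    ndarray.
    """
    theta = np.asarray(theta, dtype=np.float64)
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite angle trajectory")
    s = np.sin(theta)[:, None]
    c = np.cos(theta)[:, None]
    if not g.enabled:
        return np.zeros((theta.shape[0], 3))
    out = g.a_sin * s + g.a_cos * c  # broadcast (T,1)*(3,) -> (T,3)
    return out if out.requires_grad else out.data


def newton_euler_torque(
    inertia: InertiaCholesky,
    kin: KinematicCycle,
    g: GravityModel,
    use_filtered: bool = True,
):
    """Forward Newton-Euler torque I w_dot + w x (I w) + G(theta), shape (T, 3).

    Uses the filtered kinematics when present (and ``use_filtered``), else the
    raw/analytic ones.  Differentiable in the inertia and gravity parameters.
    """
    omega = kin.omega_filt if (use_filtered and kin.omega_filt is not None) else kin.omega
    omega_dot = (
        kin.omega_dot_filt
        if (use_filtered and kin.omega_dot_filt is not None)
        else kin.omega_dot
    )
    if omega_dot is None:
        raise ValueError("kinematic cycle has no angular acceleration")
    if omega.shape != omega_dot.shape:
        raise ValueError(
            f"omega shape {omega.shape} != omega_dot shape {omega_dot.shape}"
        )
    ieff = inertia.i_eff_tensor() if inertia.raw.requires_grad else Tensor(inertia.i_eff)
    tau = Tensor(omega_dot) @ ieff + _cross3(Tensor(omega), Tensor(omega) @ ieff)
    grav = gravity_torque(kin.theta, g)
    tau = tau + grav
    if inertia.raw.requires_grad or (isinstance(grav, Tensor) and grav.requires_grad):
        return tau
    return tau.data if isinstance(tau, Tensor) else tau


def filter_kinematics(kin: KinematicCycle, sg: SGConfig | None = None) -> KinematicCycle:
    """Populate omega_filt / omega_dot_filt from the raw angular velocity."""
    sg = sg or SGConfig()
    smooth = SGConfig(sg.window, sg.polyorder, 0)
    deriv = SGConfig(sg.window, sg.polyorder, 1)
    kin.omega_filt = sg_smooth_derivative(kin.omega, smooth, kin.dt)
    kin.omega_dot_filt = sg_smooth_derivative(kin.omega, deriv, kin.dt)
    return kin


def interior_slice(n: int, sg: SGConfig) -> slice:
    """Samples at least half an SG window away from either cycle edge."""
    half = sg.window // 2
    if n <= 2 * half:
        raise ValueError(f"cycle of {n} samples has no interior for window {sg.window}")
    return slice(half, n - half)


def physics_loss(
    tau_s,
    kin_raw: KinematicCycle,
    inertia: InertiaCholesky,
    g: GravityModel,
    sg: SGConfig | None = None,
):
    """Newton-Euler residual of a predicted torque trajectory.

    The raw angular velocity is SG-smoothed to w_filt and SG-differentiated to
    w_dot_filt; the loss is the mean over interior samples of the squared
    residual ||tau_s - (I w_dot_filt + w_filt x (I w_filt) + G(theta))||^2.
    ``tau_s`` may be (T, 3), or (T,)/(T, 1) in which case only the sagittal
    axis of the model torque is compared.  Returns a ``Tensor`` when any
    argument is on the autodiff graph.
    """
    sg = sg or SGConfig()
    filter_kinematics(kin_raw, sg)
    model_tau = newton_euler_torque(inertia, kin_raw, g, use_filtered=True)
    idx = interior_slice(kin_raw.n_samples, sg)

    ts = tau_s if isinstance(tau_s, Tensor) else Tensor(np.asarray(tau_s, dtype=np.float64))
    if ts.ndim == 1:
        ts = ts.reshape(-1, 1)
    mt = model_tau if isinstance(model_tau, Tensor) else Tensor(model_tau)
    if ts.shape[1] == 1:
        mt = mt[:, SAGITTAL_AXIS].reshape(-1, 1)
    elif ts.shape[1] != 3:
        raise ValueError(f"tau_s must have 1 or 3 axes, got {ts.shape[1]}")
    if ts.shape[0] != kin_raw.n_samples:
        raise ValueError("torque and kinematics lengths differ")

    resid = ts[idx, :] - mt[idx, :]
    loss = (resid * resid).sum(axis=1).mean()
    if loss.requires_grad:
        return loss
    return float(loss.data)


def fit_inertia(
    cycles: Sequence[tuple[KinematicCycle, np.ndarray]],
    g: GravityModel | None = None,
    sg: SGConfig | None = None,
    init_raw: np.ndarray | None = None,
    max_iter: int = 500,
    seed: int = 0,
) -> tuple[InertiaCholesky, float]:
    """Identify the equivalent inertia from (kinematics, torque) cycles.

    Minimizes the mean physics residual over all cycles with respect to the
    raw Cholesky parameters (and the gravity coefficients when the supplied
    gravity model is trainable), using L-BFGS with exact autodiff gradients.
    Deterministic given ``seed`` (which only perturbs the default init).
    """
    if len(cycles) == 0:
        raise ValueError("need at least one cycle to fit the inertia")
    sg = sg or SGConfig()
    g = g or GravityModel.disabled()

    # Precompute filtered kinematics and flatten interiors of all cycles.
    omegas, omega_dots, thetas, taus = [], [], [], []
    for kin, tau in cycles:
        filter_kinematics(kin, sg)
        idx = interior_slice(kin.n_samples, sg)
        omegas.append(kin.omega_filt[idx])
        omega_dots.append(kin.omega_dot_filt[idx])
        thetas.append(kin.theta[idx])
        tau = np.asarray(tau, dtype=np.float64)
        if tau.ndim == 1:
            tau = tau[:, None]
        taus.append(tau[idx])
    omega = np.concatenate(omegas)
    omega_dot = np.concatenate(omega_dots)
    theta = np.concatenate(thetas)
    tau_target = np.concatenate(taus)
    full_vector = tau_target.shape[1] == 3

    rng = np.random.default_rng(seed)
    if init_raw is None:
        init_raw = raw_for_factor(0.3 * np.eye(3)) + 0.01 * rng.standard_normal(6)
    grav_params = g.parameters()
    x0 = np.concatenate([init_raw] + [p.data for p in grav_params])

    sin_t = np.sin(theta)[:, None]
    cos_t = np.cos(theta)[:, None]

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        raw = Tensor(x[:6], requires_grad=True)
        params = [raw]
        off = 6
        for p in grav_params:
            p_new = Tensor(x[off : off + p.size], requires_grad=True)
            params.append(p_new)
            off += p.size
        L = _cholesky_factor(raw)
        ieff = L @ L.T
        model = Tensor(omega_dot) @ ieff + _cross3(
            Tensor(omega), Tensor(omega) @ ieff
        )
        if g.enabled and grav_params:
            model = model + params[1] * sin_t + params[2] * cos_t
        elif g.enabled:
            model = model + gravity_torque(theta, g)
        mt = model if full_vector else model[:, SAGITTAL_AXIS].reshape(-1, 1)
        resid = Tensor(tau_target) - mt
        loss = (resid * resid).sum(axis=1).mean()
        loss.backward()
        grad = np.concatenate([p.grad for p in params])
        if not np.isfinite(loss.data):
            raise FloatingPointError("physics objective diverged (non-finite loss)")
        return float(loss.data), grad

    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-12},
    )
    x = res.x
    for p, lo in zip(grav_params, range(6, len(x), 3)):
        p.data = x[lo : lo + 3].copy()
    fitted = InertiaCholesky(x[:6].copy())
    return fitted, float(res.fun)
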