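"""Synthetic rigid-body gait simulator.

Generates per-cycle data with the same structure as open lower-limb
biomechanics datasets: periodic joint kinematics, six-axis IMU signals per
segment, and hip/knee/ankle torque labels in N*m/kg, each cycle resampled to
101 time steps and split 7:2:1 at the cycle level.

Each joint's orientation trajectory is a truncated Fourier series (period =
cycle duration) with subject-specific random coefficients, so the angular
velocity and acceleration are available *analytically* — no numerical
differentiation touches the ground truth.  Torque labels are produced by the
exact forward Newton-Euler equation with the configured true inertia and
gravity coefficients, which makes the labels dynamically consistent with the
physics module by construction: the physics residual evaluated with the
generating parameters on noiseless signals is numerically zero, so inertia
recovery and physics-ablation effects are assertable.

The IMU model: gyroscope channels observe the angular velocity plus optional
bias and Gaussian noise; accelerometer channels observe gravity rotated into
the (moving) sensor frame plus tangential and centripetal terms at a fixed
sensor offset, plus noise.  The noise scale ``sigma`` is relative: it
multiplies the per-channel standard deviation of the clean signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .dataio import (
    CYCLE_LENGTH,
    JOINTS,
    CycleRecord,
    GaitDataset,
    write_dataset,
)
from .physics import SAGITTAL_AXIS, KinematicCycle

__all__ = [
    "NoiseConfig",
    "GaitSimConfig",
    "TorqueCycle",
    "generate_kinematics",
    "ground_truth_torque",
    "synthesize_imu",
    "resample_cycle",
    "simulate_dataset",
    "build_dataset",
    "default_true_inertia",
]

GRAVITY = 9.81  # m/s^2
_SENSOR_OFFSET = np.array([0.0, 0.0, 0.1])  # m, lever arm of the IMU on the segment


def default_true_inertia() -> np.ndarray:
    """Shank-like mass-normalized inertia: diag(0.12, 0.10, 0.05) + 0.01 off-diag."""
    i = np.diag([0.12, 0.10, 0.05])
    i += 0.01 * (np.ones((3, 3)) - np.eye(3))
    return i


@dataclass(frozen=True)
class NoiseConfig:
    sigma: float = 0.0  # additive Gaussian scale, relative to per-channel std
    gyro_bias: float = 0.0  # rad/s

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass(frozen=True)
class GaitSimConfig:
    n_subjects: int = 2
    n_cycles_per_subject: int = 24
    cycle_duration: float = 1.1  # s
    sample_rate: float = 100.0  # Hz
    fourier_order: int = 4
    excitation: Literal["sagittal_dominant", "full_3d"] = "sagittal_dominant"
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    true_inertia: tuple = field(
        default_factory=lambda: tuple(map(tuple, default_true_inertia()))
    )
    gravity_a_sin: tuple = (0.3, 0.1, 0.6)
    gravity_a_cos: tuple = (0.1, 0.2, 0.2)
    gravity_enabled: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.sample_rate * self.cycle_duration < 32:
            raise ValueError("need sample_rate * cycle_duration >= 32")
        i = self.inertia_matrix()
        if np.abs(i - i.T).max() > 1e-12 or np.linalg.eigvalsh(i).min() <= 0:
            raise ValueError("true_inertia must be symmetric positive definite")

    def inertia_matrix(self) -> np.ndarray:
        return np.asarray(self.true_inertia, dtype=np.float64)

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["noise"] = asdict(self.noise)
        return d

    @classmethod
    def from_manifest(cls, d: dict) -> "GaitSimConfig":
        d = dict(d)
        d["noise"] = NoiseConfig(**d["noise"])
        d["true_inertia"] = tuple(map(tuple, d["true_inertia"]))
        d["gravity_a_sin"] = tuple(d["gravity_a_sin"])
        d["gravity_a_cos"] = tuple(d["gravity_a_cos"])
        return cls(**d)


@dataclass(frozen=True)
class TorqueCycle:
    """A (T, 3) torque trajectory in N*m/kg with joint and provenance tags."""

    tau: np.ndarray
    joint: str
    role: Literal["ground_truth", "teacher", "student"] = "ground_truth"

    def __post_init__(self):
        t = np.asarray(self.tau, dtype=np.float64)
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError(f"torque trajectory must be (T, 3), got {t.shape}")
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite torque values")
        object.__setattr__(self, "tau", t)

    @property
    def sagittal(self) -> np.ndarray:
        return self.tau[:, SAGITTAL_AXIS]


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

_JOINT_INDEX = {j: i for i, j in enumerate(JOINTS)}
# per-axis base amplitude (rad) of the orientation Fourier series
_AMP = {
    "sagittal_dominant": np.array([0.05, 0.05, 0.45]),
    "full_3d": np.array([0.30, 0.35, 0.40]),
}


def _fourier_coeffs(cfg: GaitSimConfig, subject: int, cycle: int, joint: str):
    """Subject-level Fourier coefficients with a small per-cycle perturbation."""
    j = _JOINT_INDEX[joint]
    subj_rng = np.random.default_rng([cfg.seed, 11, subject, j])
    amp = _AMP[cfg.excitation]
    order = cfg.fourier_order
    decay = 1.0 / np.arange(1, order + 1)
    a = subj_rng.standard_normal((order, 3)) * decay[:, None] * amp
    b = subj_rng.standard_normal((order, 3)) * decay[:, None] * amp
    mean = subj_rng.standard_normal(3) * 0.1
    cyc_rng = np.random.default_rng([cfg.seed, 13, subject, j, cycle])
    jitter = 1.0 + 0.05 * cyc_rng.standard_normal((order, 3))
    return mean, a * jitter, b * jitter


def generate_kinematics(
    cfg: GaitSimConfig, subject: int, cycle: int, joint: str = "hip"
) -> KinematicCycle:
    """Analytic per-joint kinematics for one gait cycle.

    The three-axis orientation phi(t) is a truncated Fourier series; omega and
    omega_dot are its exact derivatives.  theta is the sagittal component of
    phi.  The returned cycle keeps the native sampling (dt = 1/sample_rate);
    use :func:`resample_cycle` for the 101-step normal form.
    """
    mean, a, b = _fourier_coeffs(cfg, subject, cycle, joint)
    period = cfg.cycle_duration
    n_raw = int(round(cfg.sample_rate * period)) + 1
    t = np.linspace(0.0, period, n_raw)
    w0 = 2.0 * np.pi / period
    phi = np.broadcast_to(mean, (n_raw, 3)).copy()
    omega = np.zeros((n_raw, 3))
    omega_dot = np.zeros((n_raw, 3))
    for n in range(1, cfg.fourier_order + 1):
        wn = n * w0
        c, s = np.cos(wn * t)[:, None], np.sin(wn * t)[:, None]
        phi += a[n - 1] * c + b[n - 1] * s
        omega += wn * (-a[n - 1] * s + b[n - 1] * c)
        omega_dot += wn**2 * (-a[n - 1] * c - b[n - 1] * s)
    kin = KinematicCycle(
        theta=phi[:, SAGITTAL_AXIS],
        omega=omega,
        omega_dot=omega_dot,
        dt=t[1] - t[0],
    )
    kin.phi = phi  # full orientation, used by the IMU model
    return kin


def ground_truth_torque(kin: KinematicCycle, cfg: GaitSimConfig, joint: str = "hip") -> TorqueCycle:
    """Exact forward Newton-Euler torque labels for a generated cycle."""
    i_eff = cfg.inertia_matrix()
    tau = kin.omega_dot @ i_eff + np.cross(kin.omega, kin.omega @ i_eff)
    if cfg.gravity_enabled:
        tau = (
            tau
            + np.sin(kin.theta)[:, None] * np.asarray(cfg.gravity_a_sin)
            + np.cos(kin.theta)[:, None] * np.asarray(cfg.gravity_a_cos)
        )
    return TorqueCycle(tau, joint=joint, role="ground_truth")


def synthesize_imu(
    kin: KinematicCycle, cfg: GaitSimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Six-axis IMU channels (gyro xyz, accel xyz) for a cycle, shape (6, T)."""
    phi = getattr(kin, "phi", None)
    if phi is None:
        phi = np.zeros((kin.n_samples, 3))
        phi[:, SAGITTAL_AXIS] = kin.theta
    rot = Rotation.from_euler("xyz", phi)
    g_world = np.array([0.0, 0.0, GRAVITY])
    acc_grav = rot.inv().apply(g_world)
    omega_dot = kin.omega_dot
    if omega_dot is None:
        raise ValueError("kinematics must carry angular acceleration")
    acc_rot = np.cross(omega_dot, _SENSOR_OFFSET) + np.cross(
        kin.omega, np.cross(kin.omega, _SENSOR_OFFSET)
    )
    gyro = kin.omega + cfg.noise.gyro_bias
    accel = acc_grav + acc_rot
    clean = np.concatenate([gyro, accel], axis=1).T  # (6, T)
    if cfg.noise.sigma > 0:
        scale = clean.std(axis=1, keepdims=True)
        clean = clean + cfg.noise.sigma * scale * rng.standard_normal(clean.shape)
    return clean


def resample_cycle(x: np.ndarray, n_out: int = CYCLE_LENGTH) -> np.ndarray:
    """Linear resampling onto ``n_out`` uniform points spanning the cycle.

    Endpoints are preserved exactly.  Accepts (T,) or (T, C).
    """
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    t_raw = x.shape[0]
    if t_raw < 2:
        raise ValueError(f"need at least 2 samples to resample, got {t_raw}")
    src = np.linspace(0.0, 1.0, t_raw)
    dst = np.linspace(0.0, 1.0, n_out)
    out = np.column_stack([np.interp(dst, src, x[:, c]) for c in range(x.shape[1])])
    return out[:, 0] if squeeze else out


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def _split_tags(n: int, seed: int) -> list[str]:
    """Cycle-level 7:2:1 split, deterministic in ``seed``, within +-1 cycle."""
    n_train = int(round(0.7 * n))
    n_val = int(round(0.2 * n))
    tags = ["train"] * n_train + ["val"] * n_val + ["test"] * (n - n_train - n_val)
    order = np.random.default_rng([seed, 777]).permutation(n)
    out = [""] * n
    for slot, idx in enumerate(order):
        out[idx] = tags[slot]
    return out


def simulate_dataset(cfg: GaitSimConfig) -> GaitDataset:
    """Generate the full in-memory dataset for all subjects, cycles and joints."""
    records: list[CycleRecord] = []
    pairs = [
        (s, c)
        for s in range(cfg.n_subjects)
        for c in range(cfg.n_cycles_per_subject)
    ]
    tags = _split_tags(len(pairs), cfg.seed)
    dt_norm = cfg.cycle_duration / (CYCLE_LENGTH - 1)
    for (subject, cycle), tag in zip(pairs, tags):
        columns: dict[str, np.ndarray] = {
            "time_index": np.arange(CYCLE_LENGTH, dtype=np.float64)
        }
        for joint in JOINTS:
            kin = generate_kinematics(cfg, subject, cycle, joint)
            tau = ground_truth_torque(kin, cfg, joint)
            noise_rng = np.random.default_rng(
                [cfg.seed, 17, subject, cycle, _JOINT_INDEX[joint]]
            )
            imu = synthesize_imu(kin, cfg, noise_rng)
            imu_rs = resample_cycle(imu.T).T
            for k, fieldname in enumerate(
                ("gyro_x", "gyro_y", "gyro_z", "acc_x", "acc_y", "acc_z")
            ):
                columns[f"{joint}_{fieldname}"] = imu_rs[k]
            columns[f"{joint}_angle"] = resample_cycle(kin.theta)
            columns[f"{joint}_torque"] = resample_cycle(tau.sagittal)
        records.append(
            CycleRecord(
                subject_id=subject,
                cycle_id=cycle,
                activity=cfg.excitation,
                split=tag,
                data=pd.DataFrame(columns),
                dt=dt_norm,
            )
        )
    manifest = {"generator": "gait_sim", "config": cfg.to_manifest()}
    return GaitDataset(records, manifest)


def build_dataset(cfg: GaitSimConfig, out_path: str | Path) -> GaitDataset:
    """Generate and persist a dataset; the manifest round-trips the config."""
    dataset = simulate_dataset(cfg)
    write_dataset(dataset, out_path)
    return dataset
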