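"""Evaluation metrics: accuracy, physical consistency, stability, noise sweeps.

Accuracy follows the standard gait-analysis conventions: R^2, RMSE, NRMSE as
a percentage of the ground-truth range, and Pearson correlation.  Physical
consistency (PCE) is the root-mean-square Newton-Euler residual of a predicted
torque trajectory over the interior of the cycle; Peak Error is the absolute
prediction deviation at the torque extrema.  Run-to-run stability is the
coefficient of variation of a metric across repeated runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .physics import (
    GravityModel,
    InertiaCholesky,
    KinematicCycle,
    SGConfig,
    filter_kinematics,
    interior_slice,
    newton_euler_torque,
)

__all__ = [
    "AccuracyMetrics",
    "accuracy_metrics",
    "physical_metrics",
    "peak_error",
    "stability_cv",
    "noise_sweep",
]


@dataclass(frozen=True)
class AccuracyMetrics:
    r2: float
    rmse: float
    nrmse_pct: float
    pcc: float

    def as_dict(self) -> dict:
        return {
            "r2": self.r2,
            "rmse": self.rmse,
            "nrmse_pct": self.nrmse_pct,
            "pcc": self.pcc,
        }


def accuracy_metrics(y: np.ndarray, yhat: np.ndarray) -> AccuracyMetrics:
    """R^2, RMSE, NRMSE (% of ground-truth range) and Pearson correlation.

    ``y`` and ``yhat`` may be any matching shape; they are flattened, so a
    stack of cycles is pooled.  A constant ground truth leaves R^2/PCC/NRMSE
    undefined and raises rather than silently returning zeros.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("ground truth is constant: R^2/PCC/NRMSE are undefined")
    resid = y - yhat
    ss_res = float((resid**2).sum())
    rmse = float(np.sqrt((resid**2).mean()))
    rng_y = float(y.max() - y.min())
    sd_hat = yhat.std()
    if sd_hat == 0.0:
        pcc = float("nan")
    else:
        pcc = float(np.corrcoef(y, yhat)[0, 1])
    return AccuracyMetrics(
        r2=1.0 - ss_res / ss_tot,
        rmse=rmse,
        nrmse_pct=100.0 * rmse / rng_y,
        pcc=pcc,
    )


def peak_error(
    tau_gt: np.ndarray,
    tau_s: np.ndarray,
    extrema_on: str = "ground_truth",
) -> float:
    """Absolute prediction deviation at the torque extrema of one cycle.

    The extrema (argmax and argmin) are located on the ground-truth sagittal
    trajectory by default — more stable than prediction-anchored extrema —
    with ``extrema_on="prediction"`` available as the alternative reading.
    """
    tau_gt = np.asarray(tau_gt, dtype=np.float64).ravel()
    tau_s = np.asarray(tau_s, dtype=np.float64).ravel()
    if tau_gt.shape != tau_s.shape:
        raise ValueError("trajectory length mismatch")
    anchor = tau_gt if extrema_on == "ground_truth" else tau_s
    idx = [int(np.argmax(anchor)), int(np.argmin(anchor))]
    return float(np.max(np.abs(tau_s[idx] - tau_gt[idx])))


def physical_metrics(
    tau_s: np.ndarray,
    tau_gt: np.ndarray,
    kin: KinematicCycle,
    inertia: InertiaCholesky,
    g: GravityModel,
    sg: SGConfig | None = None,
    extrema_on: str = "ground_truth",
) -> tuple[float, float]:
    """(PCE, Peak Error) for one cycle.

    PCE is the root-mean squared Newton-Euler residual over interior samples,
    computed against the supplied inertia/gravity parameters — either the
    model's own learned ones or, for synthetic audits, the generating truth.
    ``tau_s``/``tau_gt`` are sagittal trajectories (T,).
    """
    sg = sg or SGConfig()
    filter_kinematics(kin, sg)
    model_tau = newton_euler_torque(inertia, kin, g, use_filtered=True)
    if not isinstance(model_tau, np.ndarray):  # Tensor from trainable params
        model_tau = model_tau.data
    idx = interior_slice(kin.n_samples, sg)
    tau_s = np.asarray(tau_s, dtype=np.float64).ravel()
    resid = tau_s[idx] - model_tau[idx, 2]
    pce = float(np.sqrt((resid**2).mean()))
    return pce, peak_error(tau_gt, tau_s, extrema_on=extrema_on)


def stability_cv(values: Sequence[float]) -> float:
    """Coefficient of variation 100 * population-std / mean across runs."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least 2 runs for a CV")
    mean = v.mean()
    if mean == 0.0:
        raise ValueError("zero mean: CV undefined")
    return float(100.0 * v.std() / mean)


def noise_sweep(
    predict: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    y: np.ndarray,
    sigmas: Sequence[float],
    seed: int,
) -> pd.DataFrame:
    """Evaluate a predictor under additive input noise of increasing scale.

    ``predict`` maps inputs (N, C, T) -> sagittal torque (N, T).  For each
    sigma the held-out inputs are perturbed channel-wise by Gaussian noise of
    scale sigma * per-channel std (seeded), and the accuracy metrics are
    recomputed.  The sigma = 0 row is the clean evaluation, exactly.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    rows = []
    scale = x.std(axis=(0, 2), keepdims=True)  # per-channel std over the split
    for sigma in sigmas:
        if sigma < 0:
            raise ValueError(f"negative noise level {sigma}")
        if sigma == 0:
            x_noisy = x
        else:
            rng = np.random.default_rng([seed, int(round(1e6 * sigma))])
            x_noisy = x + sigma * scale * rng.standard_normal(x.shape)
        yhat = predict(x_noisy)
        m = accuracy_metrics(y, yhat)
        rows.append({"sigma": float(sigma), **m.as_dict()})
    return pd.DataFrame(rows)
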