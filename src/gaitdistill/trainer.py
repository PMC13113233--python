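"""Training: composite distillation objective and the teacher/student loops.

The student is trained under the composite objective

    L_total = L_data + alpha * L_KD + beta * L_Fisher + delta * L_subspace
              + gamma * L_phy

where L_data and L_KD are batch- and time-normalized squared errors against
the ground-truth and (frozen) teacher torques, L_Fisher and L_subspace align
the Gram image of the student's adapter with cached teacher-side anchor
structure, and L_phy is the Newton-Euler residual of the student's predictions
with the learnable equivalent inertia and gravity parameters (optimized
jointly with the network).  Teacher-side quantities — the anchor Gram matrix,
the diagonal Fisher information and the principal-subspace projector — are
computed once from the frozen teacher before the student sees a single batch
and stay fixed for the whole run.

Ablation presets: M0 trains the bare student (no teacher involvement at all —
bit-identical to a plain supervised run at the same seed), M1 adds response
distillation, M2 adds the two anchor-alignment terms, M3 adds the physics
term.  Stabilizers: AdamW, linear learning-rate warm-up and global gradient
clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import anchor as anchor_mod
from .anchor import (
    FisherWeights,
    SubspaceProjector,
    default_subspace_rank,
    estimate_fisher_diag,
    principal_projector,
)
from .autodiff import Tensor
from .dataio import GaitDataset, load_checkpoint, save_checkpoint, weights_checksum
from .models import (
    StudentConfig,
    StudentNet,
    TeacherConfig,
    TeacherNet,
    cwt_scalogram,
)
from .nn import AdamW, clip_grad_norm
from .physics import (
    SAGITTAL_AXIS,
    GravityModel,
    InertiaCholesky,
    SGConfig,
    interior_slice,
    sg_smooth_derivative,
)

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "TrainConfig",
    "data_loss",
    "kd_loss",
    "weighted_total",
    "composite_loss",
    "train_teacher",
    "distill",
    "train_student_supervised",
    "predict",
    "TeacherRun",
    "StudentRun",
    "save_teacher",
    "load_teacher",
    "save_student",
    "load_student",
]


# ---------------------------------------------------------------------------
# loss algebra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LossWeights:
    """Weights (alpha, beta, delta, gamma) of the composite objective."""

    alpha: float = 0.5
    beta: float = 0.1
    delta: float = 0.1
    gamma: float = 0.05

    def __post_init__(self):
        if min(self.alpha, self.beta, self.delta, self.gamma) < 0:
            raise ValueError("loss weights must be nonnegative")

    @classmethod
    def preset(cls, name: str) -> "LossWeights":
        presets = {
            "M0": cls(0.0, 0.0, 0.0, 0.0),
            "M1": cls(0.5, 0.0, 0.0, 0.0),
            "M2": cls(0.5, 0.1, 0.1, 0.0),
            "M3": cls(0.5, 0.1, 0.1, 0.05),
        }
        if name not in presets:
            raise ValueError(f"unknown ablation preset {name!r} (use M0..M3)")
        return presets[name]


@dataclass(frozen=True)
class LossBreakdown:
    total: float
    data: float
    kd: float
    fisher: float
    subspace: float
    phy: float


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 8
    lr: float = 1e-3
    warmup_epochs: int = 5
    clip_norm: float = 1.0
    weight_decay: float = 0.0
    seed: int = 0
    joint: str = "hip"
    sg: SGConfig = field(default_factory=SGConfig)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _sq_mean_bt(a, b):
    """(1/(B*T)) sum of axis-summed squared differences; Tensor-aware."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if len(a.shape) != 3:
        raise ValueError("expected (B, T, A) torque batches")
    bt = a.shape[0] * a.shape[1]
    d = b - a
    return (d * d).sum() * (1.0 / bt)


def data_loss(tau_gt, tau_s):
    """L_data: squared error against ground truth, averaged over batch and time."""
    out = _sq_mean_bt(tau_gt, tau_s)
    return out if isinstance(out, Tensor) else float(out)


def kd_loss(tau_t, tau_s):
    """L_KD: same normalization, against the frozen teacher's predictions."""
    out = _sq_mean_bt(tau_t, tau_s)
    return out if isinstance(out, Tensor) else float(out)


def weighted_total(data, kd, fisher, subspace, phy, w: LossWeights):
    """L_total = L_data + alpha L_KD + beta L_Fisher + delta L_subspace + gamma L_phy."""
    return data + w.alpha * kd + w.beta * fisher + w.delta * subspace + w.gamma * phy


def composite_loss(
    tau_gt,
    tau_s,
    w: LossWeights,
    tau_t=None,
    ws=None,
    caches: dict | None = None,
    phy=None,
) -> tuple[Tensor, LossBreakdown]:
    """Assemble the composite objective for one batch.

    Returns the total as a graph node plus a float breakdown.  Components with
    zero weight are not computed (and their inputs may be omitted); missing
    inputs for an active component raise a configuration error.
    """

    def val(x) -> float:
        return float(x.data) if isinstance(x, Tensor) else float(x)

    ldata = data_loss(tau_gt, tau_s)
    total = ldata
    lkd = lfisher = lsub = lphy = 0.0
    if w.alpha > 0:
        if tau_t is None:
            raise ValueError("alpha > 0 requires teacher predictions")
        lkd = kd_loss(tau_t, tau_s)
        total = total + w.alpha * lkd
    if w.beta > 0 or w.delta > 0:
        if ws is None or caches is None:
            raise ValueError("beta/delta > 0 require the adapter weight and teacher caches")
        gs = anchor_mod.gram(ws)
        gt = caches["gram_t"]
        if w.beta > 0:
            lfisher = anchor_mod.fisher_align_loss(gs, gt, caches["fisher"])
            total = total + w.beta * lfisher
        if w.delta > 0:
            lsub = anchor_mod.subspace_loss(gs, gt, caches["projector"])
            total = total + w.delta * lsub
    if w.gamma > 0:
        if phy is None:
            raise ValueError("gamma > 0 requires a physics residual")
        lphy = phy
        total = total + w.gamma * lphy
    breakdown = LossBreakdown(
        total=val(total),
        data=val(ldata),
        kd=val(lkd),
        fisher=val(lfisher),
        subspace=val(lsub),
        phy=val(lphy),
    )
    return total, breakdown


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------


@dataclass
class _SplitArrays:
    x: np.ndarray  # normalized inputs (N, 6, 101)
    y: np.ndarray  # sagittal torque labels (N, 101, 1)
    scalograms: np.ndarray | None  # (N, 6, S, 101) for the teacher
    phys: dict | None  # stacked filtered kinematics for the physics term


def _normalize(x: np.ndarray, stats: dict) -> np.ndarray:
    return (x - stats["mean"]) / stats["std"]


def _norm_stats(x: np.ndarray) -> dict:
    mean = x.mean(axis=(0, 2), keepdims=True)
    std = x.std(axis=(0, 2), keepdims=True)
    std[std == 0] = 1.0
    return {"mean": mean, "std": std}


def _physics_arrays(kins, sg: SGConfig) -> dict:
    """Precompute the model-independent pieces of the physics residual.

    All cycles share T = 101, so the interior slice is common; the filtered
    angular velocity/acceleration and the angle trigs are stacked to
    (N, Ti, .) for batched evaluation.
    """
    smooth = SGConfig(sg.window, sg.polyorder, 0)
    deriv = SGConfig(sg.window, sg.polyorder, 1)
    idx = interior_slice(kins[0].n_samples, sg)
    omega_f, omega_dot_f, sin_t, cos_t = [], [], [], []
    for kin in kins:
        wf = sg_smooth_derivative(kin.omega, smooth, kin.dt)
        wdf = sg_smooth_derivative(kin.omega, deriv, kin.dt)
        omega_f.append(wf[idx])
        omega_dot_f.append(wdf[idx])
        sin_t.append(np.sin(kin.theta[idx]))
        cos_t.append(np.cos(kin.theta[idx]))
    return {
        "idx": idx,
        "omega": np.stack(omega_f),  # (N, Ti, 3)
        "omega_dot": np.stack(omega_dot_f),
        "sin": np.stack(sin_t)[..., None],  # (N, Ti, 1)
        "cos": np.stack(cos_t)[..., None],
    }


def _physics_batch_residual(
    tau_s: Tensor,
    phys: dict,
    batch_idx: np.ndarray,
    inertia: InertiaCholesky,
    gravity: GravityModel,
):
    """Mean squared sagittal Newton-Euler residual over a batch's interiors."""
    idx = phys["idx"]
    omega = phys["omega"][batch_idx].reshape(-1, 3)
    omega_dot = phys["omega_dot"][batch_idx].reshape(-1, 3)
    sin_t = phys["sin"][batch_idx].reshape(-1, 1)
    cos_t = phys["cos"][batch_idx].reshape(-1, 1)
    ieff = inertia.i_eff_tensor()
    model = Tensor(omega_dot) @ ieff
    iw = Tensor(omega) @ ieff
    # omega x (I omega), sagittal row only is needed, but build full for clarity
    wx, wy = omega[:, 0], omega[:, 1]
    cross_z = iw[:, 1] * wx - iw[:, 0] * wy  # z-component of omega x (I omega)
    model_z = model[:, SAGITTAL_AXIS] + cross_z
    if gravity.enabled:
        gz = gravity.a_sin[SAGITTAL_AXIS] * sin_t[:, 0] + gravity.a_cos[
            SAGITTAL_AXIS
        ] * cos_t[:, 0]
        model_z = model_z + gz
    tau_int = tau_s[:, idx, 0].reshape(-1)
    resid = tau_int - model_z
    return (resid * resid).mean()


def _prepare_split(
    dataset: GaitDataset,
    joint: str,
    split: str,
    stats: dict,
    sg: SGConfig,
    with_scalograms: bool,
    teacher_cfg: TeacherConfig | None = None,
    with_physics: bool = False,
) -> _SplitArrays:
    arrs = dataset.arrays(joint, split)
    x = _normalize(arrs["x"], stats)
    y = arrs["y"][..., None]
    scal = None
    if with_scalograms:
        fs = 1.0 / arrs["kin"][0].dt
        scal = np.stack(
            [cwt_scalogram(xi, teacher_cfg, fs=fs).values for xi in x]
        )
    phys = _physics_arrays(arrs["kin"], sg) if with_physics else None
    return _SplitArrays(x=x, y=y, scalograms=scal, phys=phys)


# ---------------------------------------------------------------------------
# runs
# ---------------------------------------------------------------------------


@dataclass
class TeacherRun:
    model: TeacherNet
    config: TeacherConfig
    train_config: TrainConfig
    stats: dict
    history: pd.DataFrame


@dataclass
class StudentRun:
    model: StudentNet
    config: StudentConfig
    train_config: TrainConfig
    weights: LossWeights
    stats: dict
    history: pd.DataFrame
    inertia: InertiaCholesky
    gravity: GravityModel
    caches: dict | None = None
    teacher_checksum: str | None = None


def _epoch_lr(cfg: TrainConfig, epoch: int) -> float:
    if cfg.warmup_epochs > 0 and epoch < cfg.warmup_epochs:
        return cfg.lr * (epoch + 1) / cfg.warmup_epochs
    return cfg.lr


def _eval_data_loss(model, x, y, batch_size: int = 16) -> float:
    total, n = 0.0, 0
    for lo in range(0, x.shape[0], batch_size):
        xb = x[lo : lo + batch_size]
        tau = model(xb)
        b = xb.shape[0]
        total += float(data_loss(Tensor(y[lo : lo + b]), tau).data) * b
        n += b
    return total / n


def predict(model, x, batch_size: int = 16) -> np.ndarray:
    """Batched forward pass -> sagittal torque trajectories (N, T)."""
    outs = []
    for lo in range(0, x.shape[0], batch_size):
        outs.append(model(x[lo : lo + batch_size]).data[..., 0])
    return np.concatenate(outs)


def train_teacher(
    dataset: GaitDataset,
    cfg: TrainConfig,
    model_cfg: TeacherConfig | None = None,
) -> TeacherRun:
    """Supervised teacher training on CWT scalograms; keeps the best-validation
    weights; deterministic given ``cfg.seed``."""
    model_cfg = model_cfg or TeacherConfig.test()
    train_x_raw = dataset.arrays(cfg.joint, "train")["x"]
    if train_x_raw.shape[0] == 0:
        raise ValueError("empty training split")
    stats = _norm_stats(train_x_raw)
    train = _prepare_split(dataset, cfg.joint, "train", stats, cfg.sg, True, model_cfg)
    val = _prepare_split(dataset, cfg.joint, "val", stats, cfg.sg, True, model_cfg)

    model = TeacherNet(model_cfg, seed=cfg.seed)
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    n = train.x.shape[0]
    rows = []
    best = (np.inf, None)
    for epoch in range(cfg.epochs):
        opt.lr = _epoch_lr(cfg, epoch)
        order = np.random.default_rng([cfg.seed, 101, epoch]).permutation(n)
        epoch_loss, norms = [], []
        for lo in range(0, n, cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            tau = model(train.scalograms[sel])
            loss = data_loss(Tensor(train.y[sel]), tau)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite teacher loss at epoch {epoch}, step {lo // cfg.batch_size}"
                )
            model.zero_grad()
            loss.backward()
            norms.append(clip_grad_norm(model.parameters(), cfg.clip_norm))
            opt.step()
            epoch_loss.append(float(loss.data))
        val_loss = _eval_data_loss(model, val.scalograms, val.y)
        rows.append(
            {
                "epoch": epoch,
                "train_data": float(np.mean(epoch_loss)),
                "val_data": val_loss,
                "lr": opt.lr,
                "grad_norm": float(np.mean(norms)),
            }
        )
        if val_loss < best[0]:
            best = (val_loss, model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])
    return TeacherRun(model, model_cfg, cfg, stats, pd.DataFrame(rows))


def _build_caches(teacher: TeacherNet, train: _SplitArrays, batch_size: int = 16) -> dict:
    """Teacher-side anchor artifacts, computed once from the frozen teacher."""
    wt = teacher.anchor_weights().data.copy()
    gram_t = wt.T @ wt
    batches = [
        (train.scalograms[lo : lo + batch_size], train.y[lo : lo + batch_size])
        for lo in range(0, train.x.shape[0], batch_size)
    ]
    fisher = estimate_fisher_diag(teacher, batches)
    projector = principal_projector(gram_t, default_subspace_rank(gram_t))
    return {"gram_t": gram_t, "fisher": fisher, "projector": projector}


def distill(
    teacher_run: TeacherRun | None,
    dataset: GaitDataset,
    cfg: TrainConfig,
    weights: LossWeights,
    student_cfg: StudentConfig | None = None,
) -> StudentRun:
    """Student distillation under the composite objective.

    With all weights zero (preset M0) the teacher is never touched and the run
    is exactly a supervised student training.  Physics parameters (inertia and
    gravity) are created from the run seed and optimized jointly with the
    network when gamma > 0.
    """
    needs_teacher = weights.alpha > 0 or weights.beta > 0 or weights.delta > 0
    if needs_teacher and teacher_run is None:
        raise ValueError("this preset requires a trained teacher")
    if student_cfg is None:
        student_cfg = StudentConfig.test(
            d_anchor=teacher_run.config.d_anchor if teacher_run else 16
        )
    if teacher_run is not None and student_cfg.d_anchor != teacher_run.config.d_anchor:
        raise ValueError(
            f"anchor width mismatch: student {student_cfg.d_anchor} vs "
            f"teacher {teacher_run.config.d_anchor}"
        )

    train_x_raw = dataset.arrays(cfg.joint, "train")["x"]
    if train_x_raw.shape[0] == 0:
        raise ValueError("empty training split")
    stats = teacher_run.stats if teacher_run is not None else _norm_stats(train_x_raw)
    train = _prepare_split(
        dataset, cfg.joint, "train", stats, cfg.sg,
        with_scalograms=needs_teacher,
        teacher_cfg=teacher_run.config if teacher_run else None,
        with_physics=True,
    )
    val = _prepare_split(
        dataset, cfg.joint, "val", stats, cfg.sg, False, with_physics=True
    )

    caches = None
    tau_t_train = None
    teacher_checksum = None
    if needs_teacher:
        teacher = teacher_run.model
        teacher_checksum = weights_checksum(teacher.state_dict())
        caches = _build_caches(teacher, train)
        tau_t_train = np.concatenate(
            [
                teacher(train.scalograms[lo : lo + 16]).data
                for lo in range(0, train.x.shape[0], 16)
            ]
        )
        checksum_after = weights_checksum(teacher.state_dict())
        assert checksum_after == teacher_checksum  # teacher must stay frozen

    student = StudentNet(student_cfg, seed=cfg.seed)
    phys_rng = np.random.default_rng([cfg.seed, 999])
    inertia = InertiaCholesky(trainable=True)
    gravity = GravityModel.trainable(phys_rng)
    params = student.parameters()
    if weights.gamma > 0:
        params = params + [inertia.raw] + gravity.parameters()
    opt = AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)

    n = train.x.shape[0]
    rows = []
    best = (np.inf, None, None, None)
    for epoch in range(cfg.epochs):
        opt.lr = _epoch_lr(cfg, epoch)
        order = np.random.default_rng([cfg.seed, 202, epoch]).permutation(n)
        comp_sums = np.zeros(6)
        norms = []
        n_batches = 0
        for lo in range(0, n, cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            tau_s, _z, ws = student.forward_with_anchor(train.x[sel])
            phy = (
                _physics_batch_residual(tau_s, train.phys, sel, inertia, gravity)
                if weights.gamma > 0
                else None
            )
            total, br = composite_loss(
                Tensor(train.y[sel]),
                tau_s,
                weights,
                tau_t=Tensor(tau_t_train[sel]) if tau_t_train is not None else None,
                ws=ws,
                caches=caches,
                phy=phy,
            )
            if not np.isfinite(br.total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {lo // cfg.batch_size}"
                )
            for p in params:
                p.grad = None
            total.backward()
            norms.append(clip_grad_norm(params, cfg.clip_norm))
            opt.step()
            comp_sums += np.array(
                [br.total, br.data, br.kd, br.fisher, br.subspace, br.phy]
            )
            n_batches += 1
        val_loss = _eval_data_loss(student, val.x, val.y)
        val_pce = _val_pce(student, val, inertia, gravity)
        means = comp_sums / n_batches
        rows.append(
            {
                "epoch": epoch,
                "total": means[0],
                "data": means[1],
                "kd": means[2],
                "fisher": means[3],
                "subspace": means[4],
                "phy": means[5],
                "val_data": val_loss,
                "val_pce": val_pce,
                "lr": opt.lr,
                "grad_norm": float(np.mean(norms)),
            }
        )
        if val_loss < best[0]:
            best = (
                val_loss,
                student.state_dict(),
                inertia.raw.data.copy(),
                (gravity.a_sin.data.copy(), gravity.a_cos.data.copy()),
            )
    if best[1] is not None:
        student.load_state_dict(best[1])
        inertia.raw.data = best[2]
        gravity.a_sin.data, gravity.a_cos.data = best[3]
    return StudentRun(
        model=student,
        config=student_cfg,
        train_config=cfg,
        weights=weights,
        stats=stats,
        history=pd.DataFrame(rows),
        inertia=inertia,
        gravity=gravity,
        caches=caches,
        teacher_checksum=teacher_checksum,
    )


def _val_pce(student: StudentNet, val: _SplitArrays, inertia, gravity) -> float:
    """RMS Newton-Euler residual of validation predictions with the run's own
    physics parameters."""
    tau = predict(student, val.x)[:, val.phys["idx"]]
    r = _physics_batch_residual(
        Tensor(tau[..., None]),
        {**val.phys, "idx": slice(None)},
        np.arange(tau.shape[0]),
        InertiaCholesky(inertia.raw.data.copy(), trainable=True),
        gravity,
    )
    return float(np.sqrt(r.data))


def train_student_supervised(
    dataset: GaitDataset, cfg: TrainConfig, student_cfg: StudentConfig | None = None
) -> StudentRun:
    """Plain supervised student training (identical to preset M0)."""
    return distill(None, dataset, cfg, LossWeights.preset("M0"), student_cfg)


# ---------------------------------------------------------------------------
# checkpoint adapters
# ---------------------------------------------------------------------------


def _stats_to_json(stats: dict) -> dict:
    return {k: v.tolist() for k, v in stats.items()}


def _stats_from_json(d: dict) -> dict:
    return {k: np.asarray(v, dtype=np.float64) for k, v in d.items()}


def save_teacher(run: TeacherRun, path: str | Path) -> Path:
    return save_checkpoint(
        path,
        run.model.state_dict(),
        {
            "kind": "teacher",
            "model": asdict(run.config),
            "train": _train_cfg_json(run.train_config),
            "stats": _stats_to_json(run.stats),
        },
        history=run.history,
    )


def load_teacher(path: str | Path) -> TeacherRun:
    ck = load_checkpoint(path)
    if ck["config"].get("kind") != "teacher":
        raise ValueError("not a teacher checkpoint")
    mc = dict(ck["config"]["model"])
    mc["conv_channels"] = tuple(mc["conv_channels"])
    cfg = TeacherConfig(**mc)
    model = TeacherNet(cfg, seed=ck["config"]["train"]["seed"])
    model.load_state_dict(ck["state"])
    return TeacherRun(
        model,
        cfg,
        _train_cfg_from_json(ck["config"]["train"]),
        _stats_from_json(ck["config"]["stats"]),
        ck["history"],
    )


def save_student(run: StudentRun, path: str | Path) -> Path:
    caches = {}
    if run.caches is not None:
        caches = {
            "gram_t": run.caches["gram_t"],
            "fisher_diag": run.caches["fisher"].diag,
            "fisher_n": np.array([run.caches["fisher"].n_samples]),
            "basis": run.caches["projector"].basis,
        }
    caches["inertia_raw"] = run.inertia.raw.data
    caches["gravity_a_sin"] = run.gravity.a_sin.data
    caches["gravity_a_cos"] = run.gravity.a_cos.data
    return save_checkpoint(
        path,
        run.model.state_dict(),
        {
            "kind": "student",
            "model": asdict(run.config),
            "train": _train_cfg_json(run.train_config),
            "weights": asdict(run.weights),
            "stats": _stats_to_json(run.stats),
            "teacher_checksum": run.teacher_checksum,
        },
        caches=caches,
        history=run.history,
    )


def load_student(path: str | Path) -> StudentRun:
    ck = load_checkpoint(path)
    if ck["config"].get("kind") != "student":
        raise ValueError("not a student checkpoint")
    cfg = StudentConfig(**ck["config"]["model"])
    model = StudentNet(cfg, seed=ck["config"]["train"]["seed"])
    model.load_state_dict(ck["state"])
    caches = None
    c = ck["caches"]
    if "gram_t" in c:
        caches = {
            "gram_t": c["gram_t"],
            "fisher": FisherWeights(c["fisher_diag"], int(c["fisher_n"][0])),
            "projector": SubspaceProjector(c["basis"], c["basis"].shape[1]),
        }
    return StudentRun(
        model=model,
        config=cfg,
        train_config=_train_cfg_from_json(ck["config"]["train"]),
        weights=LossWeights(**ck["config"]["weights"]),
        stats=_stats_from_json(ck["config"]["stats"]),
        history=ck["history"],
        inertia=InertiaCholesky(c["inertia_raw"]),
        gravity=GravityModel(c["gravity_a_sin"], c["gravity_a_cos"]),
        caches=caches,
        teacher_checksum=ck["config"].get("teacher_checksum"),
    )


def _train_cfg_json(cfg: TrainConfig) -> dict:
    d = asdict(cfg)
    d["sg"] = asdict(cfg.sg)
    return d


def _train_cfg_from_json(d: dict) -> TrainConfig:
    d = dict(d)
    d["sg"] = SGConfig(**d["sg"])
    return TrainConfig(**d)
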