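"""Dataset format, manifests and checkpoint containers.

A dataset is a directory of one CSV per subject plus a ``manifest.json``
sidecar.  Every gait cycle occupies exactly 101 rows (0..100 % of the cycle)
with a fixed, versioned column schema: a time index, six IMU channels per
joint segment (gyro x/y/z then accelerometer x/y/z), one joint angle and one
torque label per joint.  Cycles carry subject/cycle ids, an activity label and
a train/val/test split tag assigned at the cycle level.

Checkpoints are directories: ``weights.npz`` (model parameters and any cached
teacher-side artifacts) plus ``config.json`` (architecture config, seed,
normalization statistics, training-history summary).  Teacher-derived caches
are keyed by a checksum of the teacher weights so a stale cache is detected at
load time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .physics import KinematicCycle

__all__ = [
    "FORMAT_VERSION",
    "CYCLE_LENGTH",
    "JOINTS",
    "CycleRecord",
    "GaitDataset",
    "write_dataset",
    "read_dataset",
    "save_checkpoint",
    "load_checkpoint",
    "weights_checksum",
]

FORMAT_VERSION = "1"
CYCLE_LENGTH = 101
JOINTS = ("hip", "knee", "ankle")
_IMU_FIELDS = ("gyro_x", "gyro_y", "gyro_z", "acc_x", "acc_y", "acc_z")


def cycle_columns(joints: tuple[str, ...] = JOINTS) -> list[str]:
    cols = ["time_index"]
    for j in joints:
        cols += [f"{j}_{f}" for f in _IMU_FIELDS]
        cols += [f"{j}_angle", f"{j}_torque"]
    return cols


@dataclass
class CycleRecord:
    """One time-normalized gait cycle (101 rows x fixed schema)."""

    subject_id: int
    cycle_id: int
    activity: str
    split: str
    data: pd.DataFrame
    dt: float

    def __post_init__(self):
        if self.split not in ("train", "val", "test"):
            raise ValueError(f"unknown split tag {self.split!r}")
        if len(self.data) != CYCLE_LENGTH:
            raise ValueError(
                f"cycle s{self.subject_id}c{self.cycle_id} has {len(self.data)} rows, "
                f"expected {CYCLE_LENGTH}"
            )
        missing = set(cycle_columns()) - set(self.data.columns)
        if missing:
            raise ValueError(
                f"cycle s{self.subject_id}c{self.cycle_id} missing columns {sorted(missing)}"
            )
        if not np.all(np.isfinite(self.data.to_numpy(dtype=np.float64))):
            raise ValueError(
                f"cycle s{self.subject_id}c{self.cycle_id} contains non-finite values"
            )

    def imu(self, joint: str) -> np.ndarray:
        """(6, 101) IMU channels for the joint's segment."""
        cols = [f"{joint}_{f}" for f in _IMU_FIELDS]
        return self.data[cols].to_numpy(dtype=np.float64).T

    def torque(self, joint: str) -> np.ndarray:
        return self.data[f"{joint}_torque"].to_numpy(dtype=np.float64)

    def angle(self, joint: str) -> np.ndarray:
        return self.data[f"{joint}_angle"].to_numpy(dtype=np.float64)

    def kinematics(self, joint: str) -> KinematicCycle:
        """Kinematics as a sensor would provide them: omega from the gyro."""
        gyro = self.data[[f"{joint}_gyro_{a}" for a in "xyz"]].to_numpy(np.float64)
        return KinematicCycle(
            theta=self.angle(joint), omega=gyro, omega_dot=None, dt=self.dt
        )


@dataclass
class GaitDataset:
    cycles: list[CycleRecord]
    manifest: dict = field(default_factory=dict)

    def split(self, tag: str) -> list[CycleRecord]:
        return [c for c in self.cycles if c.split == tag]

    def arrays(self, joint: str, split: str) -> dict:
        """Stacked training arrays for one joint: inputs (N, 6, 101), sagittal
        torque labels (N, 101) and per-cycle kinematics."""
        recs = self.split(split)
        if not recs:
            raise ValueError(f"no cycles in split {split!r}")
        return {
            "x": np.stack([r.imu(joint) for r in recs]),
            "y": np.stack([r.torque(joint) for r in recs]),
            "kin": [r.kinematics(joint) for r in recs],
            "records": recs,
        }


# ---------------------------------------------------------------------------
# dataset (de)serialization
# ---------------------------------------------------------------------------


def write_dataset(dataset: GaitDataset, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    by_subject: dict[int, list[CycleRecord]] = {}
    for rec in dataset.cycles:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    for sid, recs in sorted(by_subject.items()):
        frames = []
        for rec in sorted(recs, key=lambda r: r.cycle_id):
            df = rec.data.copy()
            df.insert(0, "cycle_id", rec.cycle_id)
            df.insert(0, "subject_id", rec.subject_id)
            df["activity"] = rec.activity
            df["split"] = rec.split
            df["dt"] = rec.dt
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(
            path / f"subject_{sid:03d}.csv", index=False, float_format="%.12g"
        )
    manifest = dict(dataset.manifest)
    manifest.setdefault("format_version", FORMAT_VERSION)
    manifest["columns"] = cycle_columns()
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_dataset(path: str | Path) -> GaitDataset:
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {path}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported dataset format version {manifest.get('format_version')!r}"
        )
    cycles: list[CycleRecord] = []
    for csv_path in sorted(path.glob("subject_*.csv")):
        df = pd.read_csv(csv_path)
        for (sid, cid), group in df.groupby(["subject_id", "cycle_id"], sort=True):
            group = group.reset_index(drop=True)
            cycles.append(
                CycleRecord(
                    subject_id=int(sid),
                    cycle_id=int(cid),
                    activity=str(group["activity"].iloc[0]),
                    split=str(group["split"].iloc[0]),
                    data=group[cycle_columns()].astype(np.float64),
                    dt=float(group["dt"].iloc[0]),
                )
            )
    if not cycles:
        raise ValueError(f"no cycles found under {path}")
    return GaitDataset(cycles, manifest)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def weights_checksum(state: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for name in sorted(state):
        h.update(name.encode())
        h.update(np.ascontiguousarray(state[name]).tobytes())
    return h.hexdigest()


def save_checkpoint(
    path: str | Path,
    state: dict[str, np.ndarray],
    config: dict,
    caches: dict[str, np.ndarray] | None = None,
    history: pd.DataFrame | None = None,
) -> Path:
    """Persist model weights + config (+ teacher-derived caches and history)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {f"w/{k}": v for k, v in state.items()}
    if caches:
        arrays.update({f"c/{k}": np.asarray(v) for k, v in caches.items()})
    np.savez(path / "weights.npz", **arrays)
    meta = dict(config)
    meta["checksum"] = weights_checksum(state)
    (path / "config.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    if history is not None:
        history.to_csv(path / "history.csv", index=False)
    return path


def load_checkpoint(path: str | Path) -> dict:
    """Load a checkpoint directory -> {state, caches, config, history}.

    Verifies the stored checksum against the weights actually loaded, so a
    cache produced from a different teacher fails loudly.
    """
    path = Path(path)
    config = json.loads((path / "config.json").read_text())
    with np.load(path / "weights.npz") as npz:
        state = {k[2:]: npz[k] for k in npz.files if k.startswith("w/")}
        caches = {k[2:]: npz[k] for k in npz.files if k.startswith("c/")}
    actual = weights_checksum(state)
    if actual != config.get("checksum"):
        raise ValueError(
            "checkpoint checksum mismatch: weights do not match the model/caches "
            f"this checkpoint was written for (stored {config.get('checksum')!r})"
        )
    history_path = path / "history.csv"
    history = pd.read_csv(history_path) if history_path.exists() else None
    return {"state": state, "caches": caches, "config": config, "history": history}
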