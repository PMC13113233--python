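"""Shared fixtures: simulated datasets and trained runs.

The expensive artifacts (trained teacher, distilled students) are
session-scoped so the end-to-end checks share one training run each.
Problem sizes are desk-scale: 2 subjects x 24 cycles, test-preset models,
hip joint.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaitdistill.gait_sim import GaitSimConfig, NoiseConfig, simulate_dataset
from gaitdistill.models import TeacherConfig
from gaitdistill.trainer import LossWeights, TrainConfig, distill, train_teacher

TEACHER_EPOCHS = 150
STUDENT_EPOCHS = 60
LR = 2e-3


@pytest.fixture(scope="session")
def clean_sim_config() -> GaitSimConfig:
    return GaitSimConfig(n_subjects=2, n_cycles_per_subject=24, seed=11)


@pytest.fixture(scope="session")
def clean_dataset(clean_sim_config):
    return simulate_dataset(clean_sim_config)


@pytest.fixture(scope="session")
def noisy_sim_config() -> GaitSimConfig:
    return GaitSimConfig(
        n_subjects=2, n_cycles_per_subject=24, seed=11, noise=NoiseConfig(sigma=0.1)
    )


@pytest.fixture(scope="session")
def noisy_dataset(noisy_sim_config):
    return simulate_dataset(noisy_sim_config)


@pytest.fixture(scope="session")
def teacher_run(clean_dataset):
    return train_teacher(
        clean_dataset,
        TrainConfig(epochs=TEACHER_EPOCHS, lr=LR, seed=1),
        TeacherConfig.test(),
    )


@pytest.fixture(scope="session")
def noisy_teacher_run(noisy_dataset):
    return train_teacher(
        noisy_dataset,
        TrainConfig(epochs=TEACHER_EPOCHS, lr=LR, seed=1),
        TeacherConfig.test(),
    )


@pytest.fixture(scope="session")
def m3_student_run(teacher_run, clean_dataset):
    return distill(
        teacher_run,
        clean_dataset,
        TrainConfig(epochs=STUDENT_EPOCHS, lr=LR, seed=1),
        LossWeights.preset("M3"),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
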