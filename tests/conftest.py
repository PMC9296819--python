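import numpy as np
import pytest

from metadecode import (
    LabeledDataset,
    SimulatorParams,
    TrainerConfig,
    calibrate_simulator,
)


@pytest.fixture(scope="session")
def calibrated_params() -> SimulatorParams:
    """Simulator calibrated once to the ~3:1 class imbalance of the study."""
    return calibrate_simulator(
        SimulatorParams(), target_positive_fraction=136 / 600, n_pilot=3000, seed=7
    )


@pytest.fixture(scope="session")
def small_trainer_config() -> TrainerConfig:
    """Small MLP and short schedule for toy-problem tests."""
    return TrainerConfig(
        hidden_sizes=(16, 8), max_epochs=40, max_steps=400, patience=10
    )


def make_toy_task(
    n_train: int = 200,
    n_val: int = 20,
    n_test: int = 200,
    flip_fraction: float = 0.4,
    seed: int = 0,
):
    """Separable 2-D two-blob task with a fraction of flipped training labels.

    Returns (train, val, test): train carries clean labels and a mislabel
    mask; val and test are clean.
    """
    rng = np.random.default_rng(seed)

    def blob(n):
        y = (rng.random(n) < 0.5).astype(int)
        centers = np.array([[-1.5, 0.0], [1.5, 0.0]])
        x = centers[y] + rng.normal(0, 0.5, size=(n, 2))
        return x, y

    xt, yt = blob(n_train)
    noisy = yt.copy()
    k = int(round(flip_fraction * n_train))
    flip_idx = rng.choice(n_train, k, replace=False)
    noisy[flip_idx] = 1 - noisy[flip_idx]
    train = LabeledDataset(
        xt, noisy, clean_labels=yt, mislabel_mask=noisy != yt
    )
    xv, yv = blob(n_val)
    xs, ys = blob(n_test)
    return train, LabeledDataset(xv, yv), LabeledDataset(xs, ys)
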