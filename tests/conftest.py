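import numpy as np
import pytest

from facemg.synthetic import (
    GestureProfile,
    SimulationConfig,
    default_profiles,
    generate_dataset,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """One full synthetic subject: 10 gestures x 5 x 2 s x 3 channels."""
    return generate_dataset(default_profiles(), default_config, "S1")


@pytest.fixture(scope="session")
def tiny_dataset():
    """Two gestures, two 2-s trials each: fast input for bookkeeping tests."""
    profiles = [
        GestureProfile("G1", (0.5, 0.2, 0.5)),
        GestureProfile("G2", (1.0, 0.1, 0.9)),
    ]
    cfg = SimulationConfig(trials_per_gesture=2, seed=5)
    return generate_dataset(profiles, cfg, "S1")


@pytest.fixture(scope="session")
def blob_data():
    """10 tight, well-separated 3-D Gaussian classes: 30 train / 10 test each.

    Class centers sit on a unit-cube grid with min separation 8 sigma.
    """
    rng = np.random.default_rng(42)
    sigma = 0.05
    centers = (
        np.array([[i % 3, (i // 3) % 3, i // 9] for i in range(10)], float) / 2.5
        + 0.1
    )
    Xtr, ytr, Xte, yte = [], [], [], []
    for k in range(10):
        pts = centers[k] + sigma * rng.standard_normal((40, 3))
        Xtr.append(pts[:30])
        Xte.append(pts[30:])
        ytr += [f"G{k + 1}"] * 30
        yte += [f"G{k + 1}"] * 10
    Xtr, Xte = np.vstack(Xtr), np.vstack(Xte)
    perm = rng.permutation(len(ytr))
    return Xtr[perm], [ytr[i] for i in perm], Xte, yte, sigma, centers
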