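import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from radkinetics import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_cohort():
    """The study-shaped cohort: 21 patients, 22 ORN + 21 Control VOIs."""
    return synthetic.generate_trajectory_cohort(synthetic.CohortSpec(seed=11))


@pytest.fixture(scope="session")
def shape_cohort():
    """A large cohort whose signal lives only in the month-2 detour."""
    spec = synthetic.CohortSpec(
        n_patients=100,
        n_orn_vois=100,
        n_control_vois=100,
        signal_mode="shape",
        effect_size=1.5,
        noise_sd=0.2,
        seed=1,
    )
    return synthetic.generate_trajectory_cohort(spec)


@pytest.fixture(scope="session")
def fpca_fixture():
    """Curves from a known 2-component expansion: eigenvalues (4, 1), noise 0.1."""
    grid = np.arange(7.0)
    w = synthetic.trapezoid_weights(grid)
    phi1 = np.ones_like(grid)
    phi1 /= np.sqrt(np.sum(w * phi1**2))
    raw = grid - grid.mean()
    raw -= phi1 * np.sum(w * raw * phi1)
    phi2 = raw / np.sqrt(np.sum(w * raw**2))
    phi = np.vstack([phi1, phi2])
    curves, scores = synthetic.generate_curves_from_basis(
        grid, phi, (4.0, 1.0), n=200, noise_sd=0.1, seed=7
    )
    return {"grid": grid, "weights": w, "phi": phi, "curves": curves, "scores": scores}
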