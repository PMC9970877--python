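import warnings

import numpy as np
import pytest

from phaseflux import synthdata

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_population():
    """10 cells, 2 observed cycles, default (study-condition) noise."""
    truth = synthdata.GroundTruth(seed=11)
    return truth, synthdata.simulate_population(truth, n_cells=10, n_cycles=2)


@pytest.fixture(scope="session")
def clean_population():
    """Noise-free small population for geometry/continuity checks."""
    truth = synthdata.GroundTruth(seed=7, noise_channel_frac=0.0, radii_lognorm_sd=0.0)
    return truth, synthdata.simulate_population(truth, n_cells=3, n_cycles=2)


@pytest.fixture(scope="session")
def perturbation_experiment():
    """200-cell two-peak stop-and-respond experiment (CYH-like sign)."""
    truth = synthdata.GroundTruth(seed=2, perturbation_gain=0.05)
    sim = synthdata.simulate_perturbation_experiment(
        truth, 200, t_switch=330.0, lag=6.0, activity="protein", sign=-1
    )
    return sim


def rng(seed=0):
    return np.random.default_rng(seed)
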