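import numpy as np
import pytest
from hypothesis import settings

from vdgradient.synth import (AreaDataset, AreaSpec, generate_trials,
                              simulate_area)

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def trials120():
    return generate_trials(120, seed=5)


@pytest.fixture(scope="session")
def tuned_dataset():
    """A small strongly tuned area spanning the whole trial."""
    trials = generate_trials(200, seed=5)
    area = AreaSpec("toy", 1, 30, 3.0, 250.0)
    spikes, specs = simulate_area(trials, area, seed=5)
    return AreaDataset("toy", 1, trials, spikes, specs, area)


@pytest.fixture(scope="session")
def poisson_dataset(trials120):
    """Homogeneous Poisson control: no tuning, no latent rate."""
    area = AreaSpec("flat", 1, 25, 0.0, 200.0, ou_sigma_frac=0.0,
                    baseline_log_sd=0.0)
    spikes, specs = simulate_area(trials120, area, seed=7)
    return AreaDataset("flat", 1, trials120, spikes, specs, area)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
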