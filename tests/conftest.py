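import numpy as np
import pytest

from hybeco import simulate
from hybeco.genetics import CN, PT


@pytest.fixture(scope="session")
def small_dataset():
    """Moderate synthetic dataset reused by read-only tests."""
    cfg = simulate.SimulationConfig(
        n_cn=40, n_pt=40, n_hybrid=25, n_loci=12, seed=11
    )
    return simulate.gen_individuals(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def flat_k_surface():
    """Species-offset but size/zone-flat K surface (homoscedastic null)."""
    return {
        "base": {CN: 10.5, PT: 9.0},
        "poly": {CN: [0.0, 0.0], PT: [0.0, 0.0]},
        "reference_size": 13.0,
        "k_log_sd": 0.05,
    }


def shared_growth():
    """Identical growth for both species: overlapping size supports."""
    return {
        **simulate.default_growth(),
        "l_inf": {CN: 30.0, PT: 30.0},
        "rate": {CN: 0.3, PT: 0.3},
    }


def syntopic_zones():
    return [z for z in simulate.default_zones() if z["name"] != "reference"]
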