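import numpy as np
import pytest

from cspfret.synthetic_data import (
    PhotonScenario,
    Species,
    make_titration_scenario,
    simulate_photon_stream,
    simulate_titration,
)


@pytest.fixture(scope="session")
def forward_scenario():
    """Default forward titration: Kd 768 uM, nine-residue planted patch."""
    return make_titration_scenario()


@pytest.fixture(scope="session")
def forward_series(forward_scenario):
    return simulate_titration(forward_scenario, seed=11)


@pytest.fixture(scope="session")
def noiseless_series():
    scenario = make_titration_scenario(Kd=500.0, noise_sd=0.0)
    return scenario, simulate_titration(scenario, seed=0)


@pytest.fixture(scope="session")
def short_alex():
    """A brief three-species ALEX measurement with ground-truth labels."""
    scenario = PhotonScenario(
        species=[
            Species("dual", 0.60, 0.70, 0.55),
            Species("donor_only", 0.20, 0.0, 1.0),
            Species("acceptor_only", 0.20, 0.0, 0.0),
        ],
        duration=12.0,
    )
    stream, ann = simulate_photon_stream(scenario, seed=5)
    return scenario, stream, ann
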