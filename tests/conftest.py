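"""Shared fixtures: the default model, a reduced two-entity model with a
closed-form solution, simulated trajectories and synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from tnfnet import (
    assemble_odes,
    build_network,
    default_protocols,
    run_protocol,
    steady_state,
)
from tnfnet.flux import edge_fluxes
from tnfnet.params import ParameterSet, default_truth
from tnfnet.synth import DEFAULT_TIME_GRID, NoiseModel, generate_dataset


@pytest.fixture(scope="session")
def net():
    return build_network()


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def system(net, truth):
    return assemble_odes(net, truth)


@pytest.fixture(scope="session")
def rest_state(system):
    return steady_state(system)


@pytest.fixture(scope="session")
def grid12():
    return np.asarray(DEFAULT_TIME_GRID)


@pytest.fixture(scope="session")
def trajectories(system, rest_state, grid12):
    return {
        label: run_protocol(system, proto, grid12, y0=rest_state)
        for label, proto in default_protocols().items()
    }


@pytest.fixture(scope="session")
def dense_trajectories(system, rest_state):
    grid = np.linspace(0.0, 24.0, 97)
    return {
        label: run_protocol(system, proto, grid, y0=rest_state)
        for label, proto in default_protocols().items()
    }


@pytest.fixture(scope="session")
def fluxes(system, dense_trajectories):
    return {label: edge_fluxes(system, t) for label, t in dense_trajectories.items()}


@pytest.fixture(scope="session")
def dataset_noisy(system):
    return generate_dataset(system, noise=NoiseModel(c_rel=0.10, seed=1))


@pytest.fixture(scope="session")
def dataset_noiseless(system):
    return generate_dataset(system, noise=NoiseModel(c_rel=0.0, seed=0), augment=False)


# -- reduced two-entity model with an analytic solution ---------------------

REDUCED_CONFIG = {
    "entities": ["A", "B"],
    "edges": [
        {"source": "A", "target": "B", "sign": "activation",
         "rate_law": "mass_action", "params": ["k_A_B"]},
    ],
    "inputs": [
        {"name": "TNFa", "target": "A", "sign": "activation",
         "param": "k_stim_tnfa", "dose_unit": "ng/ml"},
    ],
    "markers": {"B": ["B", "s_B"]},
}

REDUCED_TRUTH = ParameterSet(
    {
        "k_act_A": 0.3, "k_inact_A": 0.7,
        "k_act_B": 0.1, "k_inact_B": 0.9,
        "k_A_B": 1.5,
        "k_stim_tnfa": 0.02,
        "s_B": 2.0,
    },
    id="reduced-truth",
)


@pytest.fixture(scope="session")
def reduced_net():
    return build_network(REDUCED_CONFIG)


@pytest.fixture(scope="session")
def reduced_truth():
    return ParameterSet(dict(REDUCED_TRUTH), id="reduced-truth")


@pytest.fixture(scope="session")
def reduced_system(reduced_net, reduced_truth):
    return assemble_odes(reduced_net, reduced_truth)
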