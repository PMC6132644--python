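import numpy as np
import pytest

import bidcm
from bidcm.model_space import enumerate_models
from bidcm.paradigm import DesignConfig
from bidcm.synthetic import default_group_params


@pytest.fixture(scope="session")
def space():
    return enumerate_models()


@pytest.fixture(scope="session")
def design():
    """Full-size task design (study geometry: 16 trials, TR 1.79 s)."""
    return bidcm.build_design(seed=3)


@pytest.fixture(scope="session")
def inputs(design):
    return bidcm.design_to_inputs(design)


@pytest.fixture(scope="session")
def mini_design():
    """Compact design for fast fitting tests: one block of four trials,
    shorter probe trains."""
    cfg = DesignConfig(trials_per_condition=1, n_probes=5, iti=3.58)
    return bidcm.build_design(seed=5, config=cfg)


@pytest.fixture(scope="session")
def mini_inputs(mini_design):
    return bidcm.design_to_inputs(mini_design)


@pytest.fixture(scope="session")
def winner_structure(space):
    return space.model(space.winner_model_id)


@pytest.fixture(scope="session")
def winner_params(winner_structure):
    return default_group_params(winner_structure)


def simulate_noisy(params, inp, structure, snr, seed):
    """One noisy record at the given SNR from known parameters."""
    rec = bidcm.simulate_bold(params, inp, structure=structure,
                              subject_id=f"sub-{seed}")
    lam = -2.0 * np.log(rec.y.std(axis=0) / snr)
    return bidcm.add_noise(rec, lam, rho=0.2, seed=seed), rec
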