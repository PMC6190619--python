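import numpy as np
import pytest

import extrasurv as xs


@pytest.fixture(scope="session")
def scenario():
    """One default synthetic study shared across tests."""
    trial, evidence, truth = xs.generate_scenario(seed=20240)
    return trial, evidence, truth


@pytest.fixture(scope="session")
def trial(scenario):
    return scenario[0]


@pytest.fixture(scope="session")
def evidence(scenario):
    return scenario[1]


@pytest.fixture(scope="session")
def truth(scenario):
    return scenario[2]


@pytest.fixture(scope="session")
def spline_model(trial):
    knots, knots_trt = xs.place_knots(5.0, 40.0, trial.time[trial.event == 1])
    return xs.SplineTwoArmModel(knots, knots_trt)


@pytest.fixture(scope="session")
def exp_ph_draws(trial):
    """A small, converged exponential-PH trial-only posterior reused by several tests."""
    model = xs.build_two_arm_model("exponential", "PH")
    draws = xs.sample_posterior(model, trial, seed=11, n_walkers=16, n_steps=1500)
    return model, draws
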