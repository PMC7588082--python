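import pytest

import socialhgf as sh


@pytest.fixture(scope="session")
def schedule():
    return sh.build_schedule()


@pytest.fixture(scope="session")
def schedule_incongruent():
    return sh.build_schedule(variant="incongruent_first")


@pytest.fixture(scope="session")
def experiment(schedule):
    return sh.generate_experiment(schedule, seed=101)


@pytest.fixture(scope="session")
def hgf_native_params():
    """A behaviorally sane full parameter set for the winning model, native space."""
    return {
        "omega2_card": -3.0,
        "omega2_gaze": -3.0,
        "omega3_card": -6.0,
        "omega3_gaze": -6.0,
        "zeta": 1.5,
        "beta": 7.0,
        "eta": 0.6,
    }


@pytest.fixture(scope="session")
def hgf_agent(experiment, hgf_native_params):
    spec = sh.ModelSpec("hgf", 1)
    responses, info = sh.simulate_agent(experiment, hgf_native_params, spec, seed=202)
    return spec, responses, info
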