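import numpy as np
import pytest

from vwmbind import taskgen


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def exp1_dataset():
    """One participant's location-cue experiment with spatial-model responses."""
    rng = np.random.default_rng(100)
    ds = taskgen.generate_experiment(taskgen.exp1_design(), rng)
    return taskgen.simulate_responses_popmodel(
        ds, taskgen.DEFAULT_POPULATION_PARAMS, "spatial", rng
    )


@pytest.fixture(scope="session")
def exp2_dataset():
    """One participant's orientation-cue experiment with spatial-model responses."""
    rng = np.random.default_rng(101)
    ds = taskgen.generate_experiment(taskgen.exp2_design(), rng)
    return taskgen.simulate_responses_popmodel(
        ds, taskgen.DEFAULT_POPULATION_PARAMS, "spatial", rng
    )


@pytest.fixture(scope="session")
def mixture_dataset():
    """5000 trials from a known joint mixture ground truth."""
    rng = np.random.default_rng(102)
    design = taskgen.exp1_design(n_trials=5000, trials_per_block=50)
    ds = taskgen.generate_experiment(design, rng)
    truth = taskgen.MixtureGroundTruth(
        8.0, 8.0, {"TT": 0.3, "TU": 0.3, "UT": 0.2, "UU": 0.2}
    )
    return taskgen.simulate_responses_mixture(ds, truth, rng), truth
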