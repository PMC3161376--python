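import pytest

from tidi.antid import antid_model
from tidi.engine import RunOptions, run_model
from tidi.synthetic import TrialSimSpec, gen_elicitations, gen_trials

BIAS_DESCRIPTORS = [
    ("randomisation", "internal", "additive", 0.05, 0.01),
    ("blinding", "internal", "additive", 0.10, 0.02),
    ("population_relevance", "external", "proportional", 0.90, 0.02),
]


@pytest.fixture(scope="session")
def trial_studies():
    """Eight simulated trials with a true OR of 0.4 and mild heterogeneity."""
    return gen_trials(TrialSimSpec(k=8, seed=42))


@pytest.fixture(scope="session")
def elicitations(trial_studies):
    return gen_elicitations(
        [s.id for s in trial_studies],
        BIAS_DESCRIPTORS,
        n_assessors=3,
        assessor_sd=0.03,
        seed=7,
    )


@pytest.fixture(scope="session")
def model():
    return antid_model()


@pytest.fixture(scope="session")
def stochastic_psa(model):
    """Moderate-size PSA of the fixture model, shared across tests."""
    return run_model(model, RunOptions(mode="stochastic", n_sims=500, seed=3))


@pytest.fixture(scope="session")
def deterministic_psa(model):
    return run_model(model, RunOptions(mode="deterministic"))
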