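"""Shared fixtures: one synthetic study and its pipeline run per session."""

import pytest

from pausetrack import SimParams, run_pipeline, simulate_study

STUDY_SEED = 7


@pytest.fixture(scope="session")
def params():
    return SimParams(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study(params):
    """Default-noise synthetic study (n=2000 genes, fixed seed)."""
    return simulate_study(params)


@pytest.fixture(scope="session")
def result(study):
    """Full pipeline run on the default-noise study."""
    return run_pipeline(study.chip, study.expression)


@pytest.fixture(scope="session")
def noiseless_study(params):
    return simulate_study(params.zero_noise())


@pytest.fixture(scope="session")
def noiseless_result(noiseless_study):
    return run_pipeline(noiseless_study.chip, noiseless_study.expression)
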