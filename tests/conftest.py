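import dataclasses

import pytest

from seirb.model_core import (
    BehaviorParams,
    DiseaseParams,
    NoiseParams,
    ParameterSet,
    simulate,
)
from seirb.synthetic_data import generate


@pytest.fixture(scope="session")
def truth():
    """Default ground-truth parameterization."""
    return ParameterSet()


@pytest.fixture(scope="session")
def truth_noise_free(truth):
    return ParameterSet(
        disease=truth.disease,
        behavior=truth.behavior,
        noise=dataclasses.replace(truth.noise, enabled=False),
    )


@pytest.fixture(scope="session")
def det_trajectory(truth):
    """Deterministic SEIRb reference run over the full study horizon."""
    return simulate(truth.disease, truth.behavior, horizon=730)


@pytest.fixture(scope="session")
def det_dataset(truth_noise_free):
    """Single noise-free replicate: the deterministic reference corpus."""
    return generate(truth_noise_free, n_reps=1, horizon=730, base_seed=0)


@pytest.fixture(scope="session")
def small_dataset(truth):
    """Small stochastic corpus for structural tests (not power-hungry stats)."""
    return generate(truth, n_reps=8, horizon=730, base_seed=0)
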