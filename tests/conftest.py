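import numpy as np
import pytest

from acebeta.biometric import ModelSpec, ParameterSet, parameter_universe
from acebeta.synthetic import GeneratorConfig, simulate_pairs, simulate_raw_survey


def full_trivariate_spec(**kwargs) -> ModelSpec:
    """Spec with the whole trivariate parameter universe free."""
    return ModelSpec(
        "full", ("iq", "grades", "exp"), parameter_universe(("iq", "grades", "exp")),
        **kwargs,
    )


def theta_for(spec: ModelSpec, mapping) -> ParameterSet:
    return ParameterSet.from_dict(spec, mapping, strict=False)


@pytest.fixture(scope="session")
def latent_cohort():
    """Medium latent cohort with default (published-model) parameters."""
    return simulate_pairs(GeneratorConfig(n_pairs=800, seed=42))


@pytest.fixture(scope="session")
def complete_cohort():
    """Complete-data cohort (no missingness), useful for exact oracles."""
    return simulate_pairs(GeneratorConfig(n_pairs=500, seed=7, missing_rates={}))


@pytest.fixture(scope="session")
def raw_table():
    return simulate_raw_survey(GeneratorConfig(n_pairs=250, seed=11, raw_survey=True))


@pytest.fixture()
def rng():
    return np.random.default_rng(20230824)
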