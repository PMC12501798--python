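import warnings

import pytest

from seedpe.simulate import GeneratorConfig, generate_experiment
from seedpe.traits import build_trait_table


@pytest.fixture(scope="session")
def default_experiment():
    """One default synthetic experiment (500 samples), shared across tests."""
    samples, counts = generate_experiment(GeneratorConfig(), seed=11)
    return samples, counts


@pytest.fixture(scope="session")
def trait_table(default_experiment):
    samples, counts = default_experiment
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_trait_table(samples, counts).frame
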