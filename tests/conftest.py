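import pytest

from mcqsar import GeneratorConfig, dataset_profiles, generate_library, load_flavonols


@pytest.fixture(scope="session")
def flavonols():
    return load_flavonols()


@pytest.fixture(scope="session")
def flavonol_profiles(flavonols):
    return dataset_profiles(flavonols)


@pytest.fixture(scope="session")
def tiny_library():
    """Small noisy synthetic library for optimizer-level tests."""
    return generate_library(GeneratorConfig(n_molecules=30, seed=7))
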