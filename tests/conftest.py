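import pytest

from ceemod import GeneratorConfig, generate_cohort, load_default_parameters


@pytest.fixture(scope="session")
def params():
    return load_default_parameters()


@pytest.fixture(scope="session")
def default_cohort(params):
    """One synthetic cohort at the study size (n = 3787)."""
    return generate_cohort(GeneratorConfig.from_parameters(params, seed=20240502))


@pytest.fixture(scope="session")
def big_cohort(params):
    """Large cohort for convergence checks."""
    cfg = GeneratorConfig.from_parameters(
        params, seed=7, n_intervention=25_000, n_control=25_000)
    return generate_cohort(cfg)
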