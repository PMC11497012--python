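import pytest

from idmproj.synthetic import GeneratorConfig, make_truth, observe


@pytest.fixture(scope="session")
def constant_config():
    """One-key generator with time-constant transition probabilities."""
    return GeneratorConfig(
        n_locations=1, sexes=("both",), year_start=1990, year_end=2019,
        mode="constant", seed=7,
    )


@pytest.fixture(scope="session")
def constant_truth(constant_config):
    return make_truth(constant_config)


@pytest.fixture(scope="session")
def noisefree_panel(constant_truth):
    return observe(constant_truth, noise_cv=0.0)


@pytest.fixture(scope="session")
def multikey_panel():
    """Noise-free two-location, two-sex panel with log-linear trends."""
    cfg = GeneratorConfig(
        n_locations=2, sexes=("male", "female"), year_start=1990, year_end=2019,
        mode="loglinear", seed=11,
    )
    return observe(make_truth(cfg), noise_cv=0.0)
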