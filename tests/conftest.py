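import numpy as np
import pytest

from shrubcasa import synth


@pytest.fixture(scope="session")
def noise_free_spec():
    """Generator spec with every noise source silenced."""
    return synth.SynthSpec(
        temp_noise=0.0, precip_noise=0.0, solar_noise=0.0, ndvi_noise=0.0,
        plant_cv=0.0, biomass_sample_sigma=0.0, noise_herb=0.0,
        noise_litter=0.0, noise_soil_bd=0.0, noise_soil_soc=0.0,
    )


@pytest.fixture(scope="session")
def noise_free_survey(noise_free_spec):
    return synth.generate_plot_survey(noise_free_spec)


@pytest.fixture(scope="session")
def default_survey():
    return synth.generate_plot_survey(synth.SynthSpec(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
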