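import numpy as np
import pytest

from phenoflux import synthetic
from phenoflux.synthetic import SiteConfig


@pytest.fixture
def site():
    return SiteConfig("TST1", 48.0, 8.0, 5, 2000, "Fagus")


@pytest.fixture
def quiet_temp(site):
    """Noise-free temperature series for the test site."""
    return synthetic.generate_temperature(site, noise_sd=0.0, seed=0)


@pytest.fixture
def quiet_truth(site, quiet_temp):
    """Phenology truth with no imposed effect and no noise: SOS = 120."""
    return synthetic.generate_phenology_truth(
        site, quiet_temp, base_sos=120.0, true_st=0.0, sos_noise_sd=0.0,
        seed=0)


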