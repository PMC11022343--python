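import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from strainlink.config import DesignConfig, StrainProfile, default_strain_profiles


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def full_design():
    """The full two-species factorial design."""
    return DesignConfig()


@pytest.fixture
def small_design():
    """One species, two strains — fast end-to-end runs."""
    return DesignConfig(
        species=("Tetrahymena",),
        strains_per_species=2,
        temperatures=(20.0, 24.0),
        pollutant_levels=(0.0, 20.0),
        dilution_fractions=(0.2, 0.5, 0.8),
        replicates=2,
    )


@pytest.fixture
def profiles(full_design):
    return default_strain_profiles(full_design)


@pytest.fixture
def tetra_profile(profiles):
    return profiles["Tetrahymena-S2"]


@pytest.fixture
def flat_profile():
    """No treatment responses, no drift — pure baseline draws."""
    return StrainProfile(
        strain_id="flat",
        species="Test",
        base_mu=1.0,
        base_alpha=-2e-4,
        mu_response=(0.0, 0.0),
        trait_means=(50.0, 0.8, 200.0, 2.0),
        trait_sd=(10.0, 0.05, 40.0, 0.2),
    )
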