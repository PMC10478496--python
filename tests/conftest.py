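import numpy as np
import pytest

from microhab.data_model import HabitatCategory
from microhab.inference import GroupAssignment, MCMCConfig
from microhab.synthetic import generate_habitat_dataset, preset_scenario
from microhab.zoib import GammaMode, ZOIBParams, zoib_sample


@pytest.fixture
def single_group_assignment():
    """Group assignment putting n observations into one group."""

    def make(n: int) -> GroupAssignment:
        return GroupAssignment(
            mean_names=["all"],
            phi_names=["all"],
            mean_idx=np.zeros(n, dtype=np.intp),
            phi_idx=np.zeros(n, dtype=np.intp),
            mean_to_phi=np.zeros(1, dtype=np.intp),
        )

    return make


@pytest.fixture
def zoib_fixture_values():
    """n=50 draws from alpha=0.3, mu=0.6, phi=8 with gamma pinned at 0."""
    params = ZOIBParams(alpha=0.3, gamma=0.0, mu=0.6, phi=8.0,
                        gamma_fixed=GammaMode.FIXED_ZERO)
    return zoib_sample(50, params, seed=42), params


@pytest.fixture
def grass_observations():
    """Simulated used-vs-available grass proportions (mu 0.55 vs 0.70)."""
    return generate_habitat_dataset(preset_scenario("grass-lizard", seed=7))


@pytest.fixture
def fast_mcmc():
    """A short sampler configuration for tests where speed matters more than
    Monte-Carlo error."""
    return MCMCConfig(chains=2, iterations=3000, burn_in=1000, seed=11)
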