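import numpy as np
import pytest

from phylomorph import SimulationConfig, match_and_prune
from phylomorph.synthetic_data import simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    # few factor levels so the 3-term model stays estimable at n=24
    return SimulationConfig(
        n_taxa=24,
        n_landmarks=12,
        n_modules=3,
        habitat_levels=("terrestrial", "arboreal", "aquatic", "semi-fossorial"),
        diet_categories=("amphibians", "fish", "mollusks", "annelids", "mammals"),
        habitat_jump_rate=8.0,
        diet_habitat_link=0.5,
        diet_alpha_base=0.8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(tree, ecology, landmarks) for a 24-taxon BM fixture."""
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def matched(small_dataset):
    phy, eco, lm = small_dataset
    return match_and_prune(lm, eco, phy)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
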