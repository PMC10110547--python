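import logging
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from tropicalize import default_scenario, generate_metacommunity
from tropicalize.grouping import FunctionalGrouping

# statsmodels mixed models emit convergence chatter on tiny zones; the
# fallback behaviour itself is asserted explicitly where it matters.
warnings.filterwarnings("ignore", module="statsmodels")
logging.getLogger("tropicalize").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_scenario():
    """Reduced default scenario: full species pool, 12 sites per region."""
    return default_scenario(seed=11, n_sites=12)


@pytest.fixture(scope="session")
def small_world(small_scenario):
    """(survey, traits, truth) for the reduced scenario, generated once."""
    return generate_metacommunity(small_scenario)


@pytest.fixture(scope="session")
def true_grouping(small_world):
    """Ground-truth species->group assignment as a FunctionalGrouping."""
    _, _, truth = small_world
    sg = pd.Series(truth.species_group).rename("group")
    sg.index.name = "species"
    return FunctionalGrouping(sg, k=9)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def tiny_traits(rows: list[dict]) -> pd.DataFrame:
    """Build a minimal valid trait table from per-species dicts."""
    base = dict(diet="predator", habitat_association="benthic", body_size=30.0,
                aggregation=2, depth_range=20.0, thermal_guild="tropical")
    out = []
    for i, r in enumerate(rows):
        d = dict(base, species=f"s{i + 1}", **r)
        out.append(d)
    return pd.DataFrame(out)
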