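import numpy as np
import pytest

import lipidgrs as lg
from lipidgrs import reference


@pytest.fixture(scope="session")
def panel():
    return reference.variant_panel()


@pytest.fixture(scope="session")
def published():
    return reference.published_associations()


@pytest.fixture(scope="session")
def summaries():
    return reference.trait_summaries()


@pytest.fixture(scope="session")
def study_cohort():
    """One full-size synthetic cohort under the default (published) effects."""
    G, ct, pan = lg.simulate_cohort(seed=20240129)
    return G, ct, pan


@pytest.fixture(scope="session")
def study_associations(study_cohort):
    G, ct, pan = study_cohort
    return lg.run_panel(G, ct, pan)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
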