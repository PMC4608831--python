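"""Shared fixtures: the stimulus battery and surrogate ELL input.

Session-scoped because stimulus synthesis and PSTH generation are
deterministic given the fixed study-condition seed, and several modules
test against the same battery.
"""

import numpy as np
import pytest

from chirpinv.stimgen import standard_chirp_stimuli
from chirpinv.synthetic_ell import generate_population_psths

#: Fixed seed defining the packaged synthetic study conditions.
ELL_SEED = 1


@pytest.fixture(scope="session")
def stimuli():
    return standard_chirp_stimuli()


@pytest.fixture(scope="session")
def psth_pairs(stimuli):
    return generate_population_psths(stimuli, seed=ELL_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
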