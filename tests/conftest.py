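import numpy as np
import pytest

from daneuron import BioParams, MinimalParams
from daneuron.sweeps import frequency_map, synergy_report


@pytest.fixture(scope="session")
def minimal_params():
    return MinimalParams()


@pytest.fixture(scope="session")
def bio_params():
    return BioParams()


@pytest.fixture(scope="session")
def minimal_map(minimal_params):
    """Full minimal-model frequency map on the standard sweep grids."""
    ga = np.round(np.arange(0, 31) * 0.002, 10)
    gn = np.round(np.arange(0, 61) * 0.02, 10)
    return frequency_map("minimal", minimal_params, ga, gn)


@pytest.fixture(scope="session")
def minimal_synergy(minimal_map, minimal_params):
    return synergy_report(minimal_map, params=minimal_params, refine=True)


@pytest.fixture(scope="session")
def bio_map(bio_params):
    """Biophysical frequency map on a thinned version of the standard grid."""
    ga = np.round(np.arange(0, 11) * 0.04, 10)
    gn = np.round(np.arange(0, 25) * 0.5, 10)
    return frequency_map("biophysical", bio_params, ga, gn)
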