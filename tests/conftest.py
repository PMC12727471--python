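import numpy as np
import pytest

from lfnmr.library import load_metabolite_library
from lfnmr.spinsim import simulate_mixture
from lfnmr.types import MIXED_SAMPLE, make_axis


@pytest.fixture(scope="session")
def library():
    return load_metabolite_library()


@pytest.fixture(scope="session")
def axis():
    """Full canonical acquisition axis (10 to -2.5 ppm)."""
    return make_axis()


@pytest.fixture(scope="session")
def mixed_sim(axis):
    """Noiseless 80-MHz simulation of the reference mixed sample
    (glucose 10, lactate 2, citrate 0.2 mmol/L, TSP 0.1 mmol/L)."""
    return simulate_mixture(MIXED_SAMPLE, axis, linewidth=1.0,
                            spectrometer_freq=80.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251002)
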