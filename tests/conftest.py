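import numpy as np
import pytest

from burstlab.mp import build_stochastic_dictionary
from burstlab.synthetic import generate_background, simulate_lfp

FS = 250.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def small_trialset():
    """Calibrated synthetic set: 8 trials, one 400-ms burst each, 14x gamma ratio."""
    trialset, record, scale = simulate_lfp(8, 0.4, gamma_ratio=14.0, rng_seed=101)
    return trialset, record, scale


@pytest.fixture(scope="session")
def noise_trialset():
    """Pure 1/f^2 background, same geometry as the synthetic trials."""
    return generate_background(8, 4.0, FS, alpha=2.0, rng_seed=202)


@pytest.fixture(scope="session")
def tiny_dictionary():
    """2,000-atom dictionary on a 4-s, 250-Hz grid (t0 at mid-trial)."""
    n = 1000
    return build_stochastic_dictionary(2000, n, FS, rng_seed=303, t0_index=n // 2)
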