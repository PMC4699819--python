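import numpy as np
import pytest

import ppiirh


@pytest.fixture(scope="session")
def coil_ensemble_25():
    """Unbiased N=25 ensemble shared across simulator-level tests."""
    return ppiirh.simulate_ensemble(25, 0.0, rng_seed=101, min_accepted=3000)


@pytest.fixture(scope="session")
def synthetic_dataset():
    records, observed = ppiirh.synthetic_idp_dataset(7)
    return records, observed


@pytest.fixture(scope="session")
def builtin_scales():
    return {name: ppiirh.load_builtin_scale(name) for name in ppiirh.BUILTIN_SCALE_NAMES}
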