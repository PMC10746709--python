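import numpy as np
import pytest

from marshcarbon import synthdata


@pytest.fixture()
def rng():
    return np.random.default_rng(20160115)


@pytest.fixture(scope="session")
def synthetic_study():
    """One small coherent synthetic study shared by I/O and pipeline tests."""
    return synthdata.simulate_study(seed=7, n_sites=3, plots_per_site=5)
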