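import numpy as np
import pytest

import hicomp as h


@pytest.fixture(scope="session")
def truth_500():
    """One 500-bin chromosome at 100 kb with default planted architecture."""
    return h.plant_architecture({"chr1": 500}, 100_000, seed=7)


@pytest.fixture(scope="session")
def params_1m():
    return h.SimulationParams(depth=1e6)


@pytest.fixture(scope="session")
def maps_500(truth_500, params_1m):
    """Raw replicate maps: condition 1 (two replicates) and condition 2."""
    c1a = h.simulate_contact_map(truth_500, params_1m, 1, 11)["chr1"]
    c1b = h.simulate_contact_map(truth_500, params_1m, 1, 12)["chr1"]
    c2 = h.simulate_contact_map(truth_500, params_1m, 2, 13)["chr1"]
    return c1a, c1b, c2


def random_symmetric(rng, n, scale=10.0):
    m = rng.uniform(0, scale, size=(n, n))
    m = np.triu(m, 1)
    return m + m.T
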