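import numpy as np
import pytest

from dermroute.routing import CLASSES, OVA_NAMES, OVO_NAMES
from dermroute.synthetic import MockProfile, mock_bundle


def random_mock_bundle(rng: np.random.Generator, seed: int):
    """A bundle of seven mocks with random Dirichlet output profiles."""
    profiles = {}
    profiles["s3"] = MockProfile(
        {c: rng.uniform(0.5, 20.0, 3) for c in CLASSES}
    )
    for c, name in OVA_NAMES.items():
        profiles[name] = MockProfile({t: rng.uniform(0.5, 20.0, 2) for t in CLASSES})
    for pair, name in OVO_NAMES.items():
        profiles[name] = MockProfile({t: rng.uniform(0.5, 20.0, 2) for t in CLASSES})
    return mock_bundle(profiles, seed=seed)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180417)
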