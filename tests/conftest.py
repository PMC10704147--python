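import numpy as np
import pytest

from leakysnn.event_io import bundle_dataset
from leakysnn.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def temporal_bundles():
    """Desk-scale timing-coded dataset, binned (train, test)."""
    tr, te = generate(SyntheticSpec(structure="temporal", seed=11))
    return bundle_dataset(tr), bundle_dataset(te)


@pytest.fixture(scope="session")
def spatial_bundles():
    """Desk-scale rate-coded dataset, binned (train, test)."""
    tr, te = generate(SyntheticSpec(structure="spatial", seed=11))
    return bundle_dataset(tr), bundle_dataset(te)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
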