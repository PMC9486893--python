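import numpy as np
import pytest

from allostate.numbering import load_reference
from allostate.synthetic_data import EnsembleSpec, make_ensemble, reference_ensemble


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def default_spec():
    return EnsembleSpec(seed=11, n_frames=300)


@pytest.fixture(scope="session")
def ensemble_and_truth(default_spec):
    return make_ensemble(default_spec)


@pytest.fixture(scope="session")
def ref_ensemble(default_spec):
    return reference_ensemble(default_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
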