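import numpy as np
import pytest

from tunnelfold.conformer import PeptideSequence, build_conformer
from tunnelfold.synthetics import EnsembleSpec, make_test_sequences, make_tunnel


@pytest.fixture(scope="session")
def tm_sequence():
    return make_test_sequences("tm", seed=1)


@pytest.fixture(scope="session")
def soluble_sequence():
    return make_test_sequences("soluble", seed=1)


@pytest.fixture(scope="session")
def poly_ala_20():
    return PeptideSequence.from_string("A" * 20, id="polyA20")


@pytest.fixture(scope="session")
def helical_tm(tm_sequence):
    return build_conformer(tm_sequence, "helical")


@pytest.fixture(scope="session")
def extended_tm(tm_sequence):
    return build_conformer(tm_sequence, "extended")


@pytest.fixture(scope="session")
def default_tunnel():
    return make_tunnel(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_ensemble_spec():
    return EnsembleSpec(n_frames=4, seed=7)
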