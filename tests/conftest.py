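import numpy as np
import pytest

from glylstm.peptide_io import PeptideRecord
from glylstm.properties import load_builtin_property_set
from glylstm.rnn_model import ModelConfig
from glylstm.synthetic_data import SyntheticConfig, generate_null


@pytest.fixture(scope="session")
def pset():
    return load_builtin_property_set()


@pytest.fixture(scope="session")
def poly_a_record():
    return PeptideRecord(id="polyA", sequence="A" * 15 + "K" + "A" * 15, label=0)


@pytest.fixture(scope="session")
def null_records():
    """200 balanced label-independent records."""
    return generate_null(SyntheticConfig(n=200, seed=11))


def window(seq31: str, label=0, rid="w"):
    return PeptideRecord(id=rid, sequence=seq31, label=label)


@pytest.fixture(scope="session")
def random_records():
    """60 random labeled windows for encoding spot checks."""
    return generate_null(SyntheticConfig(n=60, seed=5))


@pytest.fixture
def tiny_model_config():
    """A scaled-down network for structural/protocol tests."""
    return ModelConfig(input_width=2, lstm1_units=8, lstm2_units=6,
                       dense_units=4, max_epochs=2, patience=2,
                       batch_size=32, seed=0)
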