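import numpy as np
import pytest

from dynallo.dataio import BiomassRecord, DataSet
from dynallo.synthetic_data import SynthConfig, generate_fixed


def make_record(i, leaf, stem, root, species="sp", family="fam", **kw):
    return BiomassRecord(
        record_id=f"r{i}",
        species=species,
        family=family,
        leaf_mass=leaf,
        stem_mass=stem,
        root_mass=root,
        **kw,
    )


@pytest.fixture
def toy_dataset():
    """Three records with easy totals: 6, 60, 1.0 g."""
    return DataSet(
        [
            make_record(1, 1.0, 2.0, 3.0, species="A"),
            make_record(2, 10.0, 20.0, 30.0, species="A"),
            make_record(3, 0.5, 0.1, 0.4, species="B"),
        ]
    )


@pytest.fixture
def fixed_dataset():
    """Moderate-size fixed-exponent dataset shared by several tests."""
    return generate_fixed(SynthConfig(n_records=2000, seed=42, noise_sd=0.15))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
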