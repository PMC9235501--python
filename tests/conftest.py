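import sys
import pathlib

import numpy as np
import pytest

sys.path.insert(0, str(pathlib.Path(__file__).parent))

from ontoball.synthetic import SyntheticSpec, simulate


@pytest.fixture(scope="session")
def default_fixture():
    """The standard synthetic study: 60 classes, 300 proteins."""
    return simulate(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def tiny_fixture():
    """A fast fixture for training-loop mechanics."""
    spec = SyntheticSpec(n_classes=24, n_definitions=3, n_existential=3,
                         n_proteins=80, vocab_size=80, seed=7)
    return simulate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def records_for(fixture, part="test"):
    """Helper: ProteinRecords of one split part with true labels."""
    from ontoball.model import ProteinRecord
    ds = fixture.dataset
    ann = ds.propagated()
    index = {p: i for i, p in enumerate(ds.protein_ids)}
    ids = ds.protein_ids if part == "all" else ds.ids_in(part)
    return [ProteinRecord(p, ds.features[index[p]],
                          set(ann.annotations.get(p, ())))
            for p in ids]
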