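import numpy as np
import pytest

from maosel.dataset import CompoundRecord, classify_selectivity
from maosel.synthetic import generate_dataset


def make_record(cid="c1", smiles="c1ccccc1", pic50=7.0, si=None, cls=None):
    """Record with prescribed pIC50 (and optionally SI) from exact IC50s."""
    ic50_b = 10.0 ** (-pic50)
    rec = CompoundRecord(
        id=cid, smiles=smiles, ic50_b=ic50_b, ic50_a=si * ic50_b if si is not None else None
    )
    if cls is not None:
        rec.selectivity_class = cls
    return rec


@pytest.fixture(scope="session")
def synthetic_126():
    """Reference-shaped synthetic dataset: 126 compounds, 34 selective."""
    records, ground_truth = generate_dataset(n=126, selective_fraction=34 / 126, seed=20)
    return classify_selectivity(records), ground_truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
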