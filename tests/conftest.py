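import numpy as np
import pytest

from pvsignal.core import DrugEventTable, Hierarchy


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tree():
    """3 SOCs over 7 PTs with uneven fan-out."""
    parent = {
        "100.0001": "100", "100.0002": "100", "100.0003": "100",
        "200.0004": "200", "200.0005": "200",
        "300.0006": "300", "300.0007": "300",
    }
    return Hierarchy(
        soc_ids=("100", "200", "300"),
        pt_ids=tuple(sorted(parent)),
        parent=parent,
    )


@pytest.fixture
def random_table(rng, small_tree):
    counts = rng.integers(0, 40, size=(7, 5))
    return DrugEventTable(
        counts,
        ae_ids=small_tree.pt_ids,
        drug_ids=[f"d{j}" for j in range(5)],
    )
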