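import numpy as np
import pytest

import erptopo as et
from erptopo.core import ErpDataset, average_reference


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset(rng):
    """4 subjects x 2 conditions x 5 timepoints x 6 channels of noise."""
    data = average_reference(rng.standard_normal((4, 2, 5, 6)))
    return ErpDataset(data, ("s1", "s2", "s3", "s4"), ("A", "B"),
                      dt=4.0, is_average_referenced=True)


@pytest.fixture
def two_by_two_design():
    """The canonical 2x2 within design: expectancy x day over C1,C2,F1,F2."""
    return et.define_design(
        {"expectancy": {"C1": 1, "C2": 1, "F1": 2, "F2": 2},
         "day": {"C1": 1, "F1": 1, "C2": 2, "F2": 2}},
        ("C1", "C2", "F1", "F2"))


@pytest.fixture
def dataset_2x2(rng):
    data = average_reference(rng.standard_normal((6, 4, 8, 10)))
    return ErpDataset(data, tuple(f"s{i}" for i in range(6)),
                      ("C1", "C2", "F1", "F2"), dt=4.0,
                      is_average_referenced=True)
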