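import numpy as np
import pytest

from crcal import CompetingRiskDataset


@pytest.fixture
def four_record_censoring():
    """Times (1,2,3,4), status (1,0,2,0): one primary, one competing, two censored."""
    return CompetingRiskDataset(np.arange(4), [1.0, 2.0, 3.0, 4.0], [1, 0, 2, 0])


@pytest.fixture
def three_record():
    """Times (1,2,3), status (1,2,1): no censoring."""
    return CompetingRiskDataset(np.arange(3), [1.0, 2.0, 3.0], [1, 2, 1])


@pytest.fixture
def four_record_expansion():
    """Times (1,2,3,4), status (1,2,0,1): the weighted-expansion example."""
    return CompetingRiskDataset(np.arange(4), [1.0, 2.0, 3.0, 4.0], [1, 2, 0, 1])
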