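import numpy as np
import pytest

from imv import generate_two_coin_fixture


@pytest.fixture(scope="session")
def toy():
    """Canonical two-coin dataset: 20 fair tosses (14 heads) then 20
    weighted tosses (19 heads); constant 0.55 baseline, blockwise 0.5/0.9
    enhanced prediction."""
    return generate_two_coin_fixture(fixed_counts=(14, 19))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
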