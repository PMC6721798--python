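import numpy as np
import pytest

from ftlrep.occupancy import ConstructReadouts


@pytest.fixture
def paper_readouts() -> ConstructReadouts:
    """The published normalized luciferase readouts (mean, SD, n)."""
    return ConstructReadouts.from_means(
        {
            "FTL": (1.0, 0.0, 6),
            "D3RE": (4.4, 0.4, 6),
            "LOOP": (12.5, 2.9, 6),
            "DOUBLE": (41.8, 6.5, 6),
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20190815)
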