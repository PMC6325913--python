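import pandas as pd
import pytest

from memscreen.pipeline import _default_planted
from memscreen.simulate import reference_ground_truth, simulate_screen


@pytest.fixture(scope="session")
def planted_200():
    """Default planted-class layout: 20 positive / 20 negative / 20 variable / 140 background."""
    return _default_planted()


@pytest.fixture(scope="session")
def reference_truth():
    return reference_ground_truth()


@pytest.fixture(scope="session")
def reference_counts(reference_truth) -> pd.DataFrame:
    """One simulated screen from the packaged ground truth at the default design."""
    return simulate_screen(reference_truth, seed=20260924)
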