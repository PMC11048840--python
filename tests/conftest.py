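import numpy as np
import pytest

from flavoromics.datasets import (
    load_jujube_roav_reference,
    load_jujube_voc_table,
)


@pytest.fixture(scope="session")
def jujube():
    """(profiles, threshold library) for the three dried-jujube cultivars."""
    return load_jujube_voc_table()


@pytest.fixture(scope="session")
def jujube_roav_reference():
    """Published ROAV scores (3-decimal precision) for cross-checking."""
    return load_jujube_roav_reference()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """LOO-fallback and zero-variance warnings are expected at desk scale."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*leave-one-out.*")
        warnings.filterwarnings("ignore", message=".*zero-variance.*")
        yield
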