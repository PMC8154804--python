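import numpy as np
import pytest

from gabapipe.core import SpectralAxis
from gabapipe.synthetic import default_resonance_tables


@pytest.fixture(scope="session")
def axis():
    """Desk-scale axis: 1024 points, 4 kHz spectral width, 7 T carrier."""
    return SpectralAxis(n_points=1024, dwell_time=1.0 / 4000.0)


@pytest.fixture(scope="session")
def axis2048():
    return SpectralAxis(n_points=2048, dwell_time=1.0 / 4000.0)


@pytest.fixture(scope="session")
def hippocampus():
    return default_resonance_tables("hippocampus")


@pytest.fixture(scope="session")
def pcc():
    return default_resonance_tables("pcc")


@pytest.fixture(autouse=True)
def _quiet_warnings():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield
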