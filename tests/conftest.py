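import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from octmargin.geometry import ScanGeometry

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def geom():
    return ScanGeometry()


@pytest.fixture
def tiny_geom():
    """Small geometry for volume bookkeeping tests (fast to generate)."""
    return ScanGeometry(n_rows=64, n_cols=16, slice_spacing_mm=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
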