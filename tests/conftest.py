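import numpy as np
import pytest

from ibiqc import CleanTraceSpec, IBITrace, generate_clean_trace


@pytest.fixture
def small_trace():
    return IBITrace(ibi_ms=[500.0, 510.0, 505.0])


@pytest.fixture(scope="session")
def clean_ar_trace():
    """A 600 s clean AR(1) trace with high target rMSSD (resting-seal-like)."""
    spec = CleanTraceSpec(
        duration_s=600.0, mean_ibi_ms=1000.0, target_rmssd_ms=108.0,
        ar_coefficient=0.5, seed=7,
    )
    return generate_clean_trace(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
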