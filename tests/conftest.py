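import numpy as np
import pytest

from cdpqc import PeakSpec, Trace, Treatment, simulate_trace


@pytest.fixture
def flat_trace() -> Trace:
    rt = np.arange(0.0, 15.0, 0.01)
    return Trace("flat", Treatment.BLANK, rt, np.zeros_like(rt))


@pytest.fixture
def single_peak_trace() -> Trace:
    return simulate_trace([PeakSpec(8.0, 100.0, 0.1)], noise_sd=0.0, seed=0)


def make_trace(values, rt=None, sample_id="t", treatment=Treatment.INTACT) -> Trace:
    values = np.asarray(values, dtype=float)
    if rt is None:
        rt = np.arange(values.size, dtype=float)
    return Trace(sample_id, treatment, np.asarray(rt, dtype=float), values)
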