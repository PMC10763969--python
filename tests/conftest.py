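import numpy as np
import pytest

from flysleep import ActivityTrace


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_trace(counts, fly_id="fly", zt0=0, genotype=""):
    return ActivityTrace(
        fly_id=fly_id,
        counts=np.asarray(counts, dtype=np.int64),
        zt0_offset_min=zt0,
        genotype=genotype,
    )


@pytest.fixture
def trace_factory():
    return make_trace
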