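import numpy as np
import pytest

from ribopinch import (
    NoiseSpec,
    PinchParams,
    gen_timecourse,
    load_default_params,
)


@pytest.fixture(scope="session")
def nn_params():
    return load_default_params()


@pytest.fixture
def mono_tc():
    """Noiseless monoexponential: f(t) = 0.1 + 0.9 exp(-0.01 t), 8 points."""
    t = np.linspace(0, 600, 8)
    return gen_timecourse([0.01], [0.9], 0.1, t, None, construct_id="mono")


@pytest.fixture
def biexp_tc():
    """Noiseless biexponential with well-separated rates (1.0, 0.01)."""
    t = np.geomspace(0.1, 600, 12)
    t = np.concatenate([[0.0], t])
    return gen_timecourse([1.0, 0.01], [0.5, 0.5], 0.0, t, None, construct_id="bi")


@pytest.fixture
def conf_limited_pinch():
    """Pinch parameters with chemistry so fast the conformational step
    is always rate-limiting."""
    return PinchParams(k_chem=1e9)
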