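import numpy as np
import pytest

from specsense import SimCellSpec, SimExperimentSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def full_protocol():
    """Standard protocol: 310-630/10 nm, 4 repeats, 10 kHz (no groups)."""
    return SimExperimentSpec(groups=())


@pytest.fixture
def fast_protocol():
    """Reduced protocol for population-scale tests: coarse grid, 2 kHz."""
    return SimExperimentSpec(
        groups=(),
        wavelengths=tuple(np.arange(310.0, 631.0, 20.0)),
        repeats=2,
        sample_rate=2000.0,
        duration=1100.0,
    )


@pytest.fixture
def quiet_uv_cell():
    return SimCellSpec(cell_class="UV", lambda_max=390.0, noise_sd=0.0)
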