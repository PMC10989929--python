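import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ribochase.simulate import SimulationParams

LN2 = float(np.log(2.0))


@pytest.fixture
def mock_params() -> SimulationParams:
    """Study-design mock condition: f=0.959, half-lives 3.1/7.2 min."""
    return SimulationParams(
        f_term=0.959,
        lambda_utr=LN2 / 3.1,
        lambda_orf=LN2 / 7.2,
        ct_noise_sd=0.15,
        seed=11,
    )


@pytest.fixture
def uv_params() -> SimulationParams:
    """Study-design UV condition: f=0.653, half-lives 17.1/7.5 min."""
    return SimulationParams(
        alpha=2.52 * 3.1 / 17.1,  # ~2.2-fold transcription reduction vs mock
        f_term=0.653,
        lambda_utr=LN2 / 17.1,
        lambda_orf=LN2 / 7.5,
        ct_noise_sd=0.15,
        seed=12,
    )


@pytest.fixture
def noiseless_mock(mock_params) -> SimulationParams:
    return mock_params.with_(ct_noise_sd=0.0)
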