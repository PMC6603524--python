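import warnings

import numpy as np
import pytest

from tremornet import (AnalysisConfig, ScenarioSpec, generate_benchmark_signals,
                       generate_recording)
from tremornet.embedding import SelectionWarning
from tremornet.pipeline import analyze

# parameter-selection fallbacks on noisy data are expected and verbose
warnings.simplefilter("ignore", SelectionWarning)

SINE_PERIOD = 16.3  # incommensurate with the sampling grid on purpose


@pytest.fixture(scope="session")
def sine():
    return generate_benchmark_signals("sine", 6000, period=SINE_PERIOD)


@pytest.fixture(scope="session")
def lorenz():
    return generate_benchmark_signals("lorenz", 5000, seed=0)


@pytest.fixture(scope="session")
def white_noise():
    return generate_benchmark_signals("white_noise", 2000, seed=1)


@pytest.fixture(scope="session")
def tremor_recording():
    """Default NT -> TO -> T -> NT scenario, fixed seed."""
    return generate_recording(ScenarioSpec(seed=0))


@pytest.fixture(scope="session")
def tremor_analysis(tremor_recording):
    lfp, _, labels = tremor_recording
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return analyze(lfp, AnalysisConfig(), labels=labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
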