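import numpy as np
import pytest
from hypothesis import settings

from wafecg import ECGSegment, WaveletConfig, preprocess
from wafecg.synthetic import PRESETS, synth_dataset, synth_segment

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wcfg():
    return WaveletConfig()


@pytest.fixture(scope="session")
def nsr_segment():
    return preprocess(synth_segment(PRESETS["NSR"], seed=101))


@pytest.fixture(scope="session")
def chf_segment():
    return preprocess(synth_segment(PRESETS["CHF"], seed=202))


@pytest.fixture(scope="session")
def small_dataset():
    """20 NSR + 20 CHF preprocessed segments, shared across tests."""
    nsr = [preprocess(s) for s in synth_dataset([PRESETS["NSR"]], 20, seed=7)]
    chf = [preprocess(s) for s in synth_dataset([PRESETS["CHF"]], 20, seed=8)]
    return {"NSR": nsr, "CHF": chf}


def random_segment(rng, n=2500, fs=250.0):
    return ECGSegment(rng.standard_normal(n), fs=fs, lead="synthetic", source_id="rand")
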