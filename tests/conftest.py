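import numpy as np
import pytest

from gecog import pipeline, synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_run():
    """A 2-h synthetic session scored end-to-end (shared across tests)."""
    truth = synth.generate_states(
        duration=7200.0, seed=1, n_cycles=6, n_rem=4, n_hvs_imm=40, n_hvs_rem=8, n_rears=12
    )
    lfp = synth.generate_lfp(truth, fs=250.0, n_channels=1)
    motion = synth.generate_motion(truth)
    result = pipeline.score_states(lfp[0], lfp[0], 250.0, motion)
    return truth, lfp, motion, result
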