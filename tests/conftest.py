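import numpy as np
import pytest

import centrotrack as ct


@pytest.fixture
def noiseless_pair():
    """A short noiseless cohesive centriole movie with ground truth."""
    return ct.make_centriole_movie(n_frames=5, snr=None, seed=11, orientation=0.4)


@pytest.fixture
def fracture_movie():
    """SNR-8 movie with a scripted fracture (onset 10, 2 um/min, repair 25)."""
    return ct.make_centriole_movie(
        n_frames=40,
        frame_interval=15.0,
        fracture=(10, 2.0, 25),
        snr=8,
        seed=21,
        shape=(96, 96),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
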