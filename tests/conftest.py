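import logging

import numpy as np
import pytest

import gaitpolar as gp

logging.getLogger("gaitpolar").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def layout():
    return gp.default_layout()


@pytest.fixture(scope="session")
def clean_trial(layout):
    """Noise-free symmetric trial with its ground truth."""
    return gp.generate_trial(gp.GaitTemplate(noise_sd=0.0))


@pytest.fixture(scope="session")
def clean_pipeline(clean_trial, layout):
    """COPx and phase series of the clean symmetric trial."""
    trial, truth = clean_trial
    cop = gp.compute_copx(trial, layout)
    phase = gp.estimate_phase(cop, gp.ao_profile("healthy"))
    return trial, truth, cop, phase


def make_trial(F_right, F_left, fs=100.0, **kw):
    n = np.asarray(F_right).shape[0]
    t = np.arange(n) / fs
    return gp.GRFTrial(t=t, F_right=F_right, F_left=F_left, fs=fs, **kw)
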