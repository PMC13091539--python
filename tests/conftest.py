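"""Shared fixtures: canonical synthetic datasets with known ground truth."""

import numpy as np
import pytest

from endoquant.protocols import depol_20ms, depol_20msX10
from endoquant.synthetic import (
    CmGroundTruth, SpotGroundTruth, SypHGroundTruth,
    simulate_cm_recording, simulate_spot_trace, simulate_syph_experiment,
)

#: control-condition decay parameters used for recovery checks throughout
CONTROL_MONO = dict(jump_fF=531.0, tau_s=10.2)
CONTROL_BI = dict(jump_fF=1565.0, tau1_s=1.6, tau2_s=15.5, weight1=0.31)
CONTROL_SYPH = dict(peak_dff_percent=161.0, rate=3.9)


@pytest.fixture
def mono_recording():
    """Noiseless single-pulse recording with the control mono decay."""
    truth = CmGroundTruth(decay_model="mono", noise_sd_fF=0.0, **CONTROL_MONO)
    return simulate_cm_recording(truth, depol_20ms(), seed=0)


@pytest.fixture
def bi_recording():
    """Noiseless train recording with the control bi-exponential decay."""
    truth = CmGroundTruth(decay_model="bi", noise_sd_fF=0.0,
                          jump_fF=CONTROL_BI["jump_fF"],
                          tau1_s=CONTROL_BI["tau1_s"],
                          tau2_s=CONTROL_BI["tau2_s"],
                          weight1=CONTROL_BI["weight1"])
    return simulate_cm_recording(truth, depol_20msX10(), seed=0)


@pytest.fixture
def flat_recording():
    """No jump, no decay, no noise: every estimator's null case."""
    truth = CmGroundTruth(jump_fF=0.0, decay_model="none", noise_sd_fF=0.0)
    return simulate_cm_recording(truth, depol_20ms(), seed=0)


def make_spot(mode: str, noise_sd: float = 0.0, seed: int = 0, **kwargs):
    truth = SpotGroundTruth(mode=mode, noise_sd=noise_sd, **kwargs)
    return simulate_spot_trace(truth, seed=seed, spot_id=f"{mode}_{seed}")


def make_syph(seed: int = 0, noiseless: bool = False, **kwargs):
    params = dict(CONTROL_SYPH)
    params.update(kwargs)
    rate = params.pop("rate")
    if noiseless:
        params.setdefault("noise_sd_percent", 0.0)
        params.setdefault("bouton_peak_cv", 0.0)
        params.setdefault("bouton_rate_cv", 0.0)
    truth = SypHGroundTruth(decay=("linear", rate), **params)
    return simulate_syph_experiment(truth, seed=seed)
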