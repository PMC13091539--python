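"""Parameter-recovery experiments at the control study conditions.

Each function simulates a cohort of synthetic recordings at the published
control-condition parameters (which serve as generator inputs), runs the
corresponding analyzer, and returns the per-unit estimates.  These are the
experiments behind the package's acceptance checks: the analyzers must
recover the generating values from realistic, noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .capacitance import fit_exponential_decay, measure_delta_cm_peak
from .protocols import depol_20ms, depol_20msX10
from .synthetic import (
    CmGroundTruth, SypHGroundTruth, simulate_cm_recording,
    simulate_syph_experiment,
)
from .syph import compute_syph_rate_decay_n

#: control-condition parameters used by the recovery experiments
CONTROL_MONO = {"jump_fF": 531.0, "tau_s": 10.2, "noise_sd_fF": 10.0}
CONTROL_BI = {"jump_fF": 1565.0, "tau1_s": 1.6, "tau2_s": 15.5,
              "weight1": 0.31, "noise_sd_fF": 15.0}
CONTROL_SYPH = {"peak_dff_percent": 161.0, "rate_percent_per_s": 3.9,
                "noise_sd_percent": 3.0}
N_CELLS = 11
N_EXPERIMENTS = 20


@dataclass
class RecoveryResult:
    """Per-unit estimates from one recovery cohort."""

    values: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sem(self) -> float:
        return float(self.values.std(ddof=1) / np.sqrt(len(self.values)))

    @property
    def n(self) -> int:
        return len(self.values)


def _spawned_rngs(seed: int, n: int, stream: int) -> list[np.random.Generator]:
    """Independent per-unit generators; ``stream`` separates cohorts."""
    root = np.random.SeedSequence(seed).spawn(8)[stream]
    return [np.random.default_rng(child) for child in root.spawn(n)]


def recover_mono_control(seed: int, n: int = N_CELLS
                         ) -> tuple[RecoveryResult, RecoveryResult]:
    """Fit n noisy single-pulse control traces; returns (tau, jump) cohorts."""
    truth = CmGroundTruth(decay_model="mono", **CONTROL_MONO)
    taus, jumps = [], []
    for rng in _spawned_rngs(seed, n, stream=0):
        rec = simulate_cm_recording(truth, depol_20ms(), seed=rng)
        fit = fit_exponential_decay(rec, "mono")
        taus.append(fit.tau_s)
        jumps.append(measure_delta_cm_peak(rec))
    return RecoveryResult(np.array(taus)), RecoveryResult(np.array(jumps))


def recover_bi_control(seed: int, n: int = N_CELLS) -> RecoveryResult:
    """Fit n noisy train-stimulus control traces; returns the fast-tau cohort."""
    truth = CmGroundTruth(decay_model="bi",
                          jump_fF=CONTROL_BI["jump_fF"],
                          tau1_s=CONTROL_BI["tau1_s"],
                          tau2_s=CONTROL_BI["tau2_s"],
                          weight1=CONTROL_BI["weight1"],
                          noise_sd_fF=CONTROL_BI["noise_sd_fF"])
    taus = []
    for rng in _spawned_rngs(seed, n, stream=1):
        rec = simulate_cm_recording(truth, depol_20msX10(), seed=rng)
        fit = fit_exponential_decay(rec, "bi")
        taus.append(fit.tau1_s)
    return RecoveryResult(np.array(taus))


def recover_syph_control(seed: int, n: int = N_EXPERIMENTS
                         ) -> tuple[RecoveryResult, RecoveryResult]:
    """Analyze n noisy control experiments; returns (rate, dF/F) cohorts."""
    truth = SypHGroundTruth(
        peak_dff_percent=CONTROL_SYPH["peak_dff_percent"],
        decay=("linear", CONTROL_SYPH["rate_percent_per_s"]),
        noise_sd_percent=CONTROL_SYPH["noise_sd_percent"],
    )
    rates, dffs = [], []
    for rng in _spawned_rngs(seed, n, stream=2):
        exp = simulate_syph_experiment(truth, seed=rng)
        kin = compute_syph_rate_decay_n(exp)
        rates.append(kin.rate_decay_n_percent_per_s)
        dffs.append(kin.dff_percent)
    return RecoveryResult(np.array(rates)), RecoveryResult(np.array(dffs))
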