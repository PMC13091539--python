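"""Seeded generators for every input modality, with known ground truth.

Each generator emits the statistical structure the analyzers assume —
stimulus-locked capacitance jumps with mono-/bi-exponential or overshoot
recovery and a blanked post-stimulus artifact window, 10 Hz pHluorin
bouton traces, 40-80 ms-frame three-channel fusion-spot traces, and EM
vesicle tables — so every downstream stage can be validated by parameter
recovery and closed-form identities without experimental data.  All
randomness flows through a ``numpy.random.Generator`` derived from an
explicit seed; a fixed seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .capacitance import CmRecording
from .em import EMProfileTable, vesicle_area_um2
from .errors import InvalidConfigError
from .fusion import SpotTrace
from .protocols import StimulusProtocol
from .syph import SypHExperiment, normalize_and_average


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# capacitance


@dataclass
class CmGroundTruth:
    """Generating parameters of one capacitance recording.

    ``jump_fF`` is the true capacitance jump (completed instantaneously at
    stimulus end; intra-train exocytosis kinetics are not modeled because
    only the post-stimulus decay is analyzed).  ``decay_model``:

    - ``mono``: jump * exp(-t/tau_s)
    - ``bi``:   jump * (weight1 * exp(-t/tau1_s) + (1-weight1) * exp(-t/tau2_s))
    - ``none``: no recovery
    - ``overshoot``: mono-exponential recovery (tau_s) toward a plateau below
      baseline such that the total decay equals overshoot_fraction * jump.
    """

    jump_fF: float = 500.0
    baseline_fF: float = 0.0
    decay_model: str = "mono"
    tau_s: float = 10.0
    tau1_s: float = 1.6
    tau2_s: float = 15.5
    weight1: float = 0.31
    overshoot_fraction: float = 1.5
    noise_sd_fF: float = 0.0
    sample_rate_hz: float = 100.0
    record_length_s: float = 60.0      # post-stimulus duration
    ica_peak_pA: float = 1200.0
    ica_noise_sd_pA: float = 5.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.decay_model not in ("mono", "bi", "none", "overshoot"):
            raise InvalidConfigError(f"unknown decay_model {self.decay_model!r}")
        if self.sample_rate_hz <= 0 or self.record_length_s <= 0:
            raise InvalidConfigError("sample rate and record length must be > 0")
        if self.decay_model == "mono" and self.tau_s <= 0:
            raise InvalidConfigError("tau_s must be > 0")
        if self.decay_model == "bi":
            if self.tau1_s <= 0 or self.tau2_s <= 0:
                raise InvalidConfigError("taus must be > 0")
            if not 0 < self.weight1 < 1:
                raise InvalidConfigError("weight1 must be in (0, 1)")
        if self.noise_sd_fF < 0:
            raise InvalidConfigError("noise_sd_fF must be >= 0")


def cm_decay_curve(truth: CmGroundTruth, t_post: np.ndarray) -> np.ndarray:
    """Noiseless Cm deviation from baseline at times >= 0 after stimulus end."""
    j = truth.jump_fF
    if truth.decay_model == "none":
        return np.full_like(t_post, j, dtype=float)
    if truth.decay_model == "mono":
        return j * np.exp(-t_post / truth.tau_s)
    if truth.decay_model == "bi":
        return j * (
            truth.weight1 * np.exp(-t_post / truth.tau1_s)
            + (1.0 - truth.weight1) * np.exp(-t_post / truth.tau2_s)
        )
    # overshoot: recovery amplitude overshoot_fraction * jump, so the
    # capacitance settles below baseline
    amp = truth.overshoot_fraction * j
    return j - amp * (1.0 - np.exp(-t_post / truth.tau_s))


def simulate_cm_recording(
    truth: CmGroundTruth,
    protocol: StimulusProtocol,
    seed=None,
    cell_id: str = "cell",
    condition: str = "ctrl",
) -> CmRecording:
    """Simulate a stimulus-locked capacitance + calcium-current recording.

    The trace sits at baseline until the stimulus end, jumps by the true
    amplitude, and recovers per the decay model.  Samples inside the 0.25 s
    artifact window are emitted but flagged unusable; additive Gaussian
    noise is reproducible under a fixed seed.  A square-pulse ICa trace with
    the configured peak accompanies the capacitance channel.
    """
    rng = _rng(truth.seed if seed is None else seed)
    dt = 1.0 / truth.sample_rate_hz
    total = protocol.end_s + truth.record_length_s
    t = np.arange(0.0, total + dt / 2, dt)

    cm = np.full_like(t, truth.baseline_fF)
    post = t >= protocol.end_s
    cm[post] = truth.baseline_fF + cm_decay_curve(truth, t[post] - protocol.end_s)
    if truth.noise_sd_fF > 0:
        cm = cm + rng.normal(0.0, truth.noise_sd_fF, size=len(t))

    mask = (t >= protocol.end_s) & (t <= protocol.artifact_end_s)

    ica = np.zeros_like(t)
    for start, stop in protocol.pulse_windows():
        ica[(t >= start) & (t < stop)] = -truth.ica_peak_pA
    if truth.ica_noise_sd_pA > 0:
        ica = ica + rng.normal(0.0, truth.ica_noise_sd_pA, size=len(t))

    return CmRecording(
        time_s=t, cm_fF=cm, artifact_mask=mask, protocol=protocol,
        ica_pA=ica, cell_id=cell_id, condition=condition,
    )


# ---------------------------------------------------------------------------
# synapto-pHluorin


@dataclass
class SypHGroundTruth:
    """Generating parameters of one SypH experiment.

    The decay is either ``("linear", r)`` — each bouton loses a constant
    r% of its own dF/F per second, the structure implied by a slope-based
    initial-rate statistic — or ``("exp", tau_s)`` for a mono-exponential
    return to baseline.  Boutons are heterogeneous: per-bouton peaks and
    decay rates are drawn around the experiment means with the configured
    coefficients of variation, reflecting the large bouton-to-bouton
    variability of real recordings.
    """

    peak_dff_percent: float = 161.0
    decay: tuple = ("linear", 3.9)     # ("linear", %/s of dF/F) or ("exp", tau_s)
    n_boutons: int = 20
    noise_sd_percent: float = 3.0
    bouton_peak_cv: float = 0.2
    bouton_rate_cv: float = 0.2
    frame_rate_hz: float = 10.0
    baseline_s: float = 10.0
    stim_s: float = 10.0
    post_s: float = 60.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.peak_dff_percent < 0:
            raise InvalidConfigError("peak_dff must be >= 0")
        if self.n_boutons < 1:
            raise InvalidConfigError("n_boutons must be >= 1")
        if self.decay[0] not in ("linear", "exp"):
            raise InvalidConfigError("decay must be ('linear', rate) or ('exp', tau)")
        if self.noise_sd_percent < 0:
            raise InvalidConfigError("noise_sd must be >= 0")


def simulate_syph_experiment(
    truth: SypHGroundTruth,
    seed=None,
    experiment_id: str = "exp",
    condition: str = "ctrl",
    raw_scales: bool = True,
) -> SypHExperiment:
    """Simulate 10 Hz bouton traces and return the normalized experiment.

    Each bouton rises linearly during the stimulation train to its own peak,
    then decays per the decay spec (clipped at baseline).  Traces are
    generated on a random raw-intensity scale per bouton and passed through
    the normalization path, so the returned experiment has a 100% baseline.
    """
    rng = _rng(truth.seed if seed is None else seed)
    dt = 1.0 / truth.frame_rate_hz
    onset = truth.baseline_s
    stim_end = onset + truth.stim_s
    total = stim_end + truth.post_s
    t = np.arange(0.0, total + dt / 2, dt)

    peaks = truth.peak_dff_percent * np.maximum(
        rng.normal(1.0, truth.bouton_peak_cv, truth.n_boutons), 0.05
    )
    if truth.decay[0] == "linear":
        rates = truth.decay[1] * np.maximum(
            rng.normal(1.0, truth.bouton_rate_cv, truth.n_boutons), 0.05
        )
    else:
        taus = truth.decay[1] / np.maximum(
            rng.normal(1.0, truth.bouton_rate_cv, truth.n_boutons), 0.05
        )

    traces = np.empty((truth.n_boutons, len(t)))
    for b in range(truth.n_boutons):
        f = np.full_like(t, 100.0)
        rise = (t >= onset) & (t < stim_end)
        f[rise] = 100.0 + peaks[b] * (t[rise] - onset) / truth.stim_s
        post = t >= stim_end
        tp = t[post] - stim_end
        if truth.decay[0] == "linear":
            # lose rates[b] % of this bouton's dF per second, floor at baseline
            f[post] = 100.0 + np.maximum(
                peaks[b] * (1.0 - rates[b] / 100.0 * tp), 0.0
            )
        else:
            f[post] = 100.0 + peaks[b] * np.exp(-tp / taus[b])
        traces[b] = f

    if truth.noise_sd_percent > 0:
        traces = traces + rng.normal(0.0, truth.noise_sd_percent, traces.shape)

    if raw_scales:
        scales = rng.uniform(50.0, 200.0, truth.n_boutons)
        raw = traces * scales[:, None] / 100.0
    else:
        raw = traces
    return normalize_and_average(t, raw, onset, stim_end, experiment_id, condition)


# ---------------------------------------------------------------------------
# fusion spots


@dataclass
class SpotGroundTruth:
    """Generating parameters of one fusion-spot or pre-spot trace.

    Channel kinematics per mode (noiseless canonical forms):

    - fusion onset: F_PH and F_655 step from baseline to peak while F_FFN
      starts an exponential release decay (``ffn_release_tau_s``);
    - ``close_fusion``: F_655 bleaches exponentially toward its floor from
      onset + closure_time (a closed pore stops dye exchange with the bath);
      F_PH stays high until closure + ph_delay, then decays (pinch-off);
    - ``stay_fusion``: both channels sustained to record end;
    - ``shrink_fusion``: F_PH, F_655 and spot size decline in parallel with
      a shared time constant, size to zero;
    - ``pre_close``: pre-spot (no FFN) at plateau from record start; F_655
      bleaches after the closure event while F_PH stays constant;
    - ``no_close``: pre-spot, both channels constant.
    """

    mode: str = "close_fusion"
    onset_s: float = 5.0
    closure_time_s: float = 2.0
    ffn_release_tau_s: float = 2.0
    a655_bleach_tau_s: float = 0.5
    ph_delay_s: float = 1.0
    ph_decay_tau_s: float = 1.0
    shrink_tau_s: float = 2.0
    frame_interval_s: float = 0.06
    record_length_s: float = 40.0
    noise_sd: float = 0.0             # absolute, on the 0-100 channel scale
    ch_baseline: float = 20.0
    ch_peak: float = 100.0
    ffn_plateau: float = 100.0
    ffn_floor: float = 5.0
    a655_floor: float = 5.0
    size_nm: float = 400.0
    seed: Optional[int] = None

    MODES = ("close_fusion", "stay_fusion", "shrink_fusion", "pre_close", "no_close")

    def __post_init__(self) -> None:
        if self.mode not in self.MODES:
            raise InvalidConfigError(f"unknown spot mode {self.mode!r}")
        lo, hi = 0.04, 0.08
        if not lo <= self.frame_interval_s <= hi:
            raise InvalidConfigError("frame_interval must be within 0.04-0.08 s")
        if self.mode in ("close_fusion", "pre_close") and not (
            0.05 <= self.closure_time_s <= 30.0
        ):
            raise InvalidConfigError("closure_time must be within 0.05-30 s")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")

    @property
    def is_pre_spot(self) -> bool:
        return self.mode in ("pre_close", "no_close")


def simulate_spot_trace(
    truth: SpotGroundTruth, seed=None, spot_id: str = "spot", cell_id: str = "cell"
) -> SpotTrace:
    """Simulate one spot trace with the canonical per-mode channel kinematics."""
    rng = _rng(truth.seed if seed is None else seed)
    t = np.arange(0.0, truth.record_length_s + truth.frame_interval_s / 2,
                  truth.frame_interval_s)
    base, peak = truth.ch_baseline, truth.ch_peak

    if truth.is_pre_spot:
        f_ph = np.full_like(t, peak)
        f_655 = np.full_like(t, peak)
        f_ffn = None
        size = np.full_like(t, truth.size_nm)
        if truth.mode == "pre_close":
            t_close = truth.onset_s + truth.closure_time_s
            late = t >= t_close
            f_655[late] = truth.a655_floor + (peak - truth.a655_floor) * np.exp(
                -(t[late] - t_close) / truth.a655_bleach_tau_s
            )
    else:
        on = t >= truth.onset_s
        f_ph = np.full_like(t, base)
        f_655 = np.full_like(t, base)
        f_ph[on] = peak
        f_655[on] = peak
        f_ffn = np.full_like(t, truth.ffn_plateau)
        f_ffn[on] = truth.ffn_floor + (truth.ffn_plateau - truth.ffn_floor) * np.exp(
            -(t[on] - truth.onset_s) / truth.ffn_release_tau_s
        )
        size = np.full_like(t, truth.size_nm)

        if truth.mode == "close_fusion":
            t_close = truth.onset_s + truth.closure_time_s
            late = t >= t_close
            f_655[late] = truth.a655_floor + (peak - truth.a655_floor) * np.exp(
                -(t[late] - t_close) / truth.a655_bleach_tau_s
            )
            t_ph = t_close + truth.ph_delay_s
            ph_late = t >= t_ph
            f_ph[ph_late] = base + (peak - base) * np.exp(
                -(t[ph_late] - t_ph) / truth.ph_decay_tau_s
            )
        elif truth.mode == "shrink_fusion":
            dec = np.exp(-(t[on] - truth.onset_s) / truth.shrink_tau_s)
            f_ph[on] = base + (peak - base) * dec
            f_655[on] = base + (peak - base) * dec
            size[on] = truth.size_nm * dec
        # stay_fusion: sustained plateaus, nothing further

    if truth.noise_sd > 0:
        f_ph = f_ph + rng.normal(0.0, truth.noise_sd, len(t))
        f_655 = f_655 + rng.normal(0.0, truth.noise_sd, len(t))
        if f_ffn is not None:
            f_ffn = f_ffn + rng.normal(0.0, truth.noise_sd, len(t))
        size = size + rng.normal(0.0, truth.noise_sd / 100.0 * truth.size_nm, len(t))

    return SpotTrace(
        spot_id=spot_id, cell_id=cell_id, time_s=t, f_ph=f_ph, f_655=f_655,
        f_ffn=f_ffn, size_nm=size,
        spot_kind="pre_spot" if truth.is_pre_spot else "fusion_candidate",
    )


# ---------------------------------------------------------------------------
# EM tables


@dataclass
class EMGroundTruth:
    """Generating parameters of one EM condition/timepoint dataset.

    Rates are Poisson intensities per um^2 of synaptic cross-section;
    profile areas follow a gamma distribution; regular-vesicle diameters are
    normal (truncated below the bulk threshold so truth labels stay clean);
    bulk-endosome diameters are lognormal above 80 nm.
    """

    condition: str = "ctrl"
    timepoint: str = "0min"
    n_profiles: int = 120
    profile_area_mean_um2: float = 0.35
    profile_area_shape: float = 8.0
    hrp_pos_rate_per_um2: float = 2.0
    hrp_neg_rate_per_um2: float = 60.0
    vesicle_diam_mean_nm: float = 40.0
    vesicle_diam_sd_nm: float = 5.0
    bulk_rate_per_um2: float = 0.5
    bulk_diam_log_mean: float = math.log(150.0)
    bulk_diam_log_sd: float = 0.35
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("hrp_pos_rate_per_um2", "hrp_neg_rate_per_um2",
                     "bulk_rate_per_um2"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if self.n_profiles < 1 or self.profile_area_mean_um2 <= 0:
            raise InvalidConfigError("need n_profiles >= 1 and positive areas")


def simulate_em_tables(truth: EMGroundTruth, seed=None) -> EMProfileTable:
    """Simulate per-profile vesicle rows (diameter, area, HRP status)."""
    rng = _rng(truth.seed if seed is None else seed)
    shape = truth.profile_area_shape
    areas = rng.gamma(shape, truth.profile_area_mean_um2 / shape, truth.n_profiles)

    prof_rows = []
    ves_rows = []
    for p in range(truth.n_profiles):
        pid = f"{truth.condition}_{truth.timepoint}_p{p:04d}"
        area = float(areas[p])
        prof_rows.append((pid, area, truth.condition, truth.timepoint))
        v = 0
        for rate, hrp, bulk in (
            (truth.hrp_pos_rate_per_um2, True, False),
            (truth.hrp_neg_rate_per_um2, False, False),
            (truth.bulk_rate_per_um2, True, True),
        ):
            n = rng.poisson(rate * area)
            for _ in range(n):
                if bulk:
                    d = float(np.exp(rng.normal(truth.bulk_diam_log_mean,
                                                truth.bulk_diam_log_sd)))
                    d = max(d, 80.0)
                else:
                    d = float(np.clip(
                        rng.normal(truth.vesicle_diam_mean_nm,
                                   truth.vesicle_diam_sd_nm),
                        15.0, 75.0,
                    ))
                ves_rows.append((pid, f"{pid}_v{v:04d}", d,
                                 vesicle_area_um2(d), hrp))
                v += 1

    profiles = pd.DataFrame(prof_rows, columns=[
        "profile_id", "profile_area_um2", "condition", "timepoint"])
    vesicles = pd.DataFrame(ves_rows, columns=[
        "profile_id", "vesicle_id", "diameter_nm", "area_um2", "hrp"])
    return EMProfileTable(vesicles=vesicles, profiles=profiles)


def truth_dict(truth) -> dict:
    """Ground truth as a JSON-serializable dict (sidecar payload)."""
    d = asdict(truth)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
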