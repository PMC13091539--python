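"""Capacitance kinetics: jump, exponential fits, decay rates, mode classes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import endoquant as eq
from endoquant.capacitance import (
    RATE_DECAY_WINDOWS, analyze_recording, classify_endocytic_mode,
    compute_rate_decay, compute_rate_decay_n, compute_total_decay_fraction,
    first_second_retrieval, fit_exponential_decay, measure_delta_cm_peak,
    measure_ica,
)
from endoquant.errors import InsufficientDataError, InvalidConfigError
from endoquant.protocols import depol_20ms
from endoquant.synthetic import CmGroundTruth, simulate_cm_recording

from conftest import CONTROL_BI, CONTROL_MONO


def _brute_force_slope(t, y):
    """Independent least-squares slope from the normal equations."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    tc = t - t.mean()
    return float(np.sum(tc * (y - y.mean())) / np.sum(tc * tc))


class TestDeltaCmPeak:
    def test_flat_trace_is_zero(self, flat_recording):
        assert measure_delta_cm_peak(flat_recording) == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_jump_error_below_two_percent(self):
        """Window-decay bias after extrapolation stays < 2% for tau >= 5 s."""
        for tau in (5.0, 10.2, 20.0):
            truth = CmGroundTruth(jump_fF=100.0, tau_s=tau, noise_sd_fF=0.0)
            rec = simulate_cm_recording(truth, depol_20ms(), seed=0)
            assert measure_delta_cm_peak(rec) == pytest.approx(100.0, rel=0.02)

    def test_plain_mean_carries_known_decay_bias(self):
        """Without extrapolation the estimate is the window mean of the decay."""
        truth = CmGroundTruth(jump_fF=100.0, tau_s=10.2, noise_sd_fF=0.0)
        rec = simulate_cm_recording(truth, depol_20ms(), seed=0)
        est = measure_delta_cm_peak(rec, extrapolate=False)
        post = (rec.time_s >= rec.stim_end_s) & ~rec.artifact_mask
        t_post = rec.time_s[post] - rec.stim_end_s
        win = t_post <= t_post[0] + 0.25
        expected = float(np.mean(100.0 * np.exp(-t_post[win] / 10.2)))
        assert est == pytest.approx(expected, abs=1e-9)

    def test_masked_post_stimulus_raises(self, mono_recording):
        rec = mono_recording
        rec.artifact_mask = rec.time_s >= rec.stim_end_s  # mask everything
        with pytest.raises(InsufficientDataError):
            measure_delta_cm_peak(rec)

    def test_control_recovery_from_noisy_traces(self):
        """11 noisy control traces recover the generating jump to within 1%."""
        jumps = []
        for i in range(11):
            truth = CmGroundTruth(noise_sd_fF=10.0, **CONTROL_MONO)
            rec = simulate_cm_recording(truth, depol_20ms(), seed=300 + i)
            jumps.append(measure_delta_cm_peak(rec))
        assert np.mean(jumps) == pytest.approx(CONTROL_MONO["jump_fF"], rel=0.01)


class TestExponentialFit:
    def test_noiseless_mono_exact(self):
        truth = CmGroundTruth(jump_fF=1.0, tau_s=5.0, noise_sd_fF=0.0)
        rec = simulate_cm_recording(truth, depol_20ms(), seed=0)
        fit = fit_exponential_decay(rec, "mono")
        assert fit.amplitude_fF == pytest.approx(1.0, abs=1e-6)
        assert fit.tau_s == pytest.approx(5.0, abs=1e-6)

    def test_noiseless_bi_recovers_parameters(self, bi_recording):
        fit = fit_exponential_decay(bi_recording, "bi")
        assert fit.tau1_s == pytest.approx(CONTROL_BI["tau1_s"], abs=1e-4)
        assert fit.tau2_s == pytest.approx(CONTROL_BI["tau2_s"], abs=1e-3)
        assert fit.weight1 == pytest.approx(CONTROL_BI["weight1"], abs=1e-4)
        assert fit.tau1_s < fit.tau2_s

    def test_pure_noise_is_flagged(self):
        truth = CmGroundTruth(jump_fF=0.0, decay_model="none", noise_sd_fF=10.0)
        rec = simulate_cm_recording(truth, depol_20ms(), seed=1)
        fit = fit_exponential_decay(rec, "mono")
        assert (not fit.success) or (not fit.well_determined)

    def test_unknown_model_rejected(self, mono_recording):
        with pytest.raises(InvalidConfigError):
            fit_exponential_decay(mono_recording, "tri")


class TestRateDecay:
    def test_constant_trace_is_zero(self, flat_recording):
        assert compute_rate_decay(flat_recording) == pytest.approx(0.0, abs=1e-9)

    def test_linear_decay_recovered_exactly(self):
        rec = simulate_cm_recording(
            CmGroundTruth(jump_fF=100.0, decay_model="none", noise_sd_fF=0.0),
            depol_20ms(), seed=0)
        post = rec.time_s >= rec.stim_end_s
        rec.cm_fF[post] = 100.0 - 10.0 * (rec.time_s[post] - rec.stim_end_s)
        assert compute_rate_decay(rec) == pytest.approx(10.0, abs=1e-9)

    def test_matches_brute_force_oracle(self, mono_recording):
        """Slope equals an independent normal-equation regression to 1e-9."""
        rec = mono_recording
        lo, hi = RATE_DECAY_WINDOWS[rec.protocol.name]
        sel = ((rec.time_s >= rec.stim_end_s + lo)
               & (rec.time_s <= rec.stim_end_s + hi) & ~rec.artifact_mask)
        oracle = -_brute_force_slope(rec.time_s[sel], rec.cm_fF[sel])
        assert compute_rate_decay(rec) == pytest.approx(oracle, abs=1e-9)

    def test_control_mono_slope_value(self):
        """LS slope of a 100 fF, tau=10.2 s decay over 0.5-4 s is ~7.90 fF/s."""
        truth = CmGroundTruth(jump_fF=100.0, tau_s=10.2, noise_sd_fF=0.0)
        rec = simulate_cm_recording(truth, depol_20ms(), seed=0)
        assert compute_rate_decay(rec) == pytest.approx(7.90, abs=0.02)

    def test_window_outside_record_raises(self):
        truth = CmGroundTruth(record_length_s=2.0, **CONTROL_MONO)
        rec = simulate_cm_recording(truth, depol_20ms(), seed=0)
        with pytest.raises(InsufficientDataError):
            compute_rate_decay(rec, window_s=(0.5, 4.0))

    def test_train_protocol_uses_short_window(self, bi_recording):
        rate = compute_rate_decay(bi_recording)
        explicit = compute_rate_decay(bi_recording, window_s=(0.5, 1.5))
        assert rate == pytest.approx(explicit)


class TestRateDecayN:
    def test_simple_ratio(self):
        assert compute_rate_decay_n(10.0, 100.0) == pytest.approx(0.1)

    def test_undefined_for_nonpositive_jump(self):
        with pytest.raises(InvalidConfigError):
            compute_rate_decay_n(10.0, 0.0)

    def test_first_second_retrieval_identity(self):
        """tau = 10.2 s: ~9% of the jump is retrieved in the first second."""
        assert first_second_retrieval(10.2) == pytest.approx(
            1.0 - math.exp(-1.0 / 10.2), abs=1e-12)
        assert 100.0 * first_second_retrieval(10.2) == pytest.approx(9.0, abs=0.5)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(scale=st.floats(0.1, 50.0))
    def test_scale_invariance(self, scale):
        """Scaling the trace scales Rate_decay but not Rate_decay_n or mode."""
        truth = CmGroundTruth(jump_fF=100.0, tau_s=10.2, noise_sd_fF=0.0)
        rec = simulate_cm_recording(truth, depol_20ms(), seed=0)
        kin = analyze_recording(rec, model="mono")
        scaled = simulate_cm_recording(
            CmGroundTruth(jump_fF=100.0 * scale, tau_s=10.2, noise_sd_fF=0.0),
            depol_20ms(), seed=0)
        kin2 = analyze_recording(scaled, model="mono")
        assert kin2.rate_decay_fF_per_s == pytest.approx(
            scale * kin.rate_decay_fF_per_s, rel=1e-9)
        assert kin2.rate_decay_n_per_s == pytest.approx(kin.rate_decay_n_per_s,
                                                        rel=1e-9)
        assert kin2.fit.tau_s == pytest.approx(kin.fit.tau_s, rel=1e-6)
        assert kin2.mode == kin.mode


class TestModeClassifier:
    @pytest.mark.parametrize("decay,tau,expected", [
        (1.40, 10.0, "overshoot"),     # decay > 130%
        (0.20, 10.0, "no_endo"),       # decay < 30%
        (0.80, 0.5, "ultrafast"),
        (0.80, 3.0, "fast"),
        (0.80, 10.0, "slow"),
        # documented boundary conventions
        (1.30, 10.0, "slow"),          # exactly 130% is not overshoot
        (0.30, 10.0, "slow"),          # exactly 30% is not no_endo
        (0.80, 0.6, "fast"),           # 0.6 s inclusive
        (0.80, 6.0, "fast"),           # 6 s inclusive
        (0.80, None, "unclassified"),
    ])
    def test_examples_and_boundaries(self, decay, tau, expected):
        assert classify_endocytic_mode(decay, tau) == expected

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(decay=st.floats(-0.5, 2.0), tau=st.one_of(
        st.none(), st.floats(0.01, 100.0)))
    def test_classifier_is_a_total_partition(self, decay, tau):
        mode = classify_endocytic_mode(decay, tau)
        assert mode in {"overshoot", "no_endo", "ultrafast", "fast", "slow",
                        "unclassified"}
        # re-deriving the class from the thresholds gives the same answer
        if decay > 1.30:
            assert mode == "overshoot"
        elif decay < 0.30:
            assert mode == "no_endo"
        elif tau is None:
            assert mode == "unclassified"

    def test_total_decay_fraction_overshoot_trace(self):
        truth = CmGroundTruth(jump_fF=100.0, decay_model="overshoot",
                              overshoot_fraction=1.5, tau_s=5.0, noise_sd_fF=0.0)
        rec = simulate_cm_recording(truth, depol_20ms(), seed=0)
        jump = measure_delta_cm_peak(rec)
        frac = compute_total_decay_fraction(rec, jump)
        assert frac > 1.30
        assert classify_endocytic_mode(frac, 5.0) == "overshoot"


class TestIca:
    @pytest.mark.parametrize("peak,expected", [
        (200.0, "low"), (500.0, "mid"), (1500.0, "high"),
        (380.0, "out_of_bin"),   # gap between printed bins
        (2000.0, "out_of_bin"),
    ])
    def test_binning(self, peak, expected):
        truth = CmGroundTruth(ica_peak_pA=peak, ica_noise_sd_pA=0.0,
                              noise_sd_fF=0.0)
        rec = simulate_cm_recording(truth, depol_20ms(), seed=0)
        res = measure_ica(rec)
        assert res.present
        assert res.peak_pA == pytest.approx(peak, abs=1e-9)
        assert res.bin == expected

    def test_zero_trace_out_of_bin(self):
        truth = CmGroundTruth(ica_peak_pA=0.0, ica_noise_sd_pA=0.0, noise_sd_fF=0.0)
        rec = simulate_cm_recording(truth, depol_20ms(), seed=0)
        res = measure_ica(rec)
        assert res.peak_pA == pytest.approx(0.0)
        assert res.bin == "out_of_bin"

    def test_missing_ica_flagged(self, mono_recording):
        mono_recording.ica_pA = None
        assert not measure_ica(mono_recording).present


class TestAnalyzeRecording:
    def test_auto_model_selection(self, mono_recording, bi_recording):
        noisy_mono = simulate_cm_recording(
            CmGroundTruth(noise_sd_fF=10.0, **CONTROL_MONO), depol_20ms(), seed=7)
        assert analyze_recording(noisy_mono, model="auto").fit.model == "mono"
        assert analyze_recording(bi_recording, model="auto").fit.model == "bi"

    def test_control_kinetics_assembled(self, mono_recording):
        kin = analyze_recording(mono_recording, model="mono")
        assert kin.delta_cm_peak_fF == pytest.approx(531.0, rel=0.01)
        assert kin.fit.tau_s == pytest.approx(10.2, rel=1e-4)
        assert kin.rate_decay_n_per_s == pytest.approx(
            kin.rate_decay_fF_per_s / kin.delta_cm_peak_fF)
        assert kin.mode == "slow"
        assert kin.ica.bin == "high"
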