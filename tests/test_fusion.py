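"""Fusion-spot event detection, classification, T_FFN, per-cell summaries."""

import math

import numpy as np
import pytest

from endoquant.errors import InvalidConfigError
from endoquant.fusion import (
    FusionEvent, SpotTrace, analyze_spot, classify_fusion_mode, compute_t_ffn,
    detect_fusion_onset, detect_pre_close, summarize_cell,
)
from endoquant.synthetic import SpotGroundTruth, simulate_spot_trace

from conftest import make_spot

FUSION_MODES = ("close_fusion", "stay_fusion", "shrink_fusion")


def _flat_trace(with_ffn=True):
    t = np.arange(0.0, 20.0, 0.06)
    flat = np.full(len(t), 20.0)
    return SpotTrace("flat", "cell", t, flat.copy(), flat.copy(),
                     f_ffn=np.full(len(t), 100.0) if with_ffn else None)


class TestOnsetDetection:
    def test_canonical_onset_within_one_frame(self):
        tr = make_spot("close_fusion", closure_time_s=2.0)
        onset = detect_fusion_onset(tr)
        assert onset == pytest.approx(5.0, abs=0.06 + 1e-9)

    def test_flat_trace_has_no_onset(self):
        assert detect_fusion_onset(_flat_trace()) is None

    def test_single_channel_rise_rejected(self):
        """F_PH rise without F_655 or FFN decay is an artifact, not fusion."""
        tr = _flat_trace()
        tr.f_ph[tr.time_s >= 5.0] = 100.0
        assert detect_fusion_onset(tr) is None

    def test_rise_without_ffn_release_rejected(self):
        tr = _flat_trace()
        on = tr.time_s >= 5.0
        tr.f_ph[on] = 100.0
        tr.f_655[on] = 100.0  # both step, but FFN stays flat
        assert detect_fusion_onset(tr) is None


class TestModeClassification:
    @pytest.mark.parametrize("mode", FUSION_MODES)
    def test_noiseless_confusion_matrix_is_identity(self, mode):
        tr = make_spot(mode, closure_time_s=2.0)
        onset = detect_fusion_onset(tr)
        ev = classify_fusion_mode(tr, onset)
        assert ev.mode == mode

    def test_close_fusion_closure_time_matches_generator(self):
        """Closure = truth closure + bleach half-dimming offset (closed form)."""
        truth = SpotGroundTruth(mode="close_fusion", closure_time_s=2.0,
                                noise_sd=0.0)
        tr = simulate_spot_trace(truth, seed=0)
        ev = classify_fusion_mode(tr, detect_fusion_onset(tr))
        offset = truth.a655_bleach_tau_s * math.log(
            (truth.ch_peak - truth.a655_floor)
            / (0.5 * truth.ch_peak - truth.a655_floor))
        assert ev.closure_time_s == pytest.approx(2.0 + offset,
                                                  abs=2 * truth.frame_interval_s)

    def test_stay_fusion_censoring_tracks_record_length(self):
        short = make_spot("stay_fusion", record_length_s=20.0)
        long = make_spot("stay_fusion", record_length_s=40.0)
        ev_short = classify_fusion_mode(short, detect_fusion_onset(short))
        ev_long = classify_fusion_mode(long, detect_fusion_onset(long))
        assert ev_short.censored      # record ends < 30 s after the 5 s onset
        assert not ev_long.censored

    def test_classification_accurate_under_noise(self):
        """>= 95% per-mode accuracy at 10% channel-amplitude noise."""
        n = 60
        for mode in FUSION_MODES:
            correct = 0
            for i in range(n):
                tr = make_spot(mode, noise_sd=10.0, seed=800 + i,
                               closure_time_s=2.0)
                onset = detect_fusion_onset(tr)
                if onset is None:
                    continue
                if classify_fusion_mode(tr, onset).mode == mode:
                    correct += 1
            assert correct / n >= 0.95, mode


class TestPreClose:
    def test_canonical_pre_close_detected(self):
        assert detect_pre_close(make_spot("pre_close", closure_time_s=2.0))

    def test_no_close_not_detected(self):
        assert not detect_pre_close(make_spot("no_close"))

    def test_parallel_loss_is_not_pre_close(self):
        t = np.arange(0.0, 20.0, 0.06)
        dec = np.where(t < 5.0, 100.0, 100.0 * np.exp(-(t - 5.0) / 2.0))
        tr = SpotTrace("par", "cell", t, dec.copy(), dec.copy(),
                       spot_kind="pre_spot")
        assert not detect_pre_close(tr)


class TestTFfn:
    def test_linear_decay_exact(self):
        """100 -> 0 over 10 s linearly: 20-80% decay time is 6 s exactly."""
        t = np.arange(0.0, 30.0, 0.06)
        y = np.interp(t, [0.0, 5.0, 15.0, 30.0], [100.0, 100.0, 0.0, 0.0])
        tr = SpotTrace("lin", "cell", t, np.full(len(t), 100.0),
                       np.full(len(t), 100.0), f_ffn=y)
        res = compute_t_ffn(tr, onset_s=5.0)
        assert not res.censored
        assert res.t_ffn_s == pytest.approx(6.0, abs=1e-9)

    @pytest.mark.parametrize("tau", [0.5, 1.0, 2.0, 5.0, 10.0])
    def test_exponential_decay_is_tau_ln4(self, tau):
        tr = make_spot("stay_fusion", ffn_release_tau_s=tau,
                       record_length_s=max(40.0, 8 * tau + 10.0),
                       ffn_plateau=100.0, ffn_floor=0.0)
        res = compute_t_ffn(tr, onset_s=5.0)
        assert not res.censored
        assert res.t_ffn_s == pytest.approx(tau * math.log(4.0),
                                            abs=tr.frame_interval_s)

    def test_constant_ffn_censored(self):
        res = compute_t_ffn(_flat_trace(), onset_s=5.0)
        assert res.censored and math.isnan(res.t_ffn_s)

    def test_incomplete_decay_censored(self):
        tr = make_spot("stay_fusion", ffn_release_tau_s=30.0,
                       record_length_s=20.0)
        assert compute_t_ffn(tr, onset_s=5.0).censored


class TestCellSummary:
    def _events(self, modes):
        return [FusionEvent("s%d" % i, "c", 5.0, m) for i, m in enumerate(modes)]

    def test_probability_and_counts(self):
        evs = self._events(["close_fusion"] * 4 + ["stay_fusion"] * 3
                           + ["shrink_fusion"] * 2 + ["ambiguous"])
        s = summarize_cell("c", evs, [True, False])
        assert s.n_fusion_events == 10
        assert s.prob_close_fusion == pytest.approx(0.4)
        assert s.n_close + s.n_stay + s.n_shrink + s.n_ambiguous == 10
        assert s.prob_pre_close == pytest.approx(0.5)
        assert not s.excluded

    def test_fewer_than_five_events_excluded(self):
        s = summarize_cell("c", self._events(["close_fusion"] * 4))
        assert s.excluded

    def test_no_pre_spots_flagged_nan(self):
        s = summarize_cell("c", self._events(["close_fusion"] * 5))
        assert math.isnan(s.prob_pre_close)

    def test_permutation_invariance(self):
        modes = ["close_fusion", "stay_fusion", "shrink_fusion",
                 "close_fusion", "ambiguous", "close_fusion"]
        a = summarize_cell("c", self._events(modes))
        b = summarize_cell("c", self._events(modes[::-1]))
        assert a.prob_close_fusion == b.prob_close_fusion
        assert (a.n_close, a.n_stay, a.n_shrink) == (b.n_close, b.n_stay, b.n_shrink)

    def test_analyze_spot_end_to_end(self):
        tr = make_spot("close_fusion", closure_time_s=2.0)
        ev = analyze_spot(tr)
        assert ev is not None and ev.mode == "close_fusion"
        assert not ev.t_ffn_censored
        assert ev.t_ffn_s == pytest.approx(
            2.0 * math.log(4.0), abs=2 * tr.frame_interval_s)
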