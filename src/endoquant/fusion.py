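"""Fusion-spot event detection and classification from three-channel traces.

Chromaffin-cell fusion events are imaged with three reporters measured per
frame at one spot: F_PH (membrane label, weakly excited), F_655 (bath dye
filling the fused vesicle, strongly excited) and F_FFN (false-transmitter
cargo, pre-loaded).  Fusion onset appears as a simultaneous step rise of
F_PH and F_655 with the onset of F_FFN decay (release).  Because the bath
dye exchanges freely only while the pore is open, pore closure traps dye
that then bleaches under strong excitation: F_655 dims while F_PH is
sustained (or decays with a delay reflecting pinch-off).  The three fusion
outcomes are close-fusion (kiss-and-run), stay-fusion (persistent open
pore) and shrink-fusion (Omega-profile collapse: F_PH, F_655 and spot size
decline in parallel).  Preformed Omega-profiles (pre-spots, no FFN) closing
their pore show the same F_655-bleach/F_PH-sustained signature (pre-close).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientDataError, InvalidConfigError

#: classifier defaults; the detection rules are qualitative in origin and
#: every threshold is an explicit parameter
K_SIGMA = 4.0               # onset: channels must exceed baseline + k*sd
THETA_DIM = 0.5             # "dimmed": below this fraction of post-onset peak
PHI_SUSTAIN = 0.7           # "sustained": above this fraction of peak
MIN_DELAY_FRAMES = 3        # minimum F_PH-after-F_655 lag for pore closure
RHO_PARALLEL = 0.9          # Pearson r of parallel decline (shrink)
CLOSURE_RANGE_S = (0.05, 30.0)   # physiological close-fusion interval
SIZE_SHRINK_FRACTION = 0.2  # spot size must drop by more than this for shrink
MIN_FUSION_EVENTS = 5       # cells with fewer fusion events are excluded
FRAME_INTERVAL_RANGE_S = (0.04, 0.08)


@dataclass
class SpotTrace:
    """Per-frame measurements of one fluorescence spot."""

    spot_id: str
    cell_id: str
    time_s: np.ndarray
    f_ph: np.ndarray
    f_655: np.ndarray
    f_ffn: Optional[np.ndarray] = None
    size_nm: Optional[np.ndarray] = None
    spot_kind: str = "fusion_candidate"   # or "pre_spot"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f_ph = np.asarray(self.f_ph, dtype=float)
        self.f_655 = np.asarray(self.f_655, dtype=float)
        n = len(self.time_s)
        if len(self.f_ph) != n or len(self.f_655) != n:
            raise InvalidConfigError("channels must be time-aligned")
        for name in ("f_ffn", "size_nm"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if len(arr) != n:
                    raise InvalidConfigError(f"{name} must be time-aligned")
                setattr(self, name, arr)
        if self.spot_kind not in ("fusion_candidate", "pre_spot"):
            raise InvalidConfigError(f"unknown spot_kind {self.spot_kind!r}")

    @property
    def frame_interval_s(self) -> float:
        return float(np.median(np.diff(self.time_s)))


@dataclass
class FusionEvent:
    spot_id: str
    cell_id: str
    onset_s: float
    mode: str                      # close_fusion | stay_fusion | shrink_fusion | ambiguous
    closure_time_s: float = math.nan
    t_ffn_s: float = math.nan
    t_ffn_censored: bool = False
    censored: bool = False         # record ended before the outcome resolved


@dataclass
class CellFusionSummary:
    cell_id: str
    n_fusion_events: int
    n_close: int
    n_stay: int
    n_shrink: int
    n_ambiguous: int
    prob_close_fusion: float
    n_pre_spots: int
    n_pre_closed: int
    prob_pre_close: float          # NaN when no pre-spots
    mean_t_ffn_s: float
    excluded: bool
    events: list[FusionEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# helpers


def _smooth(y: np.ndarray, frames: int = 3) -> np.ndarray:
    if frames <= 1:
        return y
    kernel = np.ones(frames) / frames
    pad = frames // 2
    ypad = np.concatenate([np.full(pad, y[0]), y, np.full(frames - 1 - pad, y[-1])])
    return np.convolve(ypad, kernel, mode="valid")


def _sd_floor(values: np.ndarray) -> float:
    """Baseline SD with a floor of 1% of the baseline mean, so that
    noiseless synthetic traces have a usable detection threshold."""
    sd = float(np.std(values))
    return max(sd, 0.01 * abs(float(np.mean(values))), 1e-12)


def _decline_onset_idx(
    smoothed: np.ndarray, peak_idx: int, peak: float,
    frac: float = 0.8, persist: int = 3,
) -> Optional[int]:
    """First index after the peak where the channel has persistently fallen
    below ``frac`` of its post-onset peak; None if it never declines."""
    thr = frac * peak
    below = smoothed[peak_idx:] < thr
    n = len(below)
    for i in range(n):
        if below[i] and np.all(below[i: min(i + persist, n)]):
            return peak_idx + i
    return None


def _first_crossing_time(
    time_s: np.ndarray, y: np.ndarray, start_idx: int, level: float
) -> Optional[float]:
    """Time of the first downward crossing of ``level`` at or after
    ``start_idx``, linearly interpolated between frames."""
    for i in range(max(start_idx, 1), len(y)):
        if y[i] < level <= y[i - 1]:
            f = (y[i - 1] - level) / (y[i - 1] - y[i])
            return float(time_s[i - 1] + f * (time_s[i] - time_s[i - 1]))
        if i == start_idx and y[i] < level:
            return float(time_s[i])
    if y[start_idx] < level:
        return float(time_s[start_idx])
    return None


# ---------------------------------------------------------------------------
# onset detection


def detect_fusion_onset(
    trace: SpotTrace,
    k_sigma: float = K_SIGMA,
    baseline_s: float = 1.0,
    ffn_check_frames: int = 10,
) -> Optional[float]:
    """Detect the fusion onset, or return None.

    Onset is the first frame where F_PH and F_655 both exceed their baseline
    mean + k_sigma * baseline SD within the same 3-frame window AND F_FFN
    begins a sustained decline within +/-2 frames of it.  The FFN decline is
    tested as a drop of the mean over the ``ffn_check_frames`` frames after
    the candidate (skipping the transition frames) relative to the frames
    before it, against a noise-scaled threshold.  Requiring all three
    channels rejects single-channel artifacts.  Traces without an FFN
    channel cannot satisfy the rule and return None.
    """
    if trace.f_ffn is None:
        return None
    t = trace.time_s
    if t[-1] - t[0] < baseline_s:
        raise InsufficientDataError("trace shorter than the required baseline")
    base = t < t[0] + baseline_s
    if base.sum() < 2:
        raise InsufficientDataError("need >= 1 s of pre-event baseline frames")

    thr_ph = trace.f_ph[base].mean() + k_sigma * _sd_floor(trace.f_ph[base])
    thr_655 = trace.f_655[base].mean() + k_sigma * _sd_floor(trace.f_655[base])
    ffn_base_mean = trace.f_ffn[base].mean()
    ffn_sd = _sd_floor(trace.f_ffn[base])

    def ffn_declines_near(i: int) -> bool:
        for j in range(max(i - 2, 0), min(i + 3, n)):
            after = trace.f_ffn[j + 2: j + 2 + ffn_check_frames]
            before = trace.f_ffn[max(0, j - ffn_check_frames): j + 1]
            if len(after) < 3 or len(before) < 1:
                continue
            noise_se = ffn_sd * math.sqrt(1.0 / len(after) + 1.0 / len(before))
            if before.mean() - after.mean() > max(
                2.5 * noise_se, 0.02 * abs(ffn_base_mean)
            ):
                return True
        return False

    n = len(t)
    start = int(np.flatnonzero(base)[-1]) + 1
    for i in range(start, n - 2):
        win_hi = min(i + 3, n)
        over_ph = trace.f_ph[i:win_hi] > thr_ph
        over_655 = trace.f_655[i:win_hi] > thr_655
        if not (over_ph.any() and over_655.any()):
            continue
        if not ffn_declines_near(i):
            continue  # no concurrent release: keep scanning
        both = over_ph & over_655
        j = i + int(np.argmax(both)) if both.any() else i + int(np.argmax(over_ph))
        return float(t[j])
    return None


# ---------------------------------------------------------------------------
# mode classification


def classify_fusion_mode(
    trace: SpotTrace,
    onset_s: float,
    theta_dim: float = THETA_DIM,
    phi_sustain: float = PHI_SUSTAIN,
    min_delay_frames: int = MIN_DELAY_FRAMES,
    rho_parallel: float = RHO_PARALLEL,
    closure_range_s: tuple[float, float] = CLOSURE_RANGE_S,
    smooth_frames: int = 5,
) -> FusionEvent:
    """Classify a detected fusion event as close-, stay- or shrink-fusion.

    Decision order:

    1. shrink-fusion - both channels decline from their post-onset peaks,
       the decline is parallel (Pearson r >= ``rho_parallel`` over the
       decline epoch, i.e. from the first decline onset until both channels
       approach their floors), the spot size (when recorded) drops by more
       than 20%, and the trace does NOT carry the closure signature (F_655
       dimmed below ``theta_dim`` of its peak while F_PH was still
       sustained) - a sequential loss is closure, not shrinking.
    2. close-fusion - F_655 falls below ``theta_dim`` of its post-onset peak
       while F_PH is still >= ``phi_sustain`` of its own peak at that time,
       or the F_PH decline onset lags the F_655 decline onset by at least
       ``min_delay_frames``.  The closure time is the onset-to-F_655
       half-dimming interval and must fall in the physiological 0.05-30 s
       range.
    3. stay-fusion - both channels still >= ``phi_sustain`` of their peaks
       at the record end; censored when the record ends less than 30 s after
       onset (a later closure could have been missed).
    4. otherwise ambiguous (a value, not an error).
    """
    t = trace.time_s
    dt = trace.frame_interval_s
    i0 = int(np.searchsorted(t, onset_s))
    if i0 >= len(t) - 2:
        return FusionEvent(trace.spot_id, trace.cell_id, onset_s, "ambiguous",
                           censored=True)

    s_ph = _smooth(trace.f_ph, smooth_frames)
    s_655 = _smooth(trace.f_655, smooth_frames)
    peak_win = slice(i0, min(i0 + max(int(round(1.0 / dt)), 3), len(t)))
    peak_ph_idx = i0 + int(np.argmax(s_ph[peak_win]))
    peak_655_idx = i0 + int(np.argmax(s_655[peak_win]))
    peak_ph = float(s_ph[peak_ph_idx])
    peak_655 = float(s_655[peak_655_idx])

    tail = slice(max(len(t) - max(smooth_frames, 5), i0), len(t))
    end_ph = float(s_ph[tail].mean())
    end_655 = float(s_655[tail].mean())

    on_ph = _decline_onset_idx(s_ph, peak_ph_idx, peak_ph)
    on_655 = _decline_onset_idx(s_655, peak_655_idx, peak_655)

    # closure signature: F_655 crosses theta while F_PH is still sustained
    close_signature = False
    t_dim = _first_crossing_time(t, s_655, peak_655_idx, theta_dim * peak_655)
    if t_dim is not None:
        i_dim = min(int(np.searchsorted(t, t_dim)), len(t) - 1)
        if s_ph[i_dim] >= phi_sustain * peak_ph:
            close_signature = True

    # --- shrink-fusion: parallel decline of both channels (and no closure
    # signature, which would mean a sequential 655-then-PH loss)
    both_declined = end_ph < phi_sustain * peak_ph and end_655 < phi_sustain * peak_655
    if both_declined and not close_signature and on_ph is not None and on_655 is not None:
        start_dec = min(peak_ph_idx, peak_655_idx)
        end_dec = len(t)
        for arr, peak, end in ((s_ph, peak_ph, end_ph), (s_655, peak_655, end_655)):
            level = end + 0.1 * (peak - end)
            t_fl = _first_crossing_time(t, arr, start_dec, level)
            if t_fl is not None:
                end_dec = min(end_dec, int(np.searchsorted(t, t_fl)) + 1)
        end_dec = max(end_dec, start_dec + 3)
        dec = slice(start_dec, end_dec)
        # heavier smoothing for the correlation statistic only: the epoch is
        # short, so the raw-noise contribution to r has to be suppressed
        corr_frames = 2 * smooth_frames + 1
        a = _smooth(trace.f_ph, corr_frames)[dec]
        b = _smooth(trace.f_655, corr_frames)[dec]
        if len(a) >= 3 and np.std(a) > 0 and np.std(b) > 0:
            rho = float(np.corrcoef(a, b)[0, 1])
            size_ok = True
            if trace.size_nm is not None:
                size = _smooth(trace.size_nm, smooth_frames)
                smax = float(size[i0:].max())
                send = float(size[tail].mean())
                size_ok = smax > 0 and (smax - send) / smax > SIZE_SHRINK_FRACTION
            if rho >= rho_parallel and size_ok:
                return FusionEvent(trace.spot_id, trace.cell_id, onset_s,
                                   "shrink_fusion")

    # --- close-fusion: F_655 dims while F_PH is sustained or lags
    closed = close_signature
    if not closed and on_ph is not None and on_655 is not None:
        if on_ph - on_655 >= min_delay_frames:
            closed = True
    if closed:
        t_half = _first_crossing_time(t, s_655, peak_655_idx, 0.5 * peak_655)
        if t_half is not None:
            closure = t_half - onset_s
            lo, hi = closure_range_s
            if lo <= closure <= hi:
                return FusionEvent(trace.spot_id, trace.cell_id, onset_s,
                                   "close_fusion", closure_time_s=float(closure))

    # --- stay-fusion: both channels sustained to the record end
    if end_ph >= phi_sustain * peak_ph and end_655 >= phi_sustain * peak_655:
        censored = (t[-1] - onset_s) < closure_range_s[1]
        return FusionEvent(trace.spot_id, trace.cell_id, onset_s, "stay_fusion",
                           censored=censored)

    return FusionEvent(trace.spot_id, trace.cell_id, onset_s, "ambiguous")


# ---------------------------------------------------------------------------
# pre-spot pore closure


def detect_pre_close(
    trace: SpotTrace,
    theta_dim: float = THETA_DIM,
    phi_sustain: float = PHI_SUSTAIN,
    min_delay_frames: int = MIN_DELAY_FRAMES,
    baseline_s: float = 1.0,
    smooth_frames: int = 3,
) -> bool:
    """True iff a pre-spot shows the pore-closure signature.

    F_655 must bleach below ``theta_dim`` of its initial level while F_PH
    stays >= ``phi_sustain`` of its initial level throughout the F_655
    dimming epoch (or F_PH declines only after a >= ``min_delay_frames``
    lag).  A parallel loss of both channels is not pre-close.
    """
    t = trace.time_s
    base = t < t[0] + baseline_s
    if base.sum() < 2:
        raise InsufficientDataError("need >= 1 s of initial baseline frames")
    s_ph = _smooth(trace.f_ph, smooth_frames)
    s_655 = _smooth(trace.f_655, smooth_frames)
    init_ph = float(s_ph[base].mean())
    init_655 = float(s_655[base].mean())
    if init_655 <= 0:
        return False

    start = int(np.flatnonzero(base)[-1])
    t_dim = _first_crossing_time(t, s_655, start, theta_dim * init_655)
    if t_dim is None:
        return False
    on_655 = _decline_onset_idx(s_655, start, init_655)
    on_ph = _decline_onset_idx(s_ph, start, init_ph)
    i_dim = int(np.searchsorted(t, t_dim))
    epoch = slice(on_655 if on_655 is not None else start, i_dim + 1)
    if np.all(s_ph[epoch] >= phi_sustain * init_ph):
        return True
    if on_ph is not None and on_655 is not None and on_ph - on_655 >= min_delay_frames:
        return True
    return False


# ---------------------------------------------------------------------------
# release time


@dataclass
class TFfnResult:
    t_ffn_s: float
    censored: bool = False
    message: str = ""


def compute_t_ffn(
    trace: SpotTrace, onset_s: float, floor_frames: int = 5
) -> TFfnResult:
    """20%-80% decay time of F_FFN, the vesicular content release time.

    The span is pre-onset plateau minus post-decay floor; T_FFN is the time
    between the (linearly interpolated) crossings of 80% and 20% remaining
    signal.  Censored when the decay has not resolved by the record end
    (no span, missing crossings, or a still-declining tail, which makes the
    floor estimate unreliable).
    """
    if trace.f_ffn is None:
        return TFfnResult(math.nan, censored=True, message="no FFN channel")
    t = trace.time_s
    y = trace.f_ffn
    pre = t < onset_s
    if not np.any(pre):
        return TFfnResult(math.nan, censored=True, message="no pre-onset frames")
    plateau = float(y[pre].mean())
    floor = float(y[-floor_frames:].mean())
    span = plateau - floor
    noise = _sd_floor(y[pre])
    if span <= max(3.0 * noise, 1e-12):
        return TFfnResult(math.nan, censored=True, message="no resolvable decay")

    # a still-declining tail means the floor (and hence the 20% crossing)
    # is not yet defined
    k = max(floor_frames * 2, 6)
    tail_slope = float(np.polyfit(t[-k:], y[-k:], 1)[0])
    if tail_slope < -0.02 * span:  # losing >2% of span per second at the end
        return TFfnResult(math.nan, censored=True, message="decay incomplete")

    i0 = int(np.searchsorted(t, onset_s))
    t80 = _first_crossing_time(t, y, i0, floor + 0.8 * span)
    t20 = _first_crossing_time(t, y, i0, floor + 0.2 * span)
    if t80 is None or t20 is None:
        return TFfnResult(math.nan, censored=True, message="crossings not reached")
    return TFfnResult(float(t20 - t80))


# ---------------------------------------------------------------------------
# per-cell summary


def summarize_cell(
    cell_id: str,
    events: Sequence[FusionEvent],
    pre_results: Sequence[bool] = (),
    min_events: int = MIN_FUSION_EVENTS,
) -> CellFusionSummary:
    """Aggregate one cell's events into probabilities and release-time mean.

    Cells with fewer than ``min_events`` fusion events are flagged excluded
    (kept in the output, omitted from group aggregates) to avoid noisy
    per-cell probabilities biasing group comparisons.
    """
    n = len(events)
    counts = {"close_fusion": 0, "stay_fusion": 0, "shrink_fusion": 0, "ambiguous": 0}
    for ev in events:
        counts[ev.mode] += 1
    t_ffn = [ev.t_ffn_s for ev in events
             if not ev.t_ffn_censored and math.isfinite(ev.t_ffn_s)]
    n_pre = len(pre_results)
    n_pre_closed = int(sum(bool(r) for r in pre_results))
    return CellFusionSummary(
        cell_id=cell_id,
        n_fusion_events=n,
        n_close=counts["close_fusion"],
        n_stay=counts["stay_fusion"],
        n_shrink=counts["shrink_fusion"],
        n_ambiguous=counts["ambiguous"],
        prob_close_fusion=counts["close_fusion"] / n if n else math.nan,
        n_pre_spots=n_pre,
        n_pre_closed=n_pre_closed,
        prob_pre_close=n_pre_closed / n_pre if n_pre else math.nan,
        mean_t_ffn_s=float(np.mean(t_ffn)) if t_ffn else math.nan,
        excluded=n < min_events,
        events=list(events),
    )


def analyze_spot(trace: SpotTrace, **kwargs) -> Optional[FusionEvent]:
    """Detect and classify a fusion-candidate spot; None when no event."""
    onset = detect_fusion_onset(trace)
    if onset is None:
        return None
    ev = classify_fusion_mode(trace, onset, **kwargs)
    res = compute_t_ffn(trace, onset)
    ev.t_ffn_s = res.t_ffn_s
    ev.t_ffn_censored = res.censored
    return ev
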