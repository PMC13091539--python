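"""Synapto-pHluorin (SypH) trace quantification.

SypH fluorescence rises on exocytosis (vesicle lumen exposed to neutral bath
pH) and falls on endocytosis plus re-acidification.  Boutons are normalized
to a 100% pre-stimulus baseline, averaged into one experiment trace, and the
experiment yields two statistics: the peak rise over baseline (dF/F, in %)
and the initial decay rate normalized to dF/F (Rate_decay_n, %/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .errors import InsufficientDataError, InvalidConfigError

BASELINE_PERCENT = 100.0
#: peak search extends this far past the stimulus end (SypH can lag the train)
PEAK_SEARCH_PAST_STIM_S = 5.0
#: allowed Rate_decay window lengths (s); the convention is "first 4-10 s"
DECAY_WINDOW_RANGE_S = (4.0, 10.0)
DEFAULT_DECAY_WINDOW_S = 6.0


@dataclass
class SypHExperiment:
    """Normalized per-bouton traces and their unweighted average."""

    time_s: np.ndarray
    bouton_f: np.ndarray        # (n_boutons, n_frames), % of baseline
    stim_onset_s: float
    stim_end_s: float
    experiment_id: str = "exp"
    condition: str = "ctrl"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.bouton_f = np.atleast_2d(np.asarray(self.bouton_f, dtype=float))
        if self.bouton_f.shape[1] != len(self.time_s):
            raise InvalidConfigError("bouton traces must match the time grid")

    @property
    def n_boutons(self) -> int:
        return self.bouton_f.shape[0]

    @property
    def mean_f(self) -> np.ndarray:
        return self.bouton_f.mean(axis=0)


@dataclass
class SypHKinetics:
    experiment_id: str
    condition: str
    dff_percent: float
    rate_decay_n_percent_per_s: float
    tau_s: float = math.nan        # optional mono-fit alternative
    n_boutons: int = 0
    flagged: bool = False
    message: str = ""


def normalize_and_average(
    time_s: np.ndarray,
    bouton_raw: np.ndarray,
    stim_onset_s: float,
    stim_end_s: float,
    experiment_id: str = "exp",
    condition: str = "ctrl",
) -> SypHExperiment:
    """Scale each bouton so its pre-stimulus mean is 100%, then average.

    Raises if there are no pre-stimulus frames or a bouton baseline is not
    positive (normalization undefined).
    """
    time_s = np.asarray(time_s, dtype=float)
    raw = np.atleast_2d(np.asarray(bouton_raw, dtype=float))
    pre = time_s < stim_onset_s
    if not np.any(pre):
        raise InsufficientDataError("no pre-stimulus baseline frames")
    base = raw[:, pre].mean(axis=1)
    if np.any(base <= 0):
        raise InvalidConfigError("bouton baseline must be positive to normalize")
    norm = raw / base[:, None] * BASELINE_PERCENT
    return SypHExperiment(time_s, norm, stim_onset_s, stim_end_s,
                          experiment_id, condition)


def _peak_search_selection(exp: SypHExperiment) -> np.ndarray:
    sel = (exp.time_s >= exp.stim_onset_s) & (
        exp.time_s <= exp.stim_end_s + PEAK_SEARCH_PAST_STIM_S
    )
    if not np.any(sel):
        raise InsufficientDataError("no frames in the peak search window")
    return sel


def compute_dff_peak(exp: SypHExperiment) -> float:
    """Peak rise of the experiment-average trace over baseline (dF/F, %).

    The maximum is searched from stimulus onset to 5 s after stimulus end.
    """
    sel = _peak_search_selection(exp)
    return float(exp.mean_f[sel].max() - BASELINE_PERCENT)


def _peak_time(exp: SypHExperiment) -> float:
    sel = _peak_search_selection(exp)
    idx = np.flatnonzero(sel)[np.argmax(exp.mean_f[sel])]
    return float(exp.time_s[idx])


def compute_syph_rate_decay_n(
    exp: SypHExperiment, window_s: float = DEFAULT_DECAY_WINDOW_S
) -> SypHKinetics:
    """Initial decay rate of the average trace, normalized to dF/F (%/s).

    Minus the least-squares slope over [t_peak, t_peak + window], divided by
    dF/F and expressed in percent.  A trace that loses a constant 3.9% of its
    dF/F per second therefore yields 3.9 %/s.  The window length must lie in
    the 4-10 s convention.  A non-positive dF/F flags the result rather than
    raising.
    """
    lo, hi = DECAY_WINDOW_RANGE_S
    if not lo <= window_s <= hi:
        raise InvalidConfigError(f"decay window must be within [{lo}, {hi}] s")
    dff = compute_dff_peak(exp)
    if dff <= 0:
        return SypHKinetics(exp.experiment_id, exp.condition, dff, math.nan,
                            n_boutons=exp.n_boutons, flagged=True,
                            message="dF/F <= 0; Rate_decay_n undefined")
    t_peak = _peak_time(exp)
    if exp.time_s[-1] < t_peak + window_s:
        raise InsufficientDataError("decay window extends past the record")
    sel = (exp.time_s >= t_peak) & (exp.time_s <= t_peak + window_s)
    res = stats.linregress(exp.time_s[sel], exp.mean_f[sel])
    rate_n = -res.slope / dff * 100.0
    return SypHKinetics(exp.experiment_id, exp.condition, dff, float(rate_n),
                        tau_s=fit_syph_decay_tau(exp), n_boutons=exp.n_boutons)


def fit_syph_decay_tau(exp: SypHExperiment) -> float:
    """Mono-exponential time constant of the post-peak decay (alternative
    estimator to the slope-based Rate_decay_n); NaN when the fit fails."""
    t_peak = _peak_time(exp)
    sel = exp.time_s >= t_peak
    x = exp.time_s[sel] - t_peak
    y = exp.mean_f[sel]
    if len(x) < 10:
        return math.nan
    a0 = max(y[0] - BASELINE_PERCENT, 1e-6)

    def f(t, a, tau):
        return BASELINE_PERCENT + a * np.exp(-t / tau)

    try:
        popt, _ = optimize.curve_fit(
            f, x, y, p0=(a0, max(x[-1] / 3.0, 1.0)),
            bounds=([0.0, 1e-3], [np.inf, 100.0 * max(x[-1], 1.0)]), maxfev=10000,
        )
        return float(popt[1])
    except (RuntimeError, ValueError):
        return math.nan
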