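"""Voltage-step stimulation protocols used in whole-cell capacitance recordings.

A protocol is one or more depolarizing steps from a holding potential of
-80 mV to +10 mV.  Trains are delivered at a fixed pulse rate (10 Hz for the
standard 10x20 ms train).  The capacitance trace in a window immediately
after the stimulus is contaminated by a gating/conductance artifact and is
blanked; the analyzer, not the simulator, owns that exclusion rule, so the
blank duration travels with the protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import InvalidConfigError

#: capacitance samples within this window after stimulus end are unusable
DEFAULT_ARTIFACT_BLANK_S = 0.25


@dataclass(frozen=True)
class StimulusProtocol:
    """A depolarization protocol and its timing within the recording.

    Parameters
    ----------
    name:
        One of ``depol_20ms``, ``depol_20msX10``, ``depol_1s``.
    pulse_duration_s:
        Duration of a single depolarizing step.
    n_pulses:
        Number of steps; trains use ``pulse_rate_hz`` for the inter-pulse
        interval (onset-to-onset).
    onset_s:
        Time of the first pulse onset within the recording.  At least 1 s
        of pre-stimulus baseline is required by the analyzers.
    """

    name: str
    pulse_duration_s: float
    n_pulses: int = 1
    pulse_rate_hz: float = 10.0
    holding_mv: float = -80.0
    step_mv: float = 10.0
    artifact_blank_s: float = DEFAULT_ARTIFACT_BLANK_S
    onset_s: float = 2.0

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise InvalidConfigError("n_pulses must be >= 1")
        if self.pulse_duration_s <= 0:
            raise InvalidConfigError("pulse_duration_s must be > 0")
        if self.n_pulses > 1 and self.pulse_rate_hz <= 0:
            raise InvalidConfigError("pulse_rate_hz must be > 0 for trains")
        if self.artifact_blank_s < 0:
            raise InvalidConfigError("artifact_blank_s must be >= 0")
        if self.name == "depol_20msX10" and not (
            self.n_pulses == 10 and self.pulse_rate_hz == 10.0
        ):
            raise InvalidConfigError("depol_20msX10 is exactly 10 pulses at 10 Hz")

    @property
    def end_s(self) -> float:
        """Stimulus end = onset + (n_pulses - 1)/rate + pulse_duration."""
        train = (self.n_pulses - 1) / self.pulse_rate_hz if self.n_pulses > 1 else 0.0
        return self.onset_s + train + self.pulse_duration_s

    @property
    def artifact_end_s(self) -> float:
        return self.end_s + self.artifact_blank_s

    def pulse_windows(self) -> list[tuple[float, float]]:
        """(start, end) of every depolarizing step, in recording time."""
        step = 1.0 / self.pulse_rate_hz if self.n_pulses > 1 else 0.0
        return [
            (self.onset_s + i * step, self.onset_s + i * step + self.pulse_duration_s)
            for i in range(self.n_pulses)
        ]

    def with_onset(self, onset_s: float) -> "StimulusProtocol":
        return replace(self, onset_s=onset_s)


def depol_20ms(onset_s: float = 2.0) -> StimulusProtocol:
    """Single 20 ms step; evokes slow endocytosis at the calyx."""
    return StimulusProtocol("depol_20ms", 0.020, n_pulses=1, onset_s=onset_s)


def depol_20msX10(onset_s: float = 2.0) -> StimulusProtocol:
    """Ten 20 ms steps at 10 Hz; evokes a rapid endocytic component."""
    return StimulusProtocol("depol_20msX10", 0.020, n_pulses=10, pulse_rate_hz=10.0,
                            onset_s=onset_s)


def depol_1s(onset_s: float = 2.0) -> StimulusProtocol:
    """Single 1 s step used in chromaffin cells."""
    return StimulusProtocol("depol_1s", 1.0, n_pulses=1, onset_s=onset_s)


PROTOCOLS = {
    "depol_20ms": depol_20ms,
    "depol_20msX10": depol_20msX10,
    "depol_1s": depol_1s,
}


def get_protocol(name: str, onset_s: float = 2.0) -> StimulusProtocol:
    try:
        return PROTOCOLS[name](onset_s=onset_s)
    except KeyError:
        raise InvalidConfigError(f"unknown protocol {name!r}") from None
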