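"""Electrical field-stimulation protocols and acquisition timing.

A recording is a time-lapse acquired at a fixed frame interval; at
``stim_onset`` a train of action potentials (APs) is delivered at
``frequency`` for ``duration`` seconds.  The standard trains are
200 AP (40 Hz, 5 s), 80 AP (40 Hz, 2 s) and 40 AP (20 Hz, 2 s), acquired
at 0.5 Hz for 100 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulationProtocol", "PHLUORIN_BASELINE_S", "CYPHER_BASELINE_S"]

#: minimum pre-stimulus baseline (s) required per indicator: F0 uses the first
#: 5 frames (10 s) for pHluorin and the first 10 frames (20 s) for CypHer.
PHLUORIN_BASELINE_S = 10.0
CYPHER_BASELINE_S = 20.0


@dataclass(frozen=True)
class StimulationProtocol:
    """AP train plus acquisition geometry.

    Parameters
    ----------
    frequency : float
        Stimulation frequency in Hz.
    duration : float
        Train duration in seconds.
    stim_onset : float
        Time of the first AP, seconds from the start of the recording.
    frame_interval : float
        Seconds between frames (default 2.0, i.e. 0.5 Hz).
    total_duration : float
        Recording length in seconds (default 100).
    n_aps : int, optional
        Number of APs; derived as ``round(frequency * duration)`` when
        omitted, validated against it otherwise.
    """

    frequency: float
    duration: float
    stim_onset: float = 10.0
    frame_interval: float = 2.0
    total_duration: float = 100.0
    n_aps: int = field(default=-1)

    def __post_init__(self) -> None:
        for name in ("frequency", "duration", "stim_onset", "frame_interval",
                     "total_duration"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.frequency <= 0 or self.duration <= 0:
            raise ValueError("frequency and duration must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.stim_onset < 0:
            raise ValueError("stim_onset must be non-negative")
        expected = int(round(self.frequency * self.duration))
        if self.n_aps == -1:
            object.__setattr__(self, "n_aps", expected)
        elif self.n_aps != expected:
            raise ValueError(
                f"n_aps={self.n_aps} inconsistent with "
                f"round(frequency*duration)={expected}")
        n_frames = self.total_duration / self.frame_interval
        if abs(n_frames - round(n_frames)) > 1e-9 or round(n_frames) < 1:
            raise ValueError(
                "total_duration must be a positive integer multiple of "
                "frame_interval")
        if self.stim_end > self.total_duration:
            raise ValueError("stimulus train extends past the recording")

    # -- derived timing ----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(round(self.total_duration / self.frame_interval))

    @property
    def stim_end(self) -> float:
        return self.stim_onset + self.duration

    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds (frame k at k*frame_interval)."""
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def baseline_frames(self) -> int:
        """Number of whole frames acquired strictly before the stimulus."""
        return int(np.ceil(self.stim_onset / self.frame_interval - 1e-9))

    def check_baseline(self, indicator: str) -> None:
        """Require the indicator's F0 window to fit before the stimulus."""
        name = str(getattr(indicator, "value", indicator)).lower()
        need = (PHLUORIN_BASELINE_S if name.startswith("ph")
                else CYPHER_BASELINE_S)
        if self.stim_onset + 1e-9 < need:
            raise ValueError(
                f"stim_onset={self.stim_onset} s leaves less than the "
                f"{need:.0f} s baseline required for {indicator}")

    # -- standard trains ---------------------------------------------------
    @classmethod
    def train_200ap(cls, indicator: str = "phluorin") -> "StimulationProtocol":
        return cls(40.0, 5.0, stim_onset=_onset(indicator))

    @classmethod
    def train_80ap(cls, indicator: str = "phluorin") -> "StimulationProtocol":
        return cls(40.0, 2.0, stim_onset=_onset(indicator))

    @classmethod
    def train_40ap(cls, indicator: str = "phluorin") -> "StimulationProtocol":
        return cls(20.0, 2.0, stim_onset=_onset(indicator))


def _onset(indicator: str) -> float:
    name = str(getattr(indicator, "value", indicator)).lower()
    return PHLUORIN_BASELINE_S if name.startswith("ph") else CYPHER_BASELINE_S
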