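"""Per-bouton fluorescence trace quantification.

The readouts of a pHluorin/CypHer recording are built in four steps:

1. background correction: F(t) = mean ROI intensity - background;
2. (CypHer only) photobleaching correction from the pre-stimulus baseline;
3. surface normalization F/F0 (F0 = mean of the first 5 frames for pHluorin,
   first 10 for CypHer) and the exocytic amplitude;
4. peak normalization: dF = F - F0 (pHluorin) or F0 - F (CypHer, so the
   deflection is positive-going), norm. dF = dF / max(dF).

Peak-normalized traces of all videos in a condition are averaged pointwise;
the decay of the average is fitted in :mod:`synapkit.decay`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .protocols import StimulationProtocol

__all__ = [
    "Indicator",
    "FluorescenceTrace",
    "SurfaceNormalized",
    "NormalizedTrace",
    "AveragedTrace",
    "BleachModel",
    "BleachFitError",
    "NonResponderError",
    "baseline_n_frames",
    "bleach_correct",
    "surface_normalize",
    "peak_normalize",
    "average_traces",
]


class Indicator(str, enum.Enum):
    """Reporter polarity: pHluorin goes up on exocytosis, CypHer goes down."""

    PHLUORIN = "phluorin"
    CYPHER = "cypher"

    @classmethod
    def coerce(cls, value: "Indicator | str") -> "Indicator":
        if isinstance(value, cls):
            return value
        v = str(value).lower()
        if v in ("phluorin", "ph", "pH".lower()):
            return cls.PHLUORIN
        if v in ("cypher", "cypher5e", "cy"):
            return cls.CYPHER
        raise ValueError(f"unknown indicator {value!r}")


def baseline_n_frames(indicator: Indicator | str) -> int:
    """F0 window length in frames: first 5 for pHluorin, first 10 for CypHer."""
    return 5 if Indicator.coerce(indicator) is Indicator.PHLUORIN else 10


class NonResponderError(ValueError):
    """Raised when a trace shows no positive-going deflection to normalize."""


class BleachFitError(RuntimeError):
    """Baseline bleach fit failed; carries the residuals of the attempt."""

    def __init__(self, message: str, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.residuals = residuals


@dataclass
class FluorescenceTrace:
    """One bouton's (or one video's bouton-averaged) intensity time course.

    ``raw_intensity`` is the mean ROI pixel intensity per frame;
    ``background`` (scalar or per-frame) is subtracted by :meth:`corrected`.
    """

    time: np.ndarray
    raw_intensity: np.ndarray
    indicator: Indicator
    protocol: StimulationProtocol
    background: np.ndarray | float = 0.0
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.raw_intensity = np.asarray(self.raw_intensity, dtype=float)
        self.indicator = Indicator.coerce(self.indicator)
        if self.time.ndim != 1 or self.time.shape != self.raw_intensity.shape:
            raise ValueError("time and raw_intensity must be 1-D, same length")
        if len(self.time) < 2:
            raise ValueError("trace needs at least two frames")
        dt = np.diff(self.time)
        if np.any(dt <= 0) or np.ptp(dt) > 1e-6 * dt[0]:
            raise ValueError("time must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.raw_intensity)):
            raise ValueError("raw_intensity must be finite")
        bg = np.asarray(self.background, dtype=float)
        if bg.ndim not in (0, 1) or (bg.ndim == 1
                                     and bg.shape != self.time.shape):
            raise ValueError("background must be scalar or per-frame")

    def corrected(self) -> np.ndarray:
        """Background-corrected fluorescence F(t)."""
        return self.raw_intensity - np.asarray(self.background, dtype=float)

    @property
    def frame_interval(self) -> float:
        return float(self.time[1] - self.time[0])

    def pre_stimulus_frames(self) -> int:
        return int(np.sum(self.time < self.protocol.stim_onset - 1e-9))


@dataclass
class SurfaceNormalized:
    """F/F0 trace plus the exocytic-amplitude readouts.

    ``fold_increase`` = max(F)/F0 for pHluorin; for CypHer the exocytic
    amplitude is F0 - min(F) in counts (``exo_amplitude``) and as a fraction
    of F0 (``exo_fraction_of_f0``).
    """

    time: np.ndarray
    f_over_f0: np.ndarray
    f0: float
    fold_increase: float | None = None
    exo_amplitude: float | None = None
    exo_fraction_of_f0: float | None = None


@dataclass
class NormalizedTrace:
    """Peak-normalized deflection dF/dFmax with its bookkeeping."""

    time: np.ndarray
    norm_df: np.ndarray
    f0: float
    df_max: float
    peak_index: int
    indicator: Indicator
    protocol: StimulationProtocol
    fold_increase: float | None = None
    roi_id: str = ""

    def __post_init__(self) -> None:
        if abs(self.norm_df[self.peak_index] - 1.0) > 1e-12:
            raise ValueError("norm_df must equal 1 at peak_index")


@dataclass
class AveragedTrace:
    """Pointwise mean +- SEM of normalized traces from one condition."""

    time: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int
    indicator: Indicator
    protocol: StimulationProtocol

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.mean))


@dataclass
class BleachModel:
    """Mono-exponential bleach baseline B(t) = b0 * exp(-t / tau_bleach)."""

    b0: float
    tau_bleach: float
    fit_frames: int = 10
    rss: float = 0.0
    corrected: bool = True  # False when tau_bleach exceeded the cap

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.b0 * np.exp(-np.asarray(t, dtype=float) / self.tau_bleach)


# ---------------------------------------------------------------------------
# bleach correction
# ---------------------------------------------------------------------------

def _fit_bleach_baseline(t: np.ndarray, f: np.ndarray) -> tuple[float, float,
                                                                np.ndarray]:
    """Least-squares fit of b0*exp(-t/tau) to the pre-stimulus frames."""
    if np.any(f <= 0):
        raise BleachFitError("baseline contains non-positive values",
                             residuals=f)
    # log-linear start values, then full nonlinear refinement
    slope, intercept = np.polyfit(t, np.log(f), 1)
    tau0 = -1.0 / slope if slope < 0 else 1e6
    b00 = float(np.exp(intercept))
    try:
        popt, _ = curve_fit(
            lambda tt, b0, tau: b0 * np.exp(-tt / tau), t, f,
            p0=(b00, min(max(tau0, 1.0), 1e6)),
            bounds=([0.0, 1e-3], [np.inf, 1e9]), maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise BleachFitError(f"bleach baseline fit did not converge: {exc}",
                             residuals=f - b00 * np.exp(-t / tau0)) from exc
    b0, tau = float(popt[0]), float(popt[1])
    resid = f - b0 * np.exp(-t / tau)
    return b0, tau, resid


def bleach_correct(
    trace: FluorescenceTrace,
    method: str = "ratio",
    fit_frames: int = 10,
    tau_cap: float = 1e4,
) -> tuple[FluorescenceTrace, BleachModel]:
    """Correct a CypHer trace for photobleaching.

    The bleach baseline B(t) = b0*exp(-t/tau_bleach) is fitted by least
    squares to the first ``fit_frames`` (default 10, i.e. the 20 s before
    stimulation).  Correction methods:

    ``"ratio"`` (default)
        F_corr = F * B(0)/B(t).  Exact inverse of a multiplicative bleach
        process; leaves a signal-free baseline at the constant b0.
    ``"addback"``
        F_corr = F + [B(0) - B(t)] — adds back the cumulative intensity
        lost to bleaching.  Also stationary on a signal-free baseline, but
        leaves the stimulus deflection itself attenuated by B(t)/B(0).
    ``"literal"``
        F_corr = F + B(t).

    If the fitted tau_bleach exceeds ``tau_cap`` (negligible bleaching) the
    correction is the identity and the model is flagged ``corrected=False``.
    """
    if trace.indicator is not Indicator.CYPHER:
        raise ValueError("bleach correction applies to CypHer traces only")
    n_pre = trace.pre_stimulus_frames()
    if n_pre < fit_frames:
        raise ValueError(
            f"need >= {fit_frames} pre-stimulation frames, got {n_pre}")
    if method not in ("ratio", "addback", "literal"):
        raise ValueError(f"unknown bleach-correction method {method!r}")

    f = trace.corrected()
    t = trace.time
    b0, tau, resid = _fit_bleach_baseline(t[:fit_frames], f[:fit_frames])
    model = BleachModel(b0=b0, tau_bleach=tau, fit_frames=fit_frames,
                        rss=float(np.sum(resid**2)))
    if tau > tau_cap:
        model.corrected = False
        return trace, model

    bleach = np.exp(-t / tau)
    if method == "ratio":
        f_corr = f / bleach
    elif method == "addback":
        f_corr = f + b0 * (1.0 - bleach)
    else:
        f_corr = f + b0 * bleach
    corrected = replace(trace, raw_intensity=f_corr, background=0.0)
    return corrected, model


# ---------------------------------------------------------------------------
# normalizations
# ---------------------------------------------------------------------------

def _f0(f: np.ndarray, indicator: Indicator) -> float:
    n = baseline_n_frames(indicator)
    if len(f) < n:
        raise ValueError(f"trace shorter than the {n}-frame F0 window")
    return float(np.mean(f[:n]))


def surface_normalize(trace: FluorescenceTrace) -> SurfaceNormalized:
    """F/F0 and the exocytic amplitude of a background-corrected trace.

    F0 is the mean of the first 5 (pHluorin) or 10 (CypHer) frames,
    regardless of when the stimulus starts.
    """
    f = trace.corrected()
    f0 = _f0(f, trace.indicator)
    if f0 <= 0:
        raise ValueError(f"F0={f0:.3g} <= 0; trace rejected")
    out = SurfaceNormalized(time=trace.time, f_over_f0=f / f0, f0=f0)
    if trace.indicator is Indicator.PHLUORIN:
        out.fold_increase = float(np.max(f) / f0)
    else:
        amp = float(f0 - np.min(f))
        out.exo_amplitude = amp
        out.exo_fraction_of_f0 = amp / f0
    return out


def peak_normalize(trace: FluorescenceTrace) -> NormalizedTrace:
    """Peak-normalized deflection dF/dFmax.

    dF = F - F0 for pHluorin and F0 - F for CypHer (sign-flipped so both
    indicators yield a positive-going deflection); the peak is the earliest
    frame attaining max(dF).
    """
    f = trace.corrected()
    f0 = _f0(f, trace.indicator)
    df = f - f0 if trace.indicator is Indicator.PHLUORIN else f0 - f
    df_max = float(np.max(df))
    if df_max <= 0:
        raise NonResponderError(
            f"max deflection {df_max:.3g} <= 0; not a responder")
    peak = int(np.argmax(df))  # argmax takes the earliest frame on ties
    fold = None
    if f0 > 0:
        fold = (float(np.max(f) / f0)
                if trace.indicator is Indicator.PHLUORIN else None)
    return NormalizedTrace(
        time=trace.time, norm_df=df / df_max, f0=f0, df_max=df_max,
        peak_index=peak, indicator=trace.indicator, protocol=trace.protocol,
        fold_increase=fold, roi_id=trace.roi_id)


def average_traces(traces: Sequence[NormalizedTrace]) -> AveragedTrace:
    """Pointwise mean and SEM of normalized traces sharing one time base.

    The averaging unit is whatever the caller passes — per the analysis
    convention this is one normalized trace per video (each video's trace
    already averages >= 20 responding boutons); per-bouton traces may be
    averaged the same way when explicitly requested upstream.
    """
    if not traces:
        raise ValueError("no traces to average")
    first = traces[0]
    for tr in traces[1:]:
        if tr.protocol != first.protocol or tr.indicator != first.indicator:
            raise ValueError("mixed protocols/indicators cannot be averaged")
        if tr.time.shape != first.time.shape or not np.allclose(
                tr.time, first.time):
            raise ValueError("traces do not share a time base")
    stack = np.vstack([tr.norm_df for tr in traces])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sem = (stack.std(axis=0, ddof=1) / np.sqrt(n)
           if n > 1 else np.zeros_like(mean))
    return AveragedTrace(time=first.time.copy(), mean=mean, sem=sem, n=n,
                         indicator=first.indicator, protocol=first.protocol)
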