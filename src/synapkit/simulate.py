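"""Seeded generators for every raw-data modality the pipeline analyzes.

Kinetic model for reporter traces
---------------------------------
The surface reporter pool S(t) (fraction of the labeled pool on the plasma
membrane above its resting level) obeys first-order endocytosis with a
uniform exocytic injection during the AP train::

    dS/dt = E(t) - S / tau_endo,
    E(t)  = exo_fraction / duration   for stim_onset <= t < stim_end, else 0.

Reacidification is folded into tau_endo, so the decay constant of the
simulated deflection equals the quantity the analysis estimates.  pHluorin
intensity is proportional to S + resting_surface_fraction (surface pool is
bright); CypHer intensity to 1 - S - resting_surface_fraction (internal
acidic pool is bright).  The noiseless signal is multiplied by
exp(-t/tau_bleach), scaled by the bouton amplitude, offset by the camera
background, and Gaussian noise with SD = noise_sd_fraction * amplitude is
added.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import FluorescenceTrace, Indicator
from .protocols import StimulationProtocol

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "TimeLapseVideo",
    "SynapseLayout",
    "MorphometryDensities",
    "surface_pool",
    "simulate_trace",
    "simulate_video",
    "simulate_sted_synapse",
    "simulate_morphometry",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Kinetic, optical and noise parameters of the trace/video generator.

    Defaults represent a typical healthy recording: tau_endo around the
    control values reported for pHluorin probes, a 20% pool turnover per
    200-AP train, ~10% resting surface fraction, moderate bouton-to-bouton
    amplitude spread and 5% amplitude noise.
    """

    tau_endo: float = 30.0           # s, ground-truth endocytic constant
    exo_fraction: float = 0.2        # pool fraction fused per train
    resting_surface_fraction: float = 0.1
    tau_bleach: float = math.inf     # s; inf = no bleaching
    background_level: float = 100.0  # camera offset, counts
    amplitude_mean: float = 1000.0   # per-bouton scale, counts
    amplitude_cv: float = 0.3
    noise_sd_fraction: float = 0.05  # Gaussian SD / amplitude
    indicator: Indicator = Indicator.PHLUORIN
    seed: int = 0

    def __post_init__(self) -> None:
        self.indicator = Indicator.coerce(self.indicator)
        finite = dict(tau_endo=self.tau_endo, exo_fraction=self.exo_fraction,
                      resting_surface_fraction=self.resting_surface_fraction,
                      background_level=self.background_level,
                      amplitude_mean=self.amplitude_mean,
                      amplitude_cv=self.amplitude_cv,
                      noise_sd_fraction=self.noise_sd_fraction)
        for name, v in finite.items():
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if math.isnan(self.tau_bleach) or self.tau_bleach <= 0:
            raise ValueError("tau_bleach must be > 0 (inf allowed)")
        if self.tau_endo <= 0:
            raise ValueError("tau_endo must be > 0")
        if not 0.0 <= self.exo_fraction <= 1.0:
            raise ValueError("exo_fraction must lie in [0, 1]")
        if not 0.0 <= self.resting_surface_fraction < 1.0:
            raise ValueError("resting_surface_fraction must lie in [0, 1)")
        if self.noise_sd_fraction < 0 or self.amplitude_cv < 0:
            raise ValueError("noise_sd_fraction and amplitude_cv must be >= 0")
        if self.exo_fraction + self.resting_surface_fraction > 1.0:
            raise ValueError("resting + released surface fraction exceeds 1")


@dataclass
class GroundTruth:
    """Planted truth paired with a simulated video, one row per bouton."""

    boutons: pd.DataFrame  # columns: bouton_id, row, col, amplitude, f0, responder
    tau_endo: float
    tau_bleach: float
    seed: int

    def responders(self) -> pd.DataFrame:
        return self.boutons[self.boutons["responder"]]


@dataclass
class TimeLapseVideo:
    """Time-ordered frame stack with its acquisition metadata."""

    frames: np.ndarray  # (n_frames, H, W)
    frame_interval: float
    protocol: StimulationProtocol | None = None
    source_dtype: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, H, W)")
        if not self.source_dtype:
            self.source_dtype = str(self.frames.dtype)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def surface_pool(t: np.ndarray, tau_endo: float, exo_fraction: float,
                 stim_onset: float, stim_end: float) -> np.ndarray:
    """Analytic S(t) for uniform injection during [stim_onset, stim_end).

    During the train S relaxes toward r*tau (r = exo_fraction/duration);
    afterwards it decays with tau_endo.  0 <= S <= exo_fraction always.
    """
    t = np.asarray(t, dtype=float)
    tau = tau_endo
    dur = stim_end - stim_onset
    s = np.zeros_like(t)
    if dur <= 0 or exo_fraction == 0:
        return s
    r = exo_fraction / dur
    during = (t >= stim_onset) & (t < stim_end)
    after = t >= stim_end
    s[during] = r * tau * (1.0 - np.exp(-(t[during] - stim_onset) / tau))
    s_end = r * tau * (1.0 - np.exp(-dur / tau))
    s[after] = s_end * np.exp(-(t[after] - stim_end) / tau)
    return s


def _noiseless_signal(config: SimulationConfig,
                      protocol: StimulationProtocol,
                      t: np.ndarray) -> np.ndarray:
    """Unit-amplitude, background-free signal including bleaching."""
    s = surface_pool(t, config.tau_endo, config.exo_fraction,
                     protocol.stim_onset, protocol.stim_end)
    if config.indicator is Indicator.PHLUORIN:
        pool = s + config.resting_surface_fraction
    else:
        pool = 1.0 - s - config.resting_surface_fraction
    if np.isfinite(config.tau_bleach):
        pool = pool * np.exp(-t / config.tau_bleach)
    return pool


def simulate_trace(config: SimulationConfig,
                   protocol: StimulationProtocol,
                   amplitude: float | None = None,
                   rng: np.random.Generator | None = None,
                   roi_id: str = "sim") -> FluorescenceTrace:
    """Simulate one bouton's fluorescence trace.

    ``amplitude`` overrides the per-bouton scale (defaults to
    ``config.amplitude_mean``); ``rng`` overrides the seeded generator so a
    caller drawing many boutons can share one stream.
    """
    protocol.check_baseline(config.indicator)
    rng = np.random.default_rng(config.seed) if rng is None else rng
    amp = config.amplitude_mean if amplitude is None else float(amplitude)
    t = protocol.times()
    signal = amp * _noiseless_signal(config, protocol, t)
    signal = signal + config.background_level
    if config.noise_sd_fraction > 0:
        signal = signal + rng.normal(0.0, config.noise_sd_fraction * amp,
                                     size=t.shape)
    return FluorescenceTrace(time=t, raw_intensity=signal,
                             indicator=config.indicator, protocol=protocol,
                             background=config.background_level,
                             roi_id=roi_id)


def draw_amplitudes(config: SimulationConfig, n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Per-bouton amplitudes: lognormal with the configured mean and CV."""
    if config.amplitude_cv == 0:
        return np.full(n, config.amplitude_mean)
    sigma2 = np.log(1.0 + config.amplitude_cv**2)
    mu = np.log(config.amplitude_mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


# ---------------------------------------------------------------------------
# videos
# ---------------------------------------------------------------------------

def _place_boutons(n: int, shape: tuple[int, int], min_dist: float,
                   margin: float, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample bouton centroids with a minimum pairwise distance."""
    h, w = shape
    pts: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 200 * n
    while len(pts) < n:
        if attempts >= max_attempts:
            density = n / ((h - 2 * margin) * (w - 2 * margin))
            raise RuntimeError(
                f"could not place {n} boutons at min_dist={min_dist:.1f}px in "
                f"{shape} after {max_attempts} tries "
                f"(requested density {density:.4f}/px^2 too high)")
        attempts += 1
        p = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        if all((p[0] - q[0])**2 + (p[1] - q[1])**2 >= min_dist**2 for q in pts):
            pts.append(p)
    return np.array(pts)


def simulate_video(config: SimulationConfig,
                   protocol: StimulationProtocol,
                   n_boutons: int = 25,
                   frame_shape: tuple[int, int] = (128, 128),
                   n_silent: int = 5,
                   footprint_sigma: float = 1.5,
                   min_distance: float | None = None,
                   ) -> tuple[TimeLapseVideo, GroundTruth]:
    """Render a time-lapse of Gaussian-footprint boutons.

    ``n_boutons`` responders follow the :func:`simulate_trace` time course;
    ``n_silent`` boutons stay at the resting surface level.  Per-pixel
    Gaussian read noise has SD = noise_sd_fraction * amplitude_mean.
    Returns the video (uint16) and the planted ground truth.
    """
    protocol.check_baseline(config.indicator)
    rng = np.random.default_rng(config.seed)
    n_total = n_boutons + n_silent
    if min_distance is None:
        min_distance = 6.0 * footprint_sigma
    margin = 4.0 * footprint_sigma
    centers = _place_boutons(n_total, frame_shape, min_distance, margin, rng)
    amps = draw_amplitudes(config, n_total, rng)
    responder = np.zeros(n_total, dtype=bool)
    responder[:n_boutons] = True

    t = protocol.times()
    signal_resp = _noiseless_signal(config, protocol, t)       # (T,)
    rest = config.resting_surface_fraction
    if config.indicator is Indicator.PHLUORIN:
        signal_silent = np.full_like(t, rest)
    else:
        signal_silent = np.full_like(t, 1.0 - rest)
    if np.isfinite(config.tau_bleach):
        signal_silent = signal_silent * np.exp(-t / config.tau_bleach)

    h, w = frame_shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    video = np.full((len(t), h, w), config.background_level, dtype=float)
    f0 = np.empty(n_total)
    for i in range(n_total):
        g = np.exp(-(((yy - centers[i, 0])**2 + (xx - centers[i, 1])**2)
                     / (2.0 * footprint_sigma**2)))
        course = signal_resp if responder[i] else signal_silent
        video += amps[i] * course[:, None, None] * g[None, :, :]
        f0[i] = config.background_level + amps[i] * course[0]
    if config.noise_sd_fraction > 0:
        video += rng.normal(
            0.0, config.noise_sd_fraction * config.amplitude_mean, video.shape)
    video = np.clip(np.round(video), 0, 65535).astype(np.uint16)

    truth = GroundTruth(
        boutons=pd.DataFrame({
            "bouton_id": np.arange(n_total),
            "row": centers[:, 0], "col": centers[:, 1],
            "amplitude": amps, "f0": f0, "responder": responder}),
        tau_endo=config.tau_endo, tau_bleach=config.tau_bleach,
        seed=config.seed)
    vid = TimeLapseVideo(frames=video, frame_interval=protocol.frame_interval,
                         protocol=protocol)
    return vid, truth


# ---------------------------------------------------------------------------
# STED synapse images
# ---------------------------------------------------------------------------

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # 1/2.3548


@dataclass
class SynapseLayout:
    """Planted geometry of one three-channel synapse image.

    Channel 0 is the presynaptic reference (Bassoon, active zone), channel 1
    the postsynaptic marker (Homer1), channel 2 the protein of interest.
    ``homer_offset`` is a signed distance (nm) along the synaptic axis in
    IMAGE coordinates (its sign decides which way the synapse faces);
    ``poi_offset`` is defined in the ORIENTED frame of the analysis, where
    the postsynaptic side is negative — a mirrored synapse (homer_offset >
    0) renders the protein of interest on the mirrored side accordingly.
    ``bassoon_position`` shifts the whole synapse relative to the image
    center.
    """

    bassoon_position: float = 0.0    # nm from image center along x
    homer_offset: float = -150.0     # nm, postsynaptic side
    poi_offset: float = 40.0         # nm, protein of interest
    poi_amplitude: float = 1.0       # relative to the reference channel
    cluster_sd: tuple[float, float, float] = (40.0, 40.0, 40.0)   # nm
    psf_fwhm: tuple[float, float, float] = (60.0, 60.0, 60.0)     # nm
    pixel_size: float = 18.9         # nm
    photon_scale: float = 200.0      # expected peak counts, Poisson noise

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if any(f <= 0 for f in self.psf_fwhm):
            raise ValueError("psf_fwhm must be > 0 per channel")
        if any(s <= 0 for s in self.cluster_sd):
            raise ValueError("cluster_sd must be > 0 per channel")
        if self.poi_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        for v in (self.bassoon_position, self.homer_offset, self.poi_offset):
            if not np.isfinite(v):
                raise ValueError("offsets must be finite")

    def rendered_sd(self, channel: int) -> float:
        """SD (nm) of cluster x PSF: sqrt(cluster_sd^2 + (fwhm/2.3548)^2)."""
        return math.hypot(self.cluster_sd[channel],
                          self.psf_fwhm[channel] * FWHM_TO_SIGMA)


def simulate_sted_synapse(layout: SynapseLayout,
                          image_shape: tuple[int, int] = (96, 96),
                          seed: int | None = 0,
                          ) -> tuple[np.ndarray, SynapseLayout]:
    """Render a three-channel synapse image with Poisson photon noise.

    Clusters are isotropic Gaussians convolved with per-channel Gaussian
    PSFs (rendered analytically as the combined Gaussian); the synaptic
    axis runs along image x through the center row.  ``seed=None`` disables
    noise.  Returns (image (3, H, W) float counts, layout) — the layout is
    the ground truth.
    """
    h, w = image_shape
    px = layout.pixel_size
    cy = (h - 1) / 2.0
    cx = (w - 1) / 2.0 + layout.bassoon_position / px
    # oriented frame: postsynapse negative; mirror the POI with the synapse
    orientation = -1.0 if layout.homer_offset > 0 else 1.0
    offsets_nm = (0.0, layout.homer_offset, orientation * layout.poi_offset)
    amplitudes = (1.0, 1.0, layout.poi_amplitude)

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    image = np.zeros((3, h, w), dtype=float)
    for c in range(3):
        x0 = cx + offsets_nm[c] / px
        sd_px = layout.rendered_sd(c) / px
        lo = 3.0 * sd_px
        if not (lo <= x0 <= w - 1 - lo and lo <= cy <= h - 1 - lo):
            raise ValueError(
                f"channel {c} cluster at x={x0:.1f}px (sd={sd_px:.1f}px) "
                f"is clipped by the {image_shape} image edge")
        image[c] = amplitudes[c] * np.exp(
            -(((xx - x0)**2 + (yy - cy)**2) / (2.0 * sd_px**2)))
    if seed is not None and layout.photon_scale > 0:
        rng = np.random.default_rng(seed)
        image = rng.poisson(image * layout.photon_scale).astype(float)
    else:
        image = image * max(layout.photon_scale, 1.0)
    return image, layout


# ---------------------------------------------------------------------------
# EM morphometry
# ---------------------------------------------------------------------------

STRUCTURES = ("svs", "elvs", "invaginations", "coated_pits", "coated_vesicles")


@dataclass
class MorphometryDensities:
    """Mean structure densities (count/um^2) and the bouton-area model."""

    svs: float = 92.2
    elvs: float = 2.0
    invaginations: float = 1.0
    coated_pits: float = 0.5
    coated_vesicles: float = 0.5
    bouton_area_mean: float = 0.5   # um^2
    bouton_area_cv: float = 0.4

    def __post_init__(self) -> None:
        for name in STRUCTURES:
            if getattr(self, name) < 0:
                raise ValueError(f"density {name} must be >= 0")
        if self.bouton_area_mean <= 0:
            raise ValueError("bouton_area_mean must be > 0")
        if self.bouton_area_cv < 0:
            raise ValueError("bouton_area_cv must be >= 0")


def simulate_morphometry(densities: MorphometryDensities,
                         n_synapses: int,
                         seed: int = 0) -> pd.DataFrame:
    """Sample per-synapse morphometry records.

    Bouton areas are lognormal with the stated mean/CV; each structure
    count is Poisson(density * area).  Returns one row per synaptic
    profile with columns ``synapse_id``, ``bouton_area`` and one count per
    structure.
    """
    if n_synapses < 1:
        raise ValueError("n_synapses must be >= 1")
    rng = np.random.default_rng(seed)
    if densities.bouton_area_cv == 0:
        areas = np.full(n_synapses, densities.bouton_area_mean)
    else:
        sigma2 = np.log(1.0 + densities.bouton_area_cv**2)
        mu = np.log(densities.bouton_area_mean) - sigma2 / 2.0
        areas = rng.lognormal(mu, np.sqrt(sigma2), size=n_synapses)
    out = {"synapse_id": np.arange(n_synapses), "bouton_area": areas}
    for name in STRUCTURES:
        out[name] = rng.poisson(getattr(densities, name) * areas)
    return pd.DataFrame(out)
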