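# Methods

`synapkit` quantifies presynaptic endocytosis kinetics from pH-sensitive
reporter recordings, nanoscale protein localization from three-channel
STED images, and synaptic ultrastructure from EM morphometry tables. Every
analysis stage has a matching seeded generator, so the whole pipeline can
be validated against planted ground truth without any raw-data download.

## Kinetic model of the reporter trace

The surface reporter pool S(t) — the fraction of the labeled vesicle-pool
protein residing on the plasma membrane above its resting level — follows
first-order retrieval with a uniform exocytic source during the action
potential (AP) train:

    dS/dt = E(t) − S/τ_endo,
    E(t)  = exo_fraction / duration   for stim_onset ≤ t < stim_end,
            0 otherwise.

This is the simplest model whose post-stimulus decay constant equals the
endocytic time constant τ the analysis estimates. Reacidification is
folded into τ_endo, which is appropriate for AP-train stimulation at
physiological temperature, where re-quenching after internalization is
fast compared with retrieval itself. pHluorin reports
S + resting_surface_fraction (surface pool fluorescent); CypHer5E reports
1 − S − resting_surface_fraction (intravesicular pool fluorescent). The
noiseless signal is multiplied by exp(−t/τ_bleach), scaled by a per-bouton
amplitude (lognormal across boutons), offset by the camera background, and
Gaussian noise with SD = noise_sd_fraction × amplitude is added.

The model deliberately excludes vesicle-pool substructure, calcium
dynamics and ultrafast (<1 s) endocytosis modes; it produces a single
mono-exponential decay because that is the quantity the constrained fit
extracts.

### Defaults and what they mean

| parameter | default | unit | rationale |
|---|---|---|---|
| τ_endo | 30 | s | typical control decay constant for vesicle-protein pHluorin probes under AP trains |
| exo_fraction | 0.2 | – | pool turnover per 200-AP train; gives ~2.8-fold peak ΔF/F₀ at rest fraction 0.1 |
| resting_surface_fraction | 0.1 | – | commonly reported surface-stranded fraction of vesicle proteins |
| τ_bleach | ∞ | s | no bleaching unless requested; 150 s emulates visible CypHer bleaching |
| amplitude_mean / cv | 1000 / 0.3 | counts | bouton-to-bouton expression spread |
| noise_sd_fraction | 0.05 | – | EM-CCD regime approximation: Gaussian, SD proportional to amplitude |
| acquisition | 50 frames @ 2 s | – | 0.5 Hz for 100 s; stimulus at 10 s (pHluorin) / 20 s (CypHer) |

Trace noise levels and amplitude distributions are calibration choices,
not measured facts; passing recovery tests therefore demonstrates
correctness of the estimators under these conditions, not performance on
any particular instrument.

## Trace quantification

Per video, the traces of all responding boutons are averaged per time
point, background-corrected, and (CypHer) bleach-corrected. F₀ is the
mean of the first 5 frames (pHluorin) or first 10 frames (CypHer),
regardless of stimulus timing. Surface normalization reports F/F₀ and the
fold increase (pHluorin) or the exocytic amplitude F₀ − F_min (CypHer).
Peak normalization forms ΔF = F − F₀ (sign-flipped for CypHer so both
polarities are positive-going) and divides by its maximum; ties on the
peak go to the earliest frame, and flat traces are rejected as
non-responders rather than fitted.

The averaging unit is the video (one normalized trace per video, each
averaging ≥ 20 boutons); per-bouton averaging is available behind a flag
but is biased at low SNR, because taking the maximum of a noisy trace
overestimates ΔF_max per bouton, uniformly shrinking the post-peak values
and dragging the constrained τ estimate low. Averaging raw traces first
cancels the noise before the maximum is taken.

### Decay fit

The condition-averaged normalized trace is fitted with
y(t′) = y₀·exp(−t′/τ) + offset under the constraints y₀ = 1 and
offset = 0, leaving τ as the only free parameter; t′ = 0 sits at the peak
frame — the only origin at which the constrained model can equal its peak
value of 1. The fit spans all frames from the peak to the end of the
recording. A coarse log-spaced scan over τ ∈ (frame_interval/10,
10 × recording length) seeds a bounded trust-region least-squares
refinement (xtol = ftol = 1e−12); estimates at a bound or non-converged
solutions are flagged, never silently reported. The standard error comes
from the Gauss–Newton curvature at the optimum. An independent
10,000-point grid search over the same bounds serves as a brute-force
cross-check in the tests, never as the fitting path.

### Photobleaching correction (CypHer)

The bleach baseline B(t) = b₀·exp(−t/τ_bleach) is fitted by least squares
to the first 10 frames (the 20 s before stimulation). Three corrections
are implemented:

- `ratio` (default): F_corr = F·B(0)/B(t), the exact inverse of a
  multiplicative bleaching process; leaves a signal-free baseline at the
  constant b₀ and recovers τ_endo exactly on noiseless input.
- `addback`: F_corr = F + [B(0) − B(t)], adding back the cumulative lost
  intensity. Also stationary on a signal-free baseline, but the stimulus
  deflection itself remains attenuated by B(t)/B(0), which biases the
  fitted τ toward 1/(1/τ_endo + 1/τ_bleach) (≈ −9% at τ_endo = 15 s,
  τ_bleach = 150 s).
- `literal`: F_corr = F + B(t).

The ratio form is the default because it is the internally consistent
inverse of the bleaching model; the additive forms reproduce the behavior
of common spreadsheet-style corrections. If the fitted τ_bleach exceeds a
configurable cap (default 10⁴ s) bleaching is negligible and the
correction is the identity.

### Responding-bouton detection

Difference image (mean of 5 post-onset frames minus mean baseline, signed
by indicator polarity) → Gaussian smoothing (σ = 1 px) → Otsu threshold →
connected components within area bounds (4–200 px) → per-component trace
check peak ΔF/F₀ ≥ 0.05. Two guards matter in practice: components must
also peak ≥ 5 robust SD above the median of the smoothed difference image
(otherwise Otsu on a response-free video simply splits the noise), and
videos yielding fewer than 20 responding boutons are flagged excluded —
the analysis floor of the assay — rather than analyzed.

## STED line-profile analysis

A 1.0 μm × 0.4 μm line perpendicular to the synaptic cleft is sampled at
the 18.9 nm pixel pitch (53 samples), averaging bilinearly interpolated
intensities across the width. Profiles are aligned so the presynaptic
reference (Bassoon) maximum sits at 0 nm and oriented so the postsynaptic
marker (Homer1) centroid lies at negative positions; the sign convention
is a package decision — the asymmetric integration window only makes
sense pointing away from the postsynapse. Localization uses per-channel
max-normalized profiles averaged across synapses (mean ± SEM on the
common grid). Presynaptic levels sum the raw protein-of-interest samples
over the closed window [−37.8, +151.4] nm — 11 grid samples, i.e. −2 to
+8 pixels — and are expressed as percent of the control-group mean.
Integration is a plain sample sum; any constant factor cancels in the
percent-of-control output.

The synthetic synapse renders the three channels as isotropic Gaussian
clusters convolved with per-channel Gaussian PSFs (drawn analytically as
the combined Gaussian, SD = sqrt(cluster_sd² + (FWHM/2.3548)²)) with
Poisson photon noise. The planted protein-of-interest offset is defined
in the oriented frame, so a mirrored synapse renders it on the mirrored
side; without this the offset would cancel over a population of mixed
orientations. The generator omits real-image nuisances — chromatic
offsets, anisotropic clusters, neighboring synapses, background
structures — so recovery tests validate the profile arithmetic, not
robustness to crowded fields. Line placement on real images is manual by
design.

The knock-in cluster measurement blurs both confocal channels (Gaussian,
σ = 2 px), binarizes each with Otsu's method, intersects the masks,
labels connected components and reports the mean STED intensity per
component; an empty intersection returns an explicitly flagged empty
table.

## EM morphometry and statistics

Per-synapse densities are count/area (count·μm⁻²) with mean ± SEM across
synapses; records with non-positive area are rejected with a report. The
generator samples bouton areas from a lognormal (mean 0.5 μm², CV 0.4)
and counts from Poisson(density × area), which makes count/area an
unbiased density estimator by construction.

The statistical decision logic: when total n > 100 or the number of
independent experiments N > 5, each group is screened with the
D'Agostino–Pearson K² test (α = 0.05, validity floor 8 observations per
group; below it the gate is skipped with an explicit flag). If any group
rejects normality the comparison routes to the non-parametric branch —
the conservative, deterministic resolution of what happens when groups
disagree. Tests by design: unpaired two-tailed t vs Mann–Whitney (two
groups), one-sample t vs one-sample Wilcoxon against the normalization
reference (single normalized group), one-way ANOVA + Tukey HSD vs
Kruskal–Wallis + Dunn's comparisons (≥ 3 groups). Mann–Whitney uses the
exact null distribution for small tie-free samples (product of group
sizes ≤ 400) and the tie-corrected normal approximation otherwise; an
exhaustive-enumeration oracle (all C(n₁+n₂, n₁) labelings, capped at 12
observations) validates it in the tests. Dunn's z statistics use the
pooled-rank variance with tie correction and Bonferroni adjustment over
all pairs (the most common convention; configurable). Degenerate inputs —
all-tied rank data, zero-variance ANOVA — raise explicit errors instead
of returning numbers.

## Problem sizes and reproducibility

The validation suite uses 128 × 128 px videos with 25 responding + 5
silent boutons, 8 videos × 30 boutons per condition, 100 synthetic
synapses per STED offset, 2,000 replicates for the type-I-error check and
100 seeded replicates for the two-condition directional check — sizes
chosen so planted effects are resolved with comfortable statistical
margin on a single CPU. All randomness flows through
`numpy.random.Generator` streams spawned from a single seed; reruns with
the same configuration are bit-identical, and `scripts/acceptance.py`
recomputes every headline quantity from scratch for any seed.

## Known limitations

- The trace model has one kinetic pool and one time constant; two-phase
  or stretched decays, drift, and focus changes are out of scope.
- Detection assumes stationary boutons (no registration) and a single
  shared background region per video.
- The STED analysis is 2-D and single-synapse per line; no deconvolution
  or chromatic correction.
- Statistics treat videos/synapses as exchangeable units; the
  video-bouton nesting is not modeled hierarchically.
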