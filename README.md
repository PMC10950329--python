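# synapkit

Quantification of presynaptic endocytosis kinetics and synaptic protein
organization, for neuroscientists analyzing live-imaging and
super-resolution data from cultured neurons.

When a neuron fires a train of action potentials, synaptic vesicles (SVs)
fuse with the presynaptic membrane and are retrieved by endocytosis.
pH-sensitive reporters make this optically measurable: pHluorin (a
pH-sensitive GFP on a vesicle protein's luminal domain) brightens on
exocytosis and re-quenches as vesicles are internalized and reacidified,
while CypHer5E has the opposite polarity. The post-stimulus decay of the
peak-normalized fluorescence deflection therefore reports the time course
of SV endocytosis, summarized by a single decay constant τ.

`synapkit` implements the full quantification chain:

- **Trace kinetics** — automated responding-bouton detection in
  time-lapse videos (difference image → Otsu → component filtering, with
  a ≥ 20 responders/video analysis floor), background correction, CypHer
  photobleaching correction from the pre-stimulus baseline, F/F₀ and
  ΔF/ΔF_max normalization, per-video averaging, and the constrained
  mono-exponential fit **y(t′) = y₀·e^(−t′/τ) + offset with y₀ = 1,
  offset = 0**, exposed statsmodels-style as
  `ExponentialDecayModel(...).fit() → DecayFitResults` with standard
  errors, diagnostics, `summary()` and `plot()`.
- **STED line profiles** — 1.0 μm × 0.4 μm line profiles perpendicular to
  the synaptic cleft at 18.9 nm sampling, aligned to the Bassoon maximum
  (0 nm) and oriented with Homer1 at negative positions; max-normalized
  localization averages, presynaptic-level integration over the closed
  [−37.8, +151.4] nm window, percent-of-control normalization, and the
  Otsu-masked knock-in cluster intensity measurement.
- **Statistics** — the normality-gated decision logic (n > 100 or N > 5 →
  D'Agostino–Pearson K² per group; any failure → non-parametric branch),
  with unpaired t / Mann–Whitney, one-sample t / Wilcoxon, ANOVA + Tukey
  and Kruskal–Wallis + Dunn, plus EM morphometry densities (count/μm²).
- **Synthetic data** — seeded generators for traces, videos, three-channel
  synapse images and morphometry tables with planted ground truth, so
  every stage is testable end to end. The kinetic model is first-order
  endocytosis dS/dt = E(t) − S/τ with uniform exocytic injection during
  the train.

## Worked example

Two simulated conditions with planted decay constants matching typical
control/perturbation magnitudes (29 s vs 56 s), eight videos of thirty
boutons each, analyzed end to end:

```python
from synapkit import (ConditionSpec, ExperimentConfig, SimulationConfig,
                      StimulationProtocol, run_pipeline)

cfg = ExperimentConfig(
    conditions=[
        ConditionSpec("DMSO", SimulationConfig(tau_endo=29.0), control=True),
        ConditionSpec("JLY", SimulationConfig(tau_endo=56.0)),
    ],
    protocol=StimulationProtocol.train_200ap(),  # 40 Hz, 5 s, 0.5 Hz frames
    seed=42)
report = run_pipeline(cfg)
for c in report.conditions:
    print(f"{c.label}: tau = {c.tau:.1f} s "
          f"(+/- {c.tau_sem():.1f} s SEM, n = {c.n_videos} videos)")
print(f"{report.stats['test']}: p = {report.stats['p_value']:.2e}")
```

prints

```
DMSO: tau = 29.2 s (+/- 0.7 s SEM, n = 8 videos)
JLY: tau = 55.6 s (+/- 1.5 s SEM, n = 8 videos)
t_unpaired: p = 2.48e-10
```

i.e. both planted constants are recovered within ~2% at 5% trace noise,
and the slowing of endocytosis in the perturbed condition is detected by
the unpaired t-test chosen by the gate. The fit itself reads like any
model/results pair:

```python
from synapkit import fit_decay, peak_normalize, simulate_trace
res = fit_decay(peak_normalize(simulate_trace(
    SimulationConfig(tau_endo=29.0, noise_sd_fraction=0.0, amplitude_cv=0.0),
    StimulationProtocol.train_200ap())))
print(res.summary())
```

```
Constrained one-phase decay fit  y(t') = exp(-t'/tau)
------------------------------------------------------
tau (s)               29.0000  +/- 0.0000
RSS               2.29903e-30
n post-peak pts            42
fit window       frames 8..49
converged                True
```

A `synapkit` command-line interface wraps the same functionality
(`simulate`, `analyze-traces`, `analyze-profiles`, `morphometry`,
`compare`, `run`); see `synapkit --help`.

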