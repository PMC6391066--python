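# v1gamma

Analysis pipeline for contextual modulation of firing and gamma-band
oscillations in primate primary visual cortex (V1), built for
electrophysiologists working with chronically implanted microelectrode
arrays and surface-stimulus paradigms. Uniform color surfaces drive strong
narrow-band gamma oscillations (~30–80 Hz) in the local field potential
(LFP) while sustained multi-unit (MU) firing falls below baseline; breaking
the center–surround predictability of the surface weakens gamma and elevates
firing. The package implements the full analysis chain behind such findings
— and a synthetic-session generator with ground truth, so every stage is
testable without any recorded data.

## What is implemented

- **Preprocessing** (`v1gamma.preprocess`) — LFP derivation from 24.414 kHz
  broadband (order-30 FIR, decimation by 24), 50/100/150 Hz band-stop with
  the exact two-pass 4th-order Butterworth magnitude response, MU envelope
  (300–6000 Hz band-pass → rectification → LFP low-pass contract), Gaussian
  rate smoothing (SD 20 ms), epoching.
- **Spectral estimation** (`v1gamma.spectral`) — DPSS multitaper power
  spectra (±5 Hz smoothing, K = 2TW − 1 tapers), baseline-total and
  fold-change normalizations, sliding Hann time–frequency maps, 100 ms
  Hann epochs zero-padded to 1 s.
- **Gamma-peak parameterization** (`v1gamma.gamma_peak`) — the core
  estimator. The detrended spectrum ΔP = ln P_stim − ln P_base (or a
  1/fⁿ-corrected raw spectrum) is resampled onto a log-spaced 20–140 Hz
  grid and fit with a polynomial whose order (1–20) is chosen by 50
  iterations of split-half cross-validation over trials. On the fitted
  curve, the peak frequency F_max is the highest local maximum in the
  search band (30–80 Hz), F_min the first local minimum to its left,
  bandwidth b = 2(F_max − F_min), and the amplitude is
  fit(F_max) − ½[fit(F_min) + fit(2F_max − F_min)], exponentiated to a
  fold-change (1 = no peak).
- **Spike–field coupling** (`v1gamma.coupling`) — pairwise phase
  consistency, PPC(f) = (|Σⱼ e^{iφⱼ}|² − N)/(N(N−1)), on per-trial
  modulus-normalized MU–LFP cross-spectra, restricted to direct grid
  neighbors at the same electrode depth.
- **Firing and behavior** (`v1gamma.firing`) — rate modulation
  log₁₀(M_stim/M_base), surround suppression vs the 0.5° size, the
  (A−B)/(A+B) modulation index on fold-changes, velocity-criterion
  microsaccade detection (threshold 6·c, c = Median[v²] − (Median[v])²),
  100 ms post-saccade censoring, pupil percent change (A−B)/|B|.
- **Statistics** (`v1gamma.stats`) — hierarchical bootstrap SEM
  (trials → channels → sessions → monkeys; B = 1000), bootstrap condition
  differences with Bonferroni correction, and max-statistic permutation
  tests with iterative step-down correction.
- **Colorimetry** (`v1gamma.colorimetry`) — DKL cone contrasts (L+M, L−M,
  S−(L+M)) and the cone-adaptation regression: each full-screen
  background's spectrum, projected onto normalized cone sensitivity
  curves, yields S/M/L adaptation coefficients that predict the red/green
  gamma ratio γ_ratio = log₁₀(γ_red/γ_green) by OLS.
- **Receptive fields** (`v1gamma.rf`) — RF ellipses from moving-bar
  back-projection (Gaussian profile fits, 10th/90th percentile points,
  least-squares ellipse; diameter 2·√(area/π)) and the electrode inclusion
  rules.
- **Synthetic sessions** (`v1gamma.synth`) — 1/fⁿ LFP background with
  condition-dependent narrow-band stochastic gamma, von Mises phase-locked
  inhomogeneous Poisson spiking with onset transients and below-baseline
  sustained rates, spike bleed-in, line noise, fixational eye traces with
  injected microsaccades, and pupil light responses — all with a
  ground-truth record per trial.

## Worked example

```bash
cd analysis
python 01_simulate_sessions.py     # sessions -> scratch/, tables -> results/
python 04_predictability_dissociation.py
```

prints, for a synthetic session with uniform-surface and center–surround
mismatch conditions:

```
gamma fold: uniform 2.48 vs mismatch 1.00; rate modulation: uniform -0.208 vs mismatch +0.224
dissociation recovered: gamma True, rate True; modulation index 1.000
8 significant bins, 48-62 Hz (max-statistic corrected)
```

The uniform surface shows a 2.5-fold gamma peak while sustained firing
drops to 10^(−0.21) ≈ 62% of baseline; the mismatch stimulus abolishes the
gamma peak (fold 1 = no peak) while firing rises 67% above baseline — the
two context signatures dissociate. The permutation test localizes the
spectral difference to 48–62 Hz, around the injected 55 Hz oscillation.
The remaining drivers cover hue/luminance tuning with spike-field PPC
(`02`), size tuning and surround suppression (`03`), the within-trial gamma
decay in dB (`05`), microsaccade and pupil controls (`06`), and the
cone-adaptation regression across full-screen backgrounds (`07`), e.g.

```
regression gamma_ratio ~ Madapt + Ladapt: M +0.37, L -0.11, intercept +0.013, R^2 0.93 (F-test p 0.00544)
```

A `v1gamma` console script exposes `simulate`, `analyze` and `report`
subcommands over the same pipeline.

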