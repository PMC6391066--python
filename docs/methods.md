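# Methods

This note documents the models, estimators and numerical choices in
`v1gamma`, and what the synthetic-data experiments do and do not establish.

## Signal model and preprocessing

Broadband extracellular voltage is modeled at the nominal digitization rate
of 24414.0625 Hz. The LFP is derived by zero-phase low-pass filtering
(Hamming-windowed sinc FIR, order 30, cutoff rate/48) and keeping every
24th sample (≈1017.25 Hz). Applying the FIR forward–backward removes its
group delay without changing the magnitude response; a single-pass
application would only shift all traces by a constant 15-sample delay.

Mains contamination is removed with 4th-order Butterworth band-stops at
49.9–50.1, 99.7–100.3 and 149.5–150.5 Hz, applied as the exact two-pass
magnitude response |H(f)|² in the frequency domain. These notches are
0.2–1 Hz wide, so their impulse responses ring for seconds; sample-domain
two-pass filtering of epoch-length traces would leave boundary transients
larger than the line component being removed, whereas the spectral product
realizes the identical steady-state zero-phase response at any trace
length (3.4% residual on a 10 s 50 Hz tone; <10⁻⁴ relative change to white
noise outside the stop bands).

The MU envelope is band-pass (300–6000 Hz, Butterworth order 4,
forward–backward), rectification, then the same low-pass/decimation
contract as the LFP, with residual negative ripple clipped to zero. Rate
traces are smoothed with a unit-mass Gaussian kernel (SD 20 ms, truncated
at ±4 SD, edge-renormalized). Epochs are cut by sample index with the
length fixed as round(duration × rate), so equal windows always produce
equal-length segments.

## Spectral estimation

Power spectra of 0.5 s (baseline; stimulus sub-epochs) or 0.3 s
(short-presentation designs) epochs use DPSS multitapers with ±5 Hz
half-bandwidth; the taper count follows the Shannon-number convention
K = ⌊2TW⌋ − 1 (4 tapers at 0.5 s, 2 at 0.3 s). Estimates are one-sided
densities in arbitrary units satisfying Parseval; absolute units are never
needed because every downstream quantity is a ratio. Two normalizations are
provided: division of all of an electrode's spectra by its total baseline
power above a configurable floor (default 25 Hz; 20 Hz is equally
supported, as the two conventions coexist in the field), and per-trial
fold-change against the condition-averaged baseline spectrum, with a dB
view for time–frequency maps (0.3 s Hann windows, 50 ms steps). Epochs of
100 ms (used after microsaccade censoring) are Hann-tapered and zero-padded
to 1 s, which interpolates the spectrum to a ~1 Hz grid without adding
power; such spectra are interpreted only above 20 Hz.

## Gamma-peak parameterization

The central estimator quantifies narrow-band gamma against two confounds:
broadband rate-driven power shifts, and spike energy bleeding into high LFP
frequencies. The detrended quantity is ΔP = ln P_stim − ln P_base on a
64-point log-spaced grid over 20–140 Hz (log spacing prevents the dense
high-frequency bins from dominating the fit). The polynomial order is
selected from 1–20 by 50 iterations of split-half cross-validation over
trials: each iteration fits every order to the training-half mean and
scores it on the test-half mean, ties going to the lower order; the median
best order (rounded down at half-integers) is then fit to the all-trial
mean. On that fit, local maxima in the 30–80 Hz search band (30–150 Hz wide
option) define the peak: F_max is the highest one, F_min the first local
minimum to its left, bandwidth b = 2(F_max − F_min), and the amplitude is
the fitted value at F_max minus the average of the fit at F_min and at the
flank point mirrored about the peak, 2F_max − F_min. The amplitude is
computed in natural log and exponentiated to a fold-change; the flank-point
convention is configurable (the mirrored point is the default because it is
the only reading consistent with the bandwidth definition). When no local
minimum exists left of F_max, F_min falls back to the search-band edge and
the result is flagged.

Two honesty rules classify a fit as "no peak" (fold-change 1): a maximum
unaccompanied by any local minimum in the fit range is bare low-order
curvature, not band-limited structure; and a fitted amplitude below twice
the standard error of the mean ΔP is indistinguishable from sampling noise.
On structureless spectra these rules yield a no-peak rate above 90% while
never discarding genuine bumps of realistic size.

For designs without a neutral baseline, the raw spectrum is corrected by an
aperiodic fit over 20–140 Hz excluding 30–80 Hz. The default model is
log₁₀P(f) = a + b·log₁₀f + d·exp(c·f): the log-log-linear part represents a
pure power law exactly, and the exponential term absorbs the high-frequency
upturn that spike bleed-in produces — the reason a plain log-log line is
inadequate. The rate c is profiled (coarse grid then bounded scalar
minimization) with the linear coefficients solved in closed form; a pure
a + b·exp(c·f) variant and the plain log-log line are available for
comparison, and non-convergence is flagged, never silently replaced.

## Spike–field coupling

Phase locking uses the pairwise phase consistency, the mean over unordered
trial pairs of cos(φⱼ − φₖ), computed as (|Σe^{iφ}|² − N)/(N(N−1)) from
per-trial taper-averaged, modulus-normalized MU–LFP cross-spectra. PPC is
unbiased by trial count (its expectation equals (I₁(κ)/I₀(κ))² for von
Mises phases at any N ≥ 2), which the calibration experiments verify.
Pairs are restricted to direct (4-neighborhood) grid neighbors at the same
electrode depth; same-electrode pairs are excluded because bleed-in
produces artifactual coherence. Per MU site, PPC is averaged over its valid
LFP partners. Error bars for PPC are plain SEM across sessions — bootstrap
resamples repeat identical trials and trivially inflate phase consistency.

## Firing, eye movements, pupil

Rate modulation is log₁₀(M_stim/M_base); surround suppression is the drop
in rate modulation relative to the 0.5° stimulus. Gamma amplitudes A, B
(fold-change − 1) are compared with the modulation index (A−B)/(A+B),
defined as 0 when both are 0; fold-changes below 1 are clamped to 1 with a
warning, since a fold below 1 means no peak.

Microsaccades are detected per axis from gaze smoothed with a ±5 ms boxcar
(edge-replicated padding — zero padding would fabricate velocities at trace
boundaries) and differentiated over 10 ms. The criterion is implemented
exactly as the variance-like c = Median[v²] − (Median[v])², threshold 6·c,
crossings on either axis, contiguous and near-coincident (≤10 ms) samples
merged; a degenerate axis (c = 0) is excluded. Because c has units of
velocity squared, the threshold-to-noise ratio scales with the noise level;
the generator's tracker noise (0.05°/sample, typical of video
oculography) places the detector in the regime where the multiplier 6 gives
high recall and a negligible false-alarm rate, as it evidently did for the
original recordings. The multiplier is a parameter. After each event,
100 ms of data are censored and the remainder re-tiled into 100 ms epochs.
Pupil responses are (A−B)/|B| relative to the 200 ms pre-onset baseline;
tracker units can be negative, and the absolute denominator keeps
constrictions negative.

## Resampling statistics

The bootstrap (B = 1000) resamples N trials with replacement within each
condition × session cell, computes the statistic per channel, then
aggregates: the LFP path averages channels within a session (they are
volume-conduction dependent), sessions within a monkey, then monkeys with
equal weight; the MU path averages each site over its sessions, then over
sites. SEM is the SD of the B aggregates. Condition differences use the
bootstrap difference distribution with a z-test (difference over bootstrap
SD); counting tail bootstraps directly is too coarse at Bonferroni-level
per-comparison alphas and measurably anticonservative, while the z-form is
calibrated (verified at α/k = 0.005). The percentile p remains available.

Frequency/time-resolved comparisons use label permutations after seeded
trial-count equalization: the critical value is the 95th percentile of the
per-permutation maxima of absolute mean differences; significant bins are
removed from the observed and every permutation distribution and the
criterion recomputed until nothing exceeds it. The default is this strict
family-wise step-down (measured family-wise error ≈ 0.05 on null data); the
FDR parameter is recorded with the results for provenance, as its exact
interplay with alpha in the original correction is ambiguous.

## Colorimetry and the adaptation model

DKL coordinates follow the Weber cone-contrast construction: w =
(stim − bg)/bg per cone, projected as L+M = (w_L + w_M)/2, L−M = w_L − w_M,
S−(L+M) = w_S − (w_L + w_M)/2. Axis scaling conventions vary across labs;
this matrix is recorded in output metadata and configurable.

Cone sensitivity curves are order-7 polynomial fits to tabulated
sensitivities, normalized to maximum 1, clipped at 0, and zeroed outside
each cone's tabulated support so polynomial extrapolation wiggles cannot
reintroduce sensitivity where a cone is silent. The bundled fundamentals
are synthetic — log-Gaussian lobes at the standard macaque S/M/L peak
wavelengths — constructed as a stand-in for measured bleaching-difference
spectra, which are not redistributable here; measured tables drop in via
`fit_cone_curves`. A background's adaptation coefficients are wavelength-
wise inner products of its unit-mass spectrum with the cone curves (only
the scalar projection is used downstream, so no sliding convolution is
involved). The adaptation regression is OLS with intercept of γ_ratio =
log₁₀(γ_red/γ_green) on {M, L} (red-green), {S, L} (blue-yellow), or all
three.

## Receptive fields

Moving-bar responses are back-projected onto the screen after a latency
shift. A pure amplitude criterion cannot identify the latency of a
full-field bar (the profile shape is latency-invariant), but opposite
motion directions are displaced oppositely, so the latency is chosen to
maximize the coherence of the back-projection — minimal inconsistency of
the per-direction Gaussian-profile centers with a single RF center. Each
direction contributes the 10th/90th percentile positions of its fitted
Gaussian (of the fitted curve, not raw response mass — configurable),
placed along its motion axis; a direct least-squares conic fit constrained
to an ellipse defines the RF, with diameter 2√(area/π) (the only reading
of the printed area-to-diameter rule that yields degrees from deg²). Site
inclusion requires RF-stimulation responses 2 SD above outside-RF
stimulation, an evoked response 2 SD above baseline in ≥1 condition, and
an RF-center-to-stimulus-center distance rule per analysis type.

## Synthetic sessions: what they emulate, and what not

Trials are 0.5 s baseline + 1.3 s stimulus by default. The LFP is Gaussian
1/fⁿ noise (n = 2 by default, flattened below 2 Hz) with a known analytic
density, plus a gamma component built by band-passing white noise at the
condition's peak ±5 Hz — giving realistic bandwidth and stochastic phase —
scaled so its density at the peak is `gamma_amplitude` times the background
density there, gated by the stimulus with exponential within-trial decay
(0.3 s⁻¹ default), plus 50/100/150 Hz lines and a biphasic ~1.5 ms
spike-bleed kernel convolved with the same channel's spikes. The gamma
component is shared across the small electrode grid (volume conduction);
backgrounds are channel-private. Spikes are an inhomogeneous Poisson
process (baseline 20 sp/s; transient 80 sp/s at 40 ms latency; sustained
level that may fall below baseline) with a normalized von Mises gain on
the instantaneous gamma phase, so the expected count is the integral of
the rate; the MU envelope applies the preprocessing rectify+low-pass
contract to the spike train. Eye traces are drift plus tracker noise with
step-plus-overshoot microsaccades (20 ms, 0.05–0.5°) at known times; the
pupil constricts sigmoidally after onset in negative tracker-like units.
One seeded generator per session is split per trial by counter, making
output bit-identical under a fixed seed and stable under reordering.

Extracted fold-changes are estimator-scale quantities: taper smoothing,
the within-trial decay and the flank-average baseline compress them
relative to the injected density ratio, so recovery experiments test
ordering, monotonicity and calibration of uncertainty — not absolute
amplitude equality. The generator is Gaussian and stationary within
epochs; it does not emulate cross-frequency coupling, non-Poisson spiking
statistics, electrode drift, or eye-movement-locked LFP transients, so
passing tests demonstrate correctness of the estimators under the stated
model, not robustness to every pathology of real recordings.

## Problem sizes

The validation experiments run at: 3 analytic curves for the gamma-peak
oracle; 200 runs × 100 trials (closed-form PPC) and 2000 runs (trial-count
bias); 100 sessions × 2 conditions × 10 trials for the dissociation; 50
replicates of n = 100 (bootstrap SEM) and 400 experiments × 50 bins ×
1000 permutations (permutation calibration); 200 trials (detector); 30
trials (censoring); 16 backgrounds (adaptation recovery). The analysis
drivers use 12-trial, 4-channel sessions. These sizes make the full suite
and the acceptance script each run in a few minutes on one core while
keeping Monte-Carlo standard errors well inside the asserted tolerances.
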