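# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `avihrf`.

## HRF model

The hemodynamic response is modeled as a difference of two gamma
*densities* convolved with the stimulus boxcar:

    h(t) = A · [ g(t; α₁, β₁) − c · g(t; α₂, β₂) ],  t ≥ 0
    g(t; α, β) = t^(α−1) β^α e^(−βt) / Γ(α)

β is a **rate** (1/s), matching the β^α e^(−βt) numerator; with the pigeon
parameters this puts the response-lobe mode at (α₁−1)/β₁ ≈ 3.9 s and the
boxcar-convolved peak at 4.94 s, consistent with the observed 4.5–5.5 s
window. Each lobe is normalized by its own Γ(α), so each is a unit-mass
density and the kernel integrates to A·(1−c); this is the only
normalization under which c is a genuine undershoot-to-response ratio.
(`strict_normalization=True` divides both lobes by Γ(α₁) instead; with the
pigeon parameters that inflates the undershoot by roughly e⁷ and is
provided only for comparison.) The fitted amplitude A is reported but its
absolute scale carries no information for GLM use, where regressors are
scale-invariant up to the units of β.

A note on widths: the FWHM of the *continuous* model response at the
pigeon point estimates is 3.76 s. Widths measured on TR-sampled response
curves (TR = 2 s, linear interpolation between samples) read systematically
broader (≈ 4.5 s for the same model), which is the regime in which
empirical HDR widths of 4–6 s are observed. `hdr_features` reports the
width of whatever curve it is given; the two numbers differ because the
measurement grids differ, not because of an implementation discrepancy.

Convolution is a direct discrete sum at the sampling resolution (curves are
a few thousand samples; no FFT needed). Feature extraction defaults:
dt = 0.01 s, t_max = 30 s — peak/width errors are then far below reporting
precision. W is the width of the main positive lobe only (half-maximum
crossings located by linear interpolation, searched outward from the peak);
the undershoot is excluded.

## HRF fitting

`fit_hrf` minimizes Σ(y − model)² over (A, α₁, α₂, β₁, β₂, c) with
`scipy.optimize.least_squares` (trust-region reflective) inside bounds
α₁ ∈ [2, 14], α₂ ∈ [2, 25], β₁ ∈ [0.2, 4], β₂ ∈ [0.1, 3], c ∈ [0, 1],
A > 0. The bounds contain both the human canonical and pigeon parameter
sets with wide margin. Because the (α₁, β₁) ridge is flat (they trade off
while preserving the peak time), the fit is multi-started: the human
canonical init plus 9 log-uniformly jittered variants; the best-RSS
converged solution wins, and RSS is non-increasing in the number of starts.
95% CIs come from the linearized covariance σ²(JᵀJ)⁻¹ at the optimum with
a t critical value at n − 6 dof. Estimates within 1e−6 of a bound are
flagged in `at_bounds`. The model is evaluated on the data's own time grid
when that grid is ≤ 0.1 s, so noiseless model-generated curves are fitted
exactly; for TR-sampled curves it is evaluated at dt = 0.02 s and
interpolated.

Single-replicate parameter estimates scatter widely along the α/β ridge —
this is why reported parameter CIs are wide — so recovery is assessed on
means over replicates (30–50 seeds), which land well inside the reported
CIs, and single-run checks assess curve-shape recovery (correlation,
time-to-peak) instead of point identity.

## HDR extraction

Per run: the ROI-mean time course is detrended by projecting out Legendre
polynomials of degrees 1..2 (the mean is deliberately retained so the
pre-stimulus baseline stays meaningful — projecting out degree 0 would
make the percent-signal-change denominator near zero), then converted to
per-trial percent signal change, 100·(x − b)/b with b the mean of the 2 s
before onset, over a 0–28 s peri-stimulus epoch; trials whose epoch runs
past the end of the run are dropped with a warning. Trial curves are
averaged within run, run averages are averaged with equal weight (the
appropriate weighting across runs/subjects with unequal usable-trial
counts is not identified; equal weight is the simplest defensible choice),
and the SEM across runs is attached per time point.

## Preprocessing

* **Smoothing**: per-volume 3D Gaussian, σ = FWHM/(2√(2 ln 2)) per axis in
  voxel units, reflective boundary, kernel truncated at 4σ (preserves the
  spatial sum). The conventional "FWHM 8 mm after 10× voxel upscaling" is
  pure metadata relabeling: it equals 0.8 mm at native 0.47 × 0.47 × 1 mm³
  voxels, and smoothing is done in native units.
* **Grand-mean scaling**: one multiplicative factor per run bringing the
  4D in-mask mean to 10000 (idempotent, contrast-preserving).
* **High-pass**: regression on a DCT-II basis restricted to periods longer
  than the cutoff, mean restored. This approximates FSL's Gaussian-weighted
  running line with a linear operator whose frequency response is easy to
  verify: >90% attenuation at 5× the cutoff period, >90% pass at one third
  of it. Task analysis uses a 60 s cutoff; tSNR uses 100 s.
* **tSNR**: temporal mean / temporal sd per voxel, computed after the
  caller applies the 100 s high-pass and smoothing; zero-variance voxels
  get a +inf sentinel rather than being dropped, preserving map geometry.
* **MAD**: median(|Xᵢ − median(X)|), no consistency scaling.

Motion correction and slice-timing correction are out of scope: the
synthetic data is generated aligned, and the motion traces exist to be
*regressed*, not corrected.

## Task GLM and inference

`build_design_matrix` expands stimulus trials plus behavioral labels into
the seven condition regressors. Epoch conventions: stimulus window 2 s
(Hit/Miss/CR/FA by label); reward 1 s starting 0.8 s after stimulus offset
(hits only); post-reward 4 s after reward offset for rewarded trials and
5 s after stimulus offset for unrewarded ones (Miss trials are treated
like NoGo here — the enumeration only specifies rewarded and NoGo cases,
and the unrewarded-Go case is structurally identical to NoGo);
mandibulation onsets as impulse events only outside each trial's
stimulus-to-post-reward span. Regressors are built on a 0.1 s grid,
convolved with the pigeon HRF, and decimated to the TR grid (sub-TR onset
fidelity matters with jittered designs). Empty condition columns are
dropped and recorded; contrasts referencing them fail loudly. Motion
columns are demeaned; an intercept closes the design.

OLS is fitted per voxel; t statistics are mapped to z through matched tail
probabilities of the t and normal distributions (|z| capped at 40).
Thresholding is one-sided, matching the directional named contrasts.

Cluster inference is permutation-based rather than Gaussian-random-field:
on small grids GRF smoothness estimation is unreliable, while the max
cluster-size permutation null is exact by construction. First level: sign
flips of whole residual volumes, refit against the full design (valid
under symmetric exchangeable noise). Group level: a one-sample t across
subject maps with whole-map sign flips (the mixed-effects model used by
FSL for group inference is deliberately not reimplemented; the
summary-statistics test applies the same decision rule, z > 3.1 with
cluster-FWE 0.05). A cluster survives when (1 + #{null max ≥ size}) /
(n_perm + 1) ≤ α. Because cluster sizes are integers, the test is slightly
conservative; on desk-scale grids at cluster-forming z = 3.1 with few
subjects the null max-size distribution degenerates to 0 and achieved FWE
is far below nominal, so FWE calibration is demonstrated at cluster-forming
z = 2.0 where the distribution is non-degenerate (measured ≈ 0.02–0.03
against α = 0.05 over 200 null datasets).

The named contrast `go_gt_nogo_plus_mandibulation` uses weights
(½, ½, −⅓, −⅓, −⅓) over (Hit, Miss, CR, FA, mandibulation). Note that the
mandibulation impulse regressor has low energy, so any contrast mixing it
carries inflated variance; at realistic single-run effect sizes the
differential Go-vs-NoGo map is underpowered (which is precisely why group
inference exists). Active-region recovery is therefore demonstrated with
the omnibus `task_gt_rest` contrast.

## Behavior

Event detection: differential channel (signal − reference, cancelling
common-mode artifacts) → robust z (median / 1.4826·MAD) → trailing RMS
envelope over 150 ms → upward crossings of z = 3, merged within a 100 ms
refractory period. The envelope step is what makes a z = 3 criterion
meaningful at kHz sampling: thresholding raw samples at 3σ would fire
constantly on noise, whereas the envelope of pure noise concentrates near
1 and crossings of 3 are rare (< 1 false event/min measured).

Classification uses only the stimulus window [onset, onset + 2 s); RT is
the first in-window event minus onset. d′ uses the log-linear correction
(add 0.5 per cell, 1 per denominator) by default so perfect sessions stay
finite; `correction="none"` gives the uncorrected value.

## Synthetic data generator

The generator reproduces the study conditions: TR 4 s discrimination runs
(rest 600 s / 72 trials / rest / 72 trials / rest; 2 s stimulus, 0.8 s
reward delay, 1 s reward; four equiprobable color-by-intensity conditions,
exactly balanced; 1170 volumes, 78 min) and TR 2 s HRF runs (30 pre
volumes, 30 trials of 2 s + 28 s, 10 post volumes, 490 volumes, 15 trials
per color). ITI jitter is a random permutation of an evenly spaced grid on
[12.2, 20.2] s, so the mean ITI is exactly 16.2 s and run length — hence
volume count — is deterministic, as it must be for fixed-length runs;
i.i.d. uniform jitter could not reproduce a fixed 1170-volume run. The
4 s/5 s post-reward windows overlap the start of the ITI (required for
144 × 20 s + 30 min to equal 78 min).

BOLD forward model: a 16×16×4 voxel grid at nominal 0.47 × 0.47 × 1 mm³
(desk-scale but preserving the real voxel geometry for smoothing/MAD
units) with an ellipsoidal active region. Active voxels carry
baseline·(1 + Σ βᵢ·rᵢ(t)/100), where each condition regressor rᵢ is the
HRF-convolved condition boxcar scaled by one common factor (the peak of a
single isolated stimulus-length event), so βᵢ is the peak percent signal
change an isolated event would evoke and relative regressor scales match
the analysis design exactly. Noise is independent per voxel: AR(1)
(φ = 0.3) driven by white innovations, plus a 120 s-period sinusoidal
drift with random phase — the minimal structure that exercises high-pass
filtering. The innovation sd (18 at baseline 1000) is calibrated so the
in-mask median tSNR of a default run, measured after the 100 s high-pass
and smoothing, falls mid-range in the observed 110–220 telencephalic
band (≈ 140). The default true-voxel response amplitude for HRF runs is
2.0% peak PSC: smoothing and ROI averaging dilute the measured
ROI-average response by roughly 40%, putting the *measured* curve near
1.0%, the middle of the observed 0.8–1.5% range. For task runs the default
condition betas (Hit 1.5, Miss 1.2, CR 0.4, FA 0.5, reward 1.0,
post-reward 0.6, mandibulation 0.4 %PSC) encode a Go-preferring active
region at the same order of magnitude.

Motion: Gaussian-smoothed random walks rescaled to a random 60–100% of the
bound (0.048 mm translation, 0.045° rotation — the observed maxima), so
bounds hold in every draw. Rotations are stored in radians, translations
in mm, in the 6-column FSL `.par` layout.

Piezo: 1000 Hz two-channel traces sharing low-frequency common-mode noise;
mandibulation bursts are 20 Hz damped oscillations of 150 ms on the signal
channel only (the real burst morphology and the sensor's amplitude units
are not specified anywhere; this is a plausible synthetic signature).
Go responses occur with probability 0.9 at truncated-normal latency
0.9 ± 0.4 s, false alarms with probability 0.1 at 0.7 ± 0.5 s, both
truncated to [0.05 s, window end] — so realized FA latency means sit
slightly above 0.7 s; drinking bursts follow rewards at 3 Hz; spontaneous
mandibulations occur at 0.05 Hz outside stimulus windows (outside so the
generator's trial labels remain exact ground truth). Every generator is a
pure function of (spec, seed).

What the generator does *not* emulate: susceptibility and eye-movement
artifacts, physiological (respiration/cardiac) noise, spatially correlated
noise, head motion actually displacing the image (traces are nuisance
regressors only), k-space/sequence effects, and attentional drift across a
session. Passing tests therefore show the *analysis* is correct under its
own assumptions at realistic SNR; they do not show robustness to artifact
classes the generator omits.

## Problem sizes used in tests

Simulations are scaled to what the checks need: full-size runs (1170/490
volumes, 16×16×4) for bookkeeping, tSNR and end-to-end detection; reduced
grids (10×10×2, 12×12×3) and 20–50 replicates for calibration and recovery
experiments; 500 permutations (the floor for stable tail quantiles at
α = 0.05) for cluster inference. The acceptance script's refit experiment
uses 50 replicates of 15-point TR-sampled curves with noise sd at 5% of
peak, emulating the precision of a 60-trial average.

## Known limitations

* No prewhitening: OLS with AR(1) noise gives slightly optimistic
  first-level variance estimates; permutation inference at cluster level
  does not rely on them being exact.
* The DCT high-pass and Legendre detrend orders approximate, not
  replicate, FSL's filters; their frequency responses are verified
  directly instead.
* d′ correction choice (log-linear) and the mandibulation-rate denominator
  (raw count per 2 s window, with a per-second convenience conversion left
  to the caller) are conventions chosen where no formula was specified.
* Group inference assumes symmetric subject effects (sign-flip
  exchangeability), not the full mixed-effects variance partitioning.
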