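# Methods

`teptools` implements a complete TMS-EEG cortical-excitability analysis —
sensor field power, spherical-head source imaging with permutation
significance, and mixed-model condition inference — together with a
synthetic session generator that provides ground truth for every stage.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic validation does and does not establish.

## Recording model and geometry

The emulated recording is a 60-channel TMS-compatible EEG cap sampled at
1450 Hz; epochs span −800..+800 ms around each TMS pulse, with roughly 180
pulses per block and three blocks per subject (before, during and after
neuromodulation of the right posterior parietal cortex).  Electrode
positions come from the standard 10-10 template (the 60-label subset used
by such amplifiers), re-centred on their best-fitting sphere and projected
radially onto a unit sphere.  Two cap positions, P2 and CP2, are treated
as missing — in the emulated protocol they are removed to make room for
the tDCS cathode — and are reconstructed by interpolation.

The head is three concentric shells with homogeneous conductivities.  No
shell radii or conductivities are prescribed by the protocol being
emulated, so the defaults follow common EEG practice: scalp/outer-skull/
inner-skull radii 92/85/81 mm and conductivities 0.33/0.0042/0.33 S/m
(skull ≈ 1/80 of soft tissue).  The cortex is a Fibonacci lattice of 3004
radially oriented dipoles (812 in reduced mode) on a sphere of radius
**76 mm**.  The source shell sits ~5 mm below the inner skull because the
forward series truncated at the default 60 Legendre terms is then
converged to better than 1e-4 of each topography's peak; a shell hugging
the skull would need a much longer series for the same accuracy.  An
optional normal-tilt parameter adds angular jitter to emulate folded
cortex; the default is purely radial.

Four angular caps stand in for the parcels used in local source analysis:
posterior-superior caps for left/right superior parietal cortex (BA7) and
dorsal-anterior caps for left/right premotor cortex (BA6).  Cap centres
are exact left/right mirror pairs and the 18° half-angle keeps the four
caps pairwise disjoint; both the centres and the half-angle are
configuration values.

## Forward model

The scalp potential of a dipole inside layered spheres is computed from
the exact Legendre expansion: for each degree *n* the radial profile in
every shell is `a r^n + b r^-(n+1)`; continuity of potential and radial
current at the two internal interfaces plus zero current through the
scalp gives a 5×5 linear system per degree whose solution yields the
surface gain `g_n`.  The per-degree systems are solved with column
equilibration so the computation stays well-conditioned up to several
hundred degrees.  With equal conductivities the gains reduce analytically
to `(2n+1)/n` and the series sums to the classical closed form for a
dipole in a bounded homogeneous sphere; the test suite and the
reproduction script verify the implementation against that closed form to
1e-6 relative over random dipoles.  Lead fields are average-referenced
(every column sums to zero).  Units are chosen so that positions in mm,
conductivities in S/m and dipole moments in nA·mm give potentials in µV.

## Synthetic sessions

Each subject is drawn from template priors: three evoked components — an
early (~25 ms) patch under the left-parietal TMS hotspot, a middle
(~60 ms) contralateral parietal patch, and a late (~100 ms) bilateral
frontal patch — each a Gaussian-tapered source patch (15 mm radius) whose
time course is a Gaussian pulse with per-subject latency and amplitude.
Amplitude priors (20000/16000/24000 nA·mm ± ~20%, the late component
largest — in real TEPs the ~100 ms deflection dominates) were set so that
evoked scalp peaks land in the 2–5 µV range conventional for TMS-evoked
potentials and every analysis window carries genuine evoked signal; the
protocol itself prescribes no amplitude scale.  A
condition gain multiplies all source amplitudes: gain 1 everywhere is the
null (no-modulation) scenario; gain > 1 during/post emulates an
excitability increase.  Within a subject the three blocks share identical
generative amplitudes — only the gain and the noise realizations differ.

Trial noise is per-channel-independent 1/f ("pink") noise with 12 µV
standard deviation per sample (flattened below 1 Hz); no channel
correlation is modelled.  A configurable fraction of trials (default 0.3)
carries an artifact: ocular trials get a slow ~150 µV frontal Gaussian
deflection, muscle trials a 60–300 Hz burst of ~60 µV on a lateral
temporal channel group.  The TMS pulse/decay artifact is *not* simulated:
the emulated amplifier gates it, so epochs are already clean at the pulse
sample.  Everything is driven by seed sequences: `(seed, config)` →
bit-identical output.

What this generator does **not** emulate: realistic cortical folding and
source orientation structure, spatially correlated background EEG,
between-block drifts (electrode impedance, vigilance), or biophysical
tDCS current flow.  Passing calibration on this generator therefore shows
the *pipeline logic* is correct and calibrated under its stated
assumptions, not that effect sizes would transfer to real recordings.

## Preprocessing

The chain follows standard TMS-EEG practice, in this order: downsample
1450 → 725 Hz (zero-phase 8th-order Butterworth anti-alias at 0.45×target,
then decimation preserving the pulse sample); deterministic artifact
rejection; trial averaging; zero-phase 3rd-order Butterworth band-pass
2–40 Hz; spherical-spline reconstruction of the bad channels; average
reference; baseline correction over −300..−50 ms.  Each `Evoked` carries
a `processing_log` and every step validates its position in the chain, so
an out-of-order call raises instead of silently producing a different
analysis.  All windows are half-open `[a, b)` in ms with 0 at the pulse.

Manual trial screening is replaced by three thresholds: any sample beyond
100 µV; any frontal (EOG-proxy) sample beyond 70 µV; any channel whose
power fraction above 40 Hz exceeds 0.5.  The high-frequency rule is meant
to run at the analysis rate (725 Hz); at the raw 1450 Hz the wider noise
bandwidth already puts pink noise near the threshold.  At default
settings the rejection recovers ≥ 90% of ground-truth artifact trials
while keeping ≥ 95% of clean ones, and retains ≈ 120 of 180 trials per
block — the plausible operating range for such recordings.

Bad-channel interpolation is a spherical spline (order m = 4, Legendre
series truncated at 50 terms).  The ridge on the spline system defaults
to 1e-8: it is there only to guard conditioning.  A heavier ridge
(e.g. 1e-5) visibly shrinks topography peaks — leave-one-out errors of
>10% at the peak channel — while 1e-8 keeps the leave-one-out error of
smooth dipolar topographies under 5% of the peak for all interior
channels.

## Field power

GMFP(t) is the per-sample spatial standard deviation across channels with
the population (1/K) convention; it is invariant to any common per-sample
offset and absolutely homogeneous under scaling.  LMFP applies the same
formula within a 4-electrode cluster, taking deviations from the
cluster-local mean by default (`local_mean=False` switches to the global
mean; the two differ only through the local/global mean choice and the
default follows the local reading of "same procedure").  The clusters are
left parietal (TMS hotspot: CP1, CP3, P1, P3), right parietal (under the
cathode: CP2, CP4, P2, P4), and left/right frontal (F1, F5, FC1, FC3 /
F2, F6, FC2, FC6).  Traces are cumulated over 0–50, 50–100 and 100–150 ms
as rectangular sums (Σ value × Δt, µV·ms); the Δt factor is a monotone
rescaling that does not affect the inference, and the three windows sum
exactly to the 0–150 ms cumulation because windows are half-open.  The
natural log of the cumulated value is the default analysis scale.

## Source imaging and significant current density

The inverse is a depth-weighted minimum norm with a smoothness prior:
`K = R Lᵀ (L R Lᵀ + λ² C)⁻¹` with `R = D^{1/2} G D^{1/2}`, `D_ss =
‖l_s‖^(−1)` (configurable exponent), `G` a Gaussian kernel of inter-source
Euclidean distance with σ = 10 mm (Euclidean chord distance is used
rather than mesh-graph distance: on a sphere shell the two are
monotonically related, and the Gaussian of Euclidean distance is
guaranteed positive semidefinite), and `λ² = trace(L R Lᵀ)/(n_ch · snr²)`
with snr = 3.  The noise covariance defaults to the diagonal of the
empirical baseline covariance plus 5% diagonal loading.  On the reduced
geometry, noiseless single-source topographies are re-localized with a
median peak error under 15 mm (≈10 mm spacing between grid points).

Per-recording significance uses a max-statistic sign-flip permutation
scheme: each surrogate flips the sign of whole trials, averages, applies
the inverse over the baseline window, and records the maximum |current|
over sources × baseline samples; the threshold is the empirical (1−α)
quantile ('higher' order statistic, so the test is slightly conservative)
of the surrogate maxima, and post-pulse samples exceeding it form the
binary mask.  Defaults: α = 0.05, 500 permutations (100 in reduced mode;
below 100 a warning is logged, below 20 it is an error).  On pure-noise
recordings the family-wise rate of any significant 0–150 ms sample stays
in the [0.02, 0.09] band around α.  Significant Current Density cumulates
|current| over masked in-window samples × Δt, globally or within a
parcel; it is monotone in α and bounded above by the global value for
every parcel.

SCD inference runs on the *raw* cumulated values rather than the log:
sub-threshold blocks produce exact zeros (the mask is empty), where a log
is undefined; zeros are genuine "no significant activation" observations.
A window/scope cell that is constant across all subjects and conditions
(e.g. all zeros) returns the exact degenerate result χ² = 0, p = 1, with
the Bayes factor reduced to its BIC-penalty limit.

## Inference

For each window × scope, two linear mixed models are fitted to the
per-subject values by maximum likelihood (not REML, as required for
likelihood-ratio testing of fixed effects): a null model with only a
by-subject random intercept, and an alternative adding the three-level
condition factor.  The LRT statistic 2(ℓ₁−ℓ₀) is referred to χ² with 2
degrees of freedom.  Fitting uses BFGS with Powell and Nelder–Mead
fallbacks (the between-subject variance can sit on the boundary of the
parameter space, where a single optimizer occasionally fails); the fit is
accurate to ~1e-7 in the statistic against a closed-form profiled ML for
balanced designs.  No multiplicity correction is applied across windows
or scopes — each analysis is reported separately, matching the emulated
protocol.

Null-hypothesis support uses the BIC approximation to the Bayes factor,
`BF01 = exp((BIC₁ − BIC₀)/2)` with `BIC = −2ℓ + k ln n` (k counts fixed
effects plus the two variance parameters).  This replaces a JZS-prior
Bayesian repeated-measures ANOVA; the BIC approximation corresponds to a
unit-information prior and is testable by formula.  `fit_condition_lrt`
exposes the underlying `ModelFit` objects so an external Bayes-factor
implementation can be plugged in.

The operating-characteristics harness closes the loop.  Its fast path
simulates the trial *average* directly (noise scaled by 1/√n_retained
with n_retained = round(180 × 0.7), on a −400..+400 ms epoch at 725 Hz)
and runs the real filtering, referencing, baseline, field-power and
mixed-model code; the full path generates every trial.  Under the null
scenario with 15 subjects the LRT rejects at ≈5–6% per window at
α = 0.05 (the exact-ML type-I rate for this design is ≈0.060 — the
small-sample inflation of the asymptotic χ² reference is a property of
the procedure, not of the implementation), p-values are near-uniform, and
the median BF01 favours the null.  A window whose cumulated power is
dominated by the noise floor rather than evoked signal produces skewed
log-values and visibly inflates the LRT — one reason the generator keeps
real signal in all three windows.  With a 1.4× gain during/post the
rejection rate exceeds 80% in every window (pooled ≈1.0).

## Problem sizes and defaults used in validation

Calibration runs use the reduced geometry (812 sources, 100
permutations): 50 localization runs, 200 null simulations for the
family-wise error rate, 1000 fast-path repetitions for type-I error and
p-uniformity, and 200 repetitions each for the null-support and
effect-detection scenarios; the end-to-end determinism check runs the
full pipeline twice with 2 subjects × 40 trials.  These sizes give
Monte-Carlo standard errors comfortably inside the tested bands while the
whole validation remains a desk-scale computation.

## Known limitations

- Spherical geometry and template electrodes only; no individual anatomy,
  BEM/FEM, or atlas-based parcels.
- The forward model requires sources ≳3% below the inner skull; very
  superficial sources are rejected rather than computed inaccurately.
- Pink noise is channel-independent, so sensor-space noise lacks the
  spatial correlation of real EEG; permutation thresholds on real data
  will differ in level (the calibration, not the value, is the claim).
- BF01 is a BIC approximation, not a JZS Bayes factor; values are
  comparable in order of magnitude, not digit-for-digit.
- EDF support is import-only (fixed-length concatenated trials); the
  native interchange format is the float32 + JSON sidecar directory.
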