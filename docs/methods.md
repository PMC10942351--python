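# Methods

`popnoise` implements a whole-brain population analysis of trial-to-trial
neural and behavioral variability in larval zebrafish responding to moving
visual objects of different sizes, together with a synthetic-data generator
that plants every statistical structure the analysis is meant to recover.
This note documents the models, the estimators, the generator's
assumptions, the numerical choices, and the known limitations.

## The analysis chain

**Preprocessing.** Raw fluorescence decays through a session by
photobleaching. The session mean across neurons is fit with a
bi-exponential trend f(t) = a·e^{bt} + c·e^{dt} by nonlinear least squares
(four initializations splitting fast/slow rates; single-exponential
fallback, flagged). Every neuron is divided by the fitted trend and
z-scored; zero-variance neurons are dropped and their indices recorded.

**Calcium kernel.** A difference-of-exponentials kernel
k(t) = e^{−t/τ_decay} − e^{−t/τ_rise}, peak-normalized, truncated at
5·τ_decay. Defaults τ_rise = 0.3 s, τ_decay = 3.5 s approximate
nuclear-localized GCaMP6s; both are configuration parameters, since the
indicator dynamics are a property of the preparation, not the analysis.

**Behavior.** Tail curvature (summed inter-segment angles; positive =
leftward) is thresholded at σ_active — one standard deviation of
|curvature| over the recording — to extract bouts (runs merged below a
0.1 s gap, discarded below 0.05 s; these two defaults suppress chatter at
threshold crossings). Per trial, the mean curvature over bout samples in
the half-open stimulus window [onset, onset+duration) gives the outcome:
left if above +σ_active, right if below −σ_active, otherwise no clear
turn; the reaction time is the first bout start after onset. The
kernel-convolved |curvature| and curvature, resampled to the imaging frame
grid, are the tail vigor and direction regressors. For freely swimming
sessions, each bout starting within six body lengths of the stimulus is
scored by its change in distance to the stimulus (positive = avoidance);
the six-body-length gate is configurable because the literature also uses
ten.

**Stimulus encoding.** A single stimulus regressor sums per-trial boxcars
of height equal to the stimulus size, negated for right-side
presentations, convolved with the calcium kernel. Partial least squares
regression of the neural timeseries on this regressor defines the
visually-evoked subspace; the dimensionality d is chosen by minimizing
cross-validated MSE over contiguous time blocks (6 folds; contiguous
blocks rather than random frames, so temporal autocorrelation cannot leak
across folds), and the best model is refit on all
timepoints (a ``d_min`` floor is available for analyses that must
represent every per-size class mean, but it is not used by default: on
this generator, forcing extra components recruits noise-cancellation
directions that distort the recovered geometry). The refit
coefficient vector, unit-normalized, is the optimal decoding direction
w_opt. The latent basis is an orthonormalization (QR) of the PLS
rotations: with an orthonormal basis, angles between latent coordinate
vectors equal angles between the corresponding projected vectors over
neurons, which the oblique rotation basis does not guarantee.

**Trial decoding.** Mean in-window responses per neuron and trial are
classified by one-vs-rest lasso-logistic regression under repeated
stratified cross-validation (6 folds × 3). The inverse-regularization grid
is log-spaced over four decades around a data-driven activation point.
Confusion matrices are held-out counts summed over folds, row-normalized.

**Noise geometry.** Trial features are projected into the latent basis;
the per-class mean is subtracted; the unbiased covariance is computed per
stimulus class (classes below 3 trials excluded) and averaged unweighted
across classes. Eigendecomposition C = Σ λ_α e_α e_αᵀ gives noise modes
sorted by variance; eigenvector signs are fixed by making the
largest-magnitude entry positive. The angle of mode α to w_opt is
arccos |w·e_α| / (|w||e_α|), folded to [0°, 90°] because eigenvector signs
are arbitrary. Behavioral relevance of a mode is tested by Pearson
correlation of its projection timeseries against the tail vigor, with a
null of random circular shifts (≥ 30 s) that preserve autocorrelation;
p = (1 + #{|null| ≥ |r|}) / (n_shifts + 1). Significant contributors to a
population vector are neurons whose |coefficient| exceeds the mean + 3 SD
of label-shuffled refits.

**Pre-motor decoding.** Each trial is time-warped to align stimulus onset
and movement initiation: a native-rate pre-window (4 s), a linearly
resampled middle segment (length = median responsive reaction time at the
frame rate; linear interpolation between frames), and a native-rate
post-window (2 s). Non-responsive trials receive a surrogate reaction
time drawn from the responsive distribution (seeded). Lasso-logistic
classifiers are fit on features averaged over a grid of (start, end)
windows; macro-averaged F (harmonic mean of precision and recall, 0 when
both vanish) summarizes held-out performance. Predictability at a
timepoint is the best window ending there; an identical procedure on
label-shuffled copies (regularization re-swept per shuffle, and each
shuffle selecting its own best window so the maximization bias is the
same on both sides) provides the chance baseline and a per-endpoint
paired one-tailed t-test across CV splits. Significant neurons are those
whose |coefficients| across folds exceed the shuffled-label ones
(one-tailed two-sample t-test, p < 0.05); their anatomical spread is
summarized as percentages across telencephalon, tectum, cerebellum and
hindbrain with pairwise paired t-tests across replicates.

**Spontaneous transfer.** Spontaneous turns are bouts outside every
stimulus window (with a 2 s post-offset buffer against carry-over, and a
stimulus-free pre-session period, default 120 s) meeting the same
±σ_active criterion. The evoked turn model — the best-performing window
ending at the movement landmark, its fold-averaged coefficients frozen
(checksum-guarded) — scores the mean population activity in the 1 s
before each spontaneous turn; transfer is quantified by the Pearson
correlation between score and observed curvature and by sign accuracy.

**Optics.** The object-space lateral resolution of the Fourier light
field microscope is R_xy = λ·f_FL / (d_MLA·M). The published axial
expression's grouping is typographically ambiguous; the default variant
R_z = d_MLA·R_xy² / (λ·d_max) is the only dimensionally consistent
reading with R_xy squared, and the variant used is always recorded in the
output rather than silently asserted.

## The synthetic generator

The generator emulates one head-fixed session: 3 s moving-dot trials at
sizes {4°, 11°, 44°} on the left or right, inter-trial intervals
N(9 s, 3 s) truncated at 1 s (truncation prevents overlapping trials; the
experimental protocol does not state one), 5 Hz imaging for the ~40 min a
180-trial session takes, and a 200 Hz tail trace.

*Encoding.* Each size drives its own unit loading vector (orthonormal
triplet) with equal calcium-observable response energy but distinct
dynamics: small-object (prey-like) populations respond late (0.8 s
latency) and sustained, large-object (looming-like) populations respond
immediately and adapt. Distinct dynamics are what make the evoked
subspace genuinely multi-dimensional for PLS; equal energy keeps
errors-in-variables attenuation uniform across encoding directions. The
planted decoding direction w_true is the exact noise-free least-squares
regression direction implied by the schedule and shapes.

*Trial-to-trial factors.* Five shared factors with unit loadings:
a tail-vigor factor whose loading is constructed at a configurable angle
(default 90°) to w_true *inside* the evoked span — mirroring the finding
that motor-related covariation lives within the visually-evoked
population — plus slow (τ = 60 s) Ornstein–Uhlenbeck turn- and
responsiveness-bias factors and signed movement ramps rising 1 s before
each movement. The orthogonal component of the vigor loading is drawn
size-weighted so it overlaps the strongly regressor-weighted populations.

*Behavioral link.* Responsiveness follows a logistic link on the
responsiveness bias (base rate 0.6, matching the reported sub-60% response
rates to small objects); turn direction follows a logistic link on the
turn bias plus a signed, size-dependent stimulus drive (approach below
~7.5°, avoidance above — one interpretable gain per size). Reaction times
are lognormal (median 1.5 s — a configurable placeholder, as no
reaction-time distribution is reported), clipped to [0.5, 2.8] s.
Spontaneous turns alternate by a two-state Markov chain (persistence 0.8,
the hindbrain-oscillator analogue) whose per-event left probability is
additionally steered by the same slow turn bias; the coupling and the
ramp loading are severed in the independent-circuit negative control.

*Rendering.* All drive terms are convolved with a mass-normalized copy of
the calcium kernel (amplitudes are then in sustained-response units),
multiplied by a bi-exponential bleaching trend, and corrupted with i.i.d.
Gaussian noise; snr is the ratio of a unit sustained latent to the noise
SD along any unit loading direction (default 5). Default amplitudes —
stimulus 5, vigor 14, biases 0.05, ramps 1 — were chosen from a variance
budget worked out before the tests were frozen: the vigor factor must
dominate the within-class trial-feature covariance (so it is recovered as
the largest noise mode) while its overall temporal variance stays below
the stimulus variance in the evoked span (so the regression-based
decoding direction is not shrunk along it). The planted-internal-state
scenarios used by the profile-shape and transfer studies raise the bias
and ramp amplitudes (0.3 / 6.0) relative to these defaults — effect sizes
chosen so each planted effect is individually detectable at desk scale
through the slow indicator (a 1 s ramp seen through a 3.5 s-decay kernel
retains only a small fraction of its amplitude before the movement) — and
the null scenarios zero them; those scenarios exercise the detection
machinery, not the defaults.

## Problem sizes used by the validation studies

Noise-geometry recovery runs 500 neurons × 180 trials (6 classes × 30);
angle statistics are means over seeds (20 replicates in the acceptance
script, 4 per angle in the test suite). Decoder calibrations use 120
trials × 300 neurons; profile studies 180 trials × 150 neurons; transfer
studies 240 trials × 200 neurons. These sizes make each study run in
minutes on one CPU while keeping every qualitative property stable.

## Known limitations

- **Planted 45° geometry recovers high (~50°).** The regression estimate
  of w_opt minimizes prediction error, which attenuates its component
  along any direction carrying stimulus-independent temporal variance —
  classical errors-in-variables shrinkage. When the dominant noise
  loading overlaps w_true at 45°, the estimated direction rotates away
  from the loading and the recovered angle lands near 50° rather than
  45°. The bias scales with the vigor factor's temporal variance; making
  that factor weak enough to remove the bias also removes its dominance
  of the within-class covariance, which the 90° recovery requires. The
  0° and 90° cases recover within tolerance. This is a property of
  regression-estimated decoding directions generally — angles measured
  against such directions are biased toward 90° for strong noise modes —
  not a defect of the implementation.
- **Stimulus carry-over.** With a 3.5 s indicator decay and ~9 s
  intervals, the previous trial's response tail contributes real
  trial-to-trial covariance along the encoding directions. It is left in
  deliberately (it is present in any slow-indicator recording) and is the
  main competitor of the vigor mode in the noise spectrum.
- **What passing tests do not show.** The generator is linear-Gaussian
  with a handful of planted factors; real recordings have nonlinear
  calcium dynamics, correlated segmentation noise, non-stationary
  behavioral states and anatomically structured (not random) loadings.
  Passing recovery tests certifies the estimators, not the biology.
- The tail trace is an amplitude-modulated envelope, not an oscillatory
  swim pattern, so frequency-domain bout features are out of reach.
- Surrogate reaction times for non-responsive trials reuse the responsive
  distribution; if real non-response reflects slower dynamics, warped
  non-responsive segments are mildly mis-scaled.
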