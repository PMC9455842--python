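# Methods

This note documents the models, numerical choices and limitations of
the package, module by module, in the order data flows through the
pipeline.

## Synthetic data

**Measurement model.** Scalp EEG is generated by inverting the
analysis assumptions: a set of cortical dipoles with fixed (radial)
orientations emit band-limited Gaussian oscillations — white noise
band-passed to theta/alpha/beta/gamma — whose *variance* is multiplied
by a class gain depending on the trial's later memory outcome.
Band-limited noise rather than sinusoids is used so spectral estimates
have realistic variance: the planted effects are power modulations,
not phase-locked components, matching the event-related spectral
statistics the pipeline computes. Scalp data are
`leadfield · sources + background`.

**Background noise and SNR.** The background is 1/f^α noise (α = 1 by
default) emitted by 40 randomly placed dipoles and mixed through the
lead field, so it is spatially correlated the way real EEG noise is; a
10% white sensor-noise floor is added. `snr_db` is defined *per band*:
each planted source's unit-gain scalp power is set `snr_db` above the
realized background power inside that source's frequency band
(measured by Parseval from the background's spectrum). With a 1/f
background a broadband SNR would make identical class-gain ratios
trivially detectable in gamma and undetectable in alpha; the per-band
definition matches how band-limited effects are quantified in practice
(power change relative to the band's baseline). Background RMS is
scaled to 10 µV.

**Behavior.** Old words are remembered (confidence 3–4) with
probability `p_remember` (default 0.8, giving the ~80/20 class
imbalance); new words are falsely recognized with probability 0.2.
Retrieval reaction times are log-normal with medians ordered
remembered (500 ms) < false remembered (750 ms) < forgotten (1200 ms),
σ = 0.35 on the log scale — the ordering is the modeled phenomenon;
the values are round numbers of realistic magnitude, not estimates.
Encoding judgments (abstract/concrete) are completed more often for
later-remembered items (95% vs 83%).

**Artifacts** are 200 ms, 400 µV Hanning bumps on four random channels
in an `artifact_rate` fraction of trials — enough to trip the ±200 µV
rejection deterministically, with no attempt at ocular/EMG morphology.

**Seeding.** One master seed; behavior, source waveforms, background
noise and artifacts draw from sub-streams at fixed offsets, so any
stage can be regenerated independently and bit-identically.

**What this generator does not emulate:** evoked (phase-locked)
components and ERPs, cross-frequency coupling, non-stationary
artifacts, volume-conduction errors from real anatomy, or behavioral
lapses. Passing tests therefore demonstrate that the pipeline recovers
*band-power* class differences through the forward/inverse chain — not
that it would reach any particular accuracy on real recordings.

## Preprocessing

Stage order is fixed: downsample (polyphase, anti-aliased; events
rounded to nearest sample, ties to even) → zero-phase fifth-order
Butterworth 0.5–40 Hz (second-order sections; two passes square the
magnitude response, so the effective attenuation at each cutoff is
−6 dB rather than −3 dB, and group delay is zero) → average reference
→ epoch [−1000, 1000) ms around onsets (half-open windows everywhere;
trials without full coverage are dropped with their metadata) →
whole-epoch baseline subtraction (a pre-stimulus-only mode is
available) → rejection iff max |x| strictly exceeds 200 µV →
spherical-spline interpolation (order-4 Legendre kernel, 20 terms,
1e-8 ridge, constant-exact) for configured bad channels → outcome
labeling from retrieval confidences.

## Forward model and inverse

**Spherical head model.** Concentric three-shell conductor, radii
0.87/0.92/1.0 head radii, conductivities 1 : 1/80 : 1. For each
Legendre degree n the radial two-point boundary-value problem across
the shells is solved directly (2S−1 linear equations), yielding a
transfer scalar g_n applied to the free-medium dipole expansion; the
homogeneous-sphere closed form g_n = (2n+1)/n is reproduced exactly
and serves as the solver's oracle. The series is truncated at 60 terms
(source eccentricities ≤ 0.74 make the tail negligible). Rows are
projected onto the average reference. The source grid is a Fibonacci
lattice on three shells (radii 0.40/0.58/0.74, sources allocated ∝
r²), each point tagged with one of 12 coarse anatomical sectors
(medial parietal, medial prefrontal, cuneus, lingual, cingulate,
temporal l/r, parietal l/r, occipital, frontal, other) by angular
rules — vocabulary for reporting, not anatomy. Default grid 642
sources; the end-to-end demo uses 162 (grid size is a fidelity knob,
not a correctness one).

**Inverse.** Minimum norm with identity source prior:
`K = Gᵀ(G Gᵀ + λ²C)⁻¹` via pseudo-inverse (G and C share the
average-reference null space). λ² defaults to the SNR heuristic
`tr(G Gᵀ)/(SNR² tr C)` with SNR 3. The noise covariance is the
empirical pre-stimulus covariance with 10% diagonal loading, pooled
across subjects (one template montage, one inverse). sLORETA
standardization whitens each source's 3-vector estimate by the inverse
square root of its 3×3 resolution block (K G)_jj; activity is the
orientation norm, hence nonnegative. Zero localization error for
noiseless single dipoles — every grid point, every orientation — is
the module's oracle test. For classification, source activity is
averaged within the 12 region parcels: there is no canonical recipe
for reducing a many-thousand-voxel source estimate to a classifier
input, and region means keep the dimensionality commensurate with the
trial counts while preserving the anatomical vocabulary of the
reported effects.

## Spectral features

Sliding 100 ms Hanning windows, 50% overlap (at 250 Hz: 25 samples,
hop 12), `S = |DFT(w·x)|²/Fs`, zero-padded tenfold so the spectrum is
sampled on the 1 Hz grid 4–40 Hz (at 250 Hz the padded bins land
exactly on integers; otherwise linear interpolation). Edge windows are
never padded — the first/last centers keep the window inside the
epoch. Band averages are arithmetic means over inclusive integer bins
(theta 4–8, alpha 8–12, beta 12–30, gamma 30–40 Hz; delta excluded).
A 100 ms window has 10 Hz native resolution: a 10 Hz sinusoid leaks
substantially into theta, and the tests assert exactly what the
direct-DFT oracle yields (window-averaged alpha dominance, ~10³×
separation only versus gamma) rather than a sharper separation the
window cannot deliver. ERSP is 10·log₁₀(power/baseline) with the mean
pre-stimulus power as default baseline; GFP is the population standard
deviation across channels of a condition-mean topography, computed per
condition because trial counts differ.

## Statistics

Paired Student's t (zero-variance guards: identical samples → t = 0,
p = 1; constant nonzero difference → ±∞, p = 0), element-wise t maps
over arbitrary grids with Benjamini–Hochberg step-up FDR (hand-rolled
five-liner, cross-checked against statsmodels) for large
frequency × time (× source) families and Bonferroni for small post-hoc
families. Repeated-measures ANOVA (one- and two-way, each effect
tested against its effect × subject mean square) is delegated to
statsmodels' AnovaRM; the two-level identity F = t² is tested to
1e-8. Sphericity corrections are not applied (two-level factors don't
need them; the frequency factor is reported uncorrected).
Hierarchical regression fits base and base+added OLS models per
subject (statsmodels, pseudo-inverse — duplicated columns add
nothing), then paired-t's R² and overall F across subjects.

## Classification

Trials labeled remembered (positive class) vs forgotten. Features per
cell: the epochs zero-phase filtered to the band (4th order), source
cells additionally passed through the inverse and parcellated, cropped
to the analysis window ([−300, 0) or [400, 800) ms) and decimated by 2
(the band ceiling of 40 Hz leaves 125 Hz sampling ample). The
band-filtered time series — not band-power vectors — are the
classifier input, consistent with concatenating (channels × time)
signals; a band-power input is available via the spectral module.

**Shrinkage LDA.** `w = Σ(γ)⁻¹(μ₁−μ₀)` with pooled biased within-class
covariance and `Σ(γ) = (1−γ)Σ + γ(tr Σ/d)I`, γ = 0.1 by default (γ is
exposed; scikit-learn's lsqr-solver LDA with the same γ is the
cross-check, never the implementation). For wide problems (d > 2n) the
solve uses the Woodbury identity on the n × n Gram matrix, verified
against the explicit d × d solve.

**CNN.** One convolution layer, (1, 3) kernel shared across channels
(8 filters; 4 in the demo), batch normalization, ELU, dropout 0.25,
flatten, fully connected to 2 logits; Adam at learning rate 0.005,
batch size 25, cross-entropy, early stopping on a 10% train-internal
split (patience 10), at most 100 epochs (20 in the demo, 8 in the null
runs). Forward and backward passes are explicit numpy, seeded
end-to-end: same seed and data give identical weight hashes. The ELU
nonlinearity is what lets the network detect variance-coded (power)
class differences that a linear readout of raw voltages cannot see.

**Cross-validation.** Seeded random 5-fold partition, drawn once per
dataset and reused across every feature space × band × model cell so
cells are compared on identical splits. SMOTE (synthetic samples
`x + u(x_nn − x)`, k = 5 minority neighbors, reduced with a warning
when the minority is small) is applied to training folds only. The
cell statistic is the mean of per-fold AUCs (midrank ties; folds whose
random test split is one-class are skipped) — per-fold AUC is
invariant to fold-specific score offsets, which pooled scores are not
(training-fold class ratios shift the LDA intercept per fold).

**Permutation null.** Labels are permuted within subject against the
held-out scores and the identical fold-matched statistic is
recomputed (rank-sum formulation, 200 permutations), giving the null
of "no score–label association". This is *not* the sampling
distribution of the CV estimator: per-fold AUCs are positively
correlated through their 80%-overlapping training sets, so the
fold-mean statistic is over-dispersed relative to this null by roughly
√2. A re-training permutation null would match but costs hundreds of
extra model fits per cell; the reported band is therefore interpreted
as an association test, and null-scenario calibration is asserted
against the span of the 200-draw null rather than its central 95%.

## End-to-end scenario sizes

The shipped demo scenario: 13 synthetic subjects, 96 encoding words
each (~77/19 remembered/forgotten after ~5% artifact rejection),
simulation directly at 250 Hz, 162-source grid, planted pre-stimulus
alpha decrease (variance gains 0.45 remembered / 1.55 forgotten) and
beta/gamma increases (1.55/0.45) at two medial-parietal and two
medial-prefrontal sources, in-band SNR 0 dB, with analogous on-going
effects. The no-effect scenario for type-I checks uses 8 subjects × 48
words and a 2-filter, 8-epoch CNN. These sizes were chosen so a full
comparison runs in minutes on one CPU; the full-scale defaults (250
words, 1000 Hz acquisition, 642 sources, 100-epoch CNN) remain the
package defaults for real use.

## Known limitations

- The spherical head model and template montage ignore individual
  anatomy; no BEM, no depth weighting, no dSPM/eLORETA variants.
- Source orientation is free with norm collapse; rectified activity is
  nonnegative, so source-space "signals" are envelope-like and their
  band-pass filtering measures envelope dynamics, not oscillatory
  phase.
- Sensor-space detection of a *pure* narrow-band power modulation
  through a 300 ms window is near chance for alpha (≈ 2·BW·T effective
  power samples per channel); real recordings carry additional evoked
  and broadband features the generator deliberately omits.
- The permutation band understates CV-estimator variance (see above);
  treat it as an association test, not a confidence interval.
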