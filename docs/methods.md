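# Methods

`eegfuse` implements a hybrid discrimination pipeline for two-class EEG
cohorts (the motivating application is separating brain-death-like from
coma-like recordings): parametric spectral features, ordinal-pattern
complexity features, canonical-correlation feature fusion, group
statistics, and supervised evaluation — plus a synthetic cohort
generator that makes the whole chain testable without clinical data.
This note records the models, the parameters that matter, and the
design decisions taken where more than one reasonable construction
exists.

## Preprocessing

Recordings are plain matrices (channels x samples) with a sampling rate
and channel labels; the default montage is the six frontal electrodes
FP1, FP2, F3, F4, F7, F8. Each recording is cut into consecutive
non-overlapping epochs starting at sample 0 (default: five 1-minute
epochs); a tail shorter than one epoch is discarded, and no epoch
rejection is applied. The six sub-bands are delta 0.5–4, theta 4–7,
alpha 8–12, beta 13–30, gamma1 30–40 and gamma2 41–100 Hz; the printed
gaps between bands (7–8, 12–13, 40–41 Hz) are preserved deliberately,
and every relative-power denominator is the full 0.5–100 Hz range, not
the union of bands. Band filtering is a zero-phase forward-backward
Butterworth (order 4 per direction). Artifact removal is out of scope;
an optional 0.5 Hz high-pass detrend hook is provided, default off.
I/O formats are delimited text plus a `key: value` sidecar, and EDF
(read through `mne`; written by a small 16-bit EDF writer whose
round-trip error is bounded by the per-channel quantisation step).

## Spectral features

The PSD of each epoch/channel is a Yule-Walker AR model of order p = 10.
The signal is demeaned per epoch, cut into 250-sample sliding windows
with half overlap, and Hamming-tapered; the per-window biased
autocovariances (lags 0..10, rescaled by the taper's mean square) are
averaged across windows and a single Levinson–Durbin solve yields the
coefficients and innovation variance. The spectrum is the standard AR
form S(f) = sigma^2 / |1 + sum a_k exp(-i 2 pi f k / fs)|^2 on a 0.5 Hz
grid.

Two numerical choices deserve note. First, windows are *not* demeaned
individually: subtracting a 250-sample window's mean removes precisely
the sub-window-frequency content that the delta band lives in. Second,
the window autocovariances are averaged *before* a single AR solve
rather than averaging per-window AR spectra. Per-window fits jitter in
peak location and width; averaging their spectra convolves the estimate
with that jitter and systematically flattens narrow low-frequency
structure (measured on exactly-AR test processes, the delta-band
relative power of a strongly delta-dominant signal loses roughly 0.07
under spectrum averaging and essentially nothing under covariance
averaging). Covariance averaging uses the same data and the same model
family and is consistent when the signal is AR.

Spectral features are computed at a 250 Hz working rate: recordings
sampled faster are polyphase-decimated (anti-aliased) before
estimation. At 1000 Hz a 250-sample window spans 0.25 s — a spectral
resolution of about 4 Hz, which cannot resolve the 3.5 Hz-wide delta
band at all; at 250 Hz the same window spans 1 s (≈1 Hz resolution)
while the 125 Hz Nyquist still covers the full 0.5–100 Hz range of
interest. Relative band power is the trapezoid-integrated PSD over the
closed band interval divided by the integral over 0.5–100 Hz; adjacent
bands share only a zero-width edge, so disjoint bands sum to at most 1,
with strict inequality because of the inter-band gaps.

The time-varying spectrum applies K orthogonal DPSS tapers
(time-bandwidth 2, K = 3 by default) to 2 s windows stepped by 0.1 s;
each tapered window is AR(10)-fitted and the K spectra are averaged,
trading a little resolution for a K-fold variance reduction. K = 1
reduces to single-taper sliding-window estimation.

## Permutation entropy

PE is the Shannon entropy of the ordinal-pattern distribution: windows
of m samples spaced tau apart are reduced to the permutation that sorts
them, and PE = -sum P_j log P_j over observed patterns (0 log 0 = 0).
Defaults are m = 4, tau = 1, natural log (values in nats, at most
log m! ≈ 3.178), with optional normalisation by log m!. Ties are broken
by order of occurrence (stable sort), so permuting equal values never
changes a pattern; a seeded-jitter option exists for heavily quantised
data, default off. The pipeline computes PE on the broadband
(0.5–100 Hz) filtered signal at the same 250 Hz working rate as the
spectral features, so both feature families see the same frequency
support. Time-varying PE evaluates PE in consecutive non-overlapping
windows; the windows are non-overlapping by default (an overlap option
is deliberately not provided — the monitoring use case never needed
one). Per-subject features average PE over epochs, and monitoring plots
average over channels.

The m = 4 default matters: PE is extremely sensitive to the fastest
signal component, because local ordinal patterns are dominated by
whichever component has the largest sample-to-sample increments. Even a
few percent of broadband noise saturates PE toward log m!; the
generator's noise fractions (below) are therefore chosen in the
responsive part of that curve.

## Feature fusion

Two feature views per subject: the per-electrode delta relative power
(6-dimensional; delta is the band with the strongest group effect) and
the per-electrode broadband PE (6-dimensional). Each view is
column-centred, z-scored (the views mix unit-free ratios with nats —
correlation-matrix PCA is the default, configurable), and reduced to
the minimal number of leading principal components explaining at least
70% of the variance. Under the default study conditions both views
reduce to two components.

Fusion uses the compact-SVD CCA construction: with centred reduced
views A = U_A S_A V_A^T and B = U_B S_B V_B^T, the SVD
U_A^T U_B = U Sigma V^T gives projections W_A = V_A S_A^{-1} U and
W_B = V_B S_B^{-1} V; X = A W_A and Y = B W_B have orthonormal columns
with corr(X_i, Y_j) = Sigma_ii delta_ij, and the fused matrix is
Z = [X | Y] with exactly 2r columns, r = min(rank A, rank B). Ranks use
the tolerance max(dim) * eps * sigma_max. (Using the right singular
vectors V for W_B is the standard construction; a W_B built from U
would not be conformable in general.) Four candidate feature sets are
evaluated: set1 = reduced spectral view, set2 = reduced PE view,
set3 = [set1 | set2], set4 = Z.

## Statistics

Each feature family is tested feature-wise with a one-way ANOVA (for
two groups, F on (1, n1+n2-2) degrees of freedom equals the squared
pooled t). The unit of observation is the subject (epoch-averaged
features), never the epoch — per-epoch testing would pseudo-replicate.
Families are the six bands (electrode-averaged rPSD) or the six
electrodes (PE); p-values are Bonferroni-corrected within the family
(p_corr = min(1, 6p)) and flagged at alpha = 0.01. Raw and corrected
p-values are both reported.

## Classification

An RBF-kernel SVM is evaluated by leave-one-out cross-validation. For
every left-out subject, C and gamma are tuned on the remaining subjects
only, by a 3-stage coarse-to-fine grid search over exponentially
growing sequences 2^-5 .. 2^15: stage 1 scans exponents in steps of 4;
each later stage scans one step either side of the previous optimum
with the step halved. Inner model selection scores stratified 3-fold
accuracy; ties resolve deterministically to the smallest C, then the
smallest gamma. Features are z-scored with training-fold statistics at
every level, so the held-out subject never influences scaling or
hyperparameters. Decision scores pooled across outer folds form a
single ROC (per-fold curves from one subject each would be
meaningless); AUC is the normalised Mann–Whitney statistic with ties
counting 1/2, and the confusion matrix at decision threshold 0 yields
sensitivity TP/(TP+FN), specificity TN/(FP+TN) and accuracy, with
class 1 ("death-like") as the positive class. No class reweighting by
default; a class-weight option exists. All feature sets are evaluated
under identical CV conditions (LOO is deterministic; the inner-fold
seed is shared).

## Synthetic cohorts

Each channel is generated at the 250 Hz working rate as

    x = amp * ( sqrt(1 - nu) * sum_b g_b u_b + sqrt(nu) z ),

then polyphase-upsampled to the recording rate. Each band component u_b
is white noise filtered through a fixed fourth-order all-pole resonator
pair (two slightly offset second-order resonances per band) and
normalised to unit variance; the cascade gives a rounded in-band bump
with f^-4 skirts, so ≥ ~90% of a component's power stays within its
band ± 1 Hz, while the mixture remains smooth and close to the AR model
family the spectral pipeline fits. A brick-wall band construction was
rejected after measurement: sharp-edged spectra are far from any
low-order AR model, and the maximum-entropy character of Yule-Walker
fits fills inter-band valleys, biasing the delta relative power of a
delta weight 0.8 construction down to ≈ 0.6. With the resonator
mixture and covariance-averaged estimation the same construction reads
back ≈ 0.77 — the residual few percent being component power falling in
the inter-band gaps, which the 0.5–100 Hz denominator counts but no
band numerator does.

The gains g_b are calibrated per subject by a multiplicative fixed
point on the components' analytic spectra so the mixture's relative
band powers match the subject's weight vector; realized fractions are
returned by `calibrate_band_gains`. z is unit-variance white noise at
the working rate; its fraction nu controls ordinal pattern diversity
and raises PE monotonically.

Default study conditions: 20 subjects per class, 6 channels, 1000 Hz,
five 1-minute epochs. Class 0 ("coma-like") has band weights
(0.80, 0.10, 0.05, 0.03, 0.01, 0.01) and nu = 0.02; class 1
("death-like") has (0.55, 0.13, 0.15, 0.11, 0.03, 0.03) and nu = 0.15 —
lower delta dominance, relatively more alpha/beta power, and higher
complexity, the qualitative contrast the pipeline is designed to
detect. The noise fractions sit in the responsive region of the PE
curve (PE saturates above nu ≈ 0.2 at these settings). Between-subject
variability — log-normal weight jitter (sd 0.25 on the log scale), a
truncated-normal noise-fraction jitter (sd 0.03) and log-normal
amplitude scatter (sd 0.2) — is a free parameter of the generator,
chosen to give clearly separable but not degenerate classes; it is not
calibrated to any clinical population, and no attempt is made to model
physiological generators, artifacts, electrode noise, or volume
conduction. Everything is driven by one seed through per-subject child
streams, so cohorts are bit-reproducible.

A scaled replicate configuration (`reduced_cohort_spec`: 12 subjects
per class, 250 Hz, three 10 s epochs, attenuated class contrast with
delta weights 0.70 vs 0.64, noise fractions 0.02 vs 0.15, weight jitter
0.35) is used for Monte-Carlo experiments. Its contrast is set so the
two single-view feature sets classify in the mid-80% to low-90% range
rather than saturating — the regime where the benefit of fusion over
the better single view is measurable, and comparable to the accuracy
range reported for clinical cohorts of this kind. Problem sizes in the
test suite (replicate counts, cohort sizes, epoch lengths) are scaled
to keep the full suite comfortably runnable on one CPU.

## What passing tests do and do not show

The generator emits stationary Gaussian mixtures whose band powers and
complexity are known by construction; the test suite shows that every
stage recovers what was built in — spectral fractions within a few
percent, PE agreeing with a brute-force oracle to 1e-12, canonical
correlations agreeing with an eigenvalue solver to 1e-8, familywise
error controlled at alpha on null cohorts, and end-to-end
discrimination recovering a designed class contrast. It does not show
anything about nonstationary, artifact-laden clinical EEG, about the
clinical validity of the delta-rPSD/PE contrast, or about classifier
performance on real cohorts of unbalanced size.

## Known limitations

- The Yule-Walker/AR(10) spectrum is a smooth rational approximation;
  signals far from the AR family (sharp band edges, deep spectral
  valleys) are read back with a maximum-entropy bias toward filled
  valleys. This is a property of the estimator, preserved deliberately.
- Relative band powers of the six bands never sum to 1 (gap power), and
  requested generator profiles are realized only up to gap leakage
  (returned by the calibration for inspection).
- EDF export requires an integer sampling rate and whole seconds of
  data; 16-bit quantisation bounds the round-trip error.
- LOOCV with per-fold nested tuning is expensive (O(n) full grid
  searches); cohorts of a few hundred subjects are the practical limit.
- The column-binary matrix format is not implemented; use delimited
  text or EDF.
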