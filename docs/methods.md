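# Methods

This note documents the models, numerical choices and limitations behind
`oscoupler`. It is the package's own account of its science; every number
quoted here is computed by the test suite or the acceptance script.

## EEG artifact correction

**Average artifact subtraction (AAS).** Gradient artifacts repeat with the
volume period. For each channel, epochs locked to the volume triggers are
averaged over a sliding, centered window of 21 occurrences (truncated at
the run edges) and the local average is subtracted at each occurrence. A
sliding rather than global template tracks slow artifact drift. When the
artifact is identical at every occurrence the subtraction is exact to
machine precision; the price is that the template also carries ~1/21 of
any TR-locked share of the underlying EEG, which bounds the signal
distortion. Trigger spacing is validated to within 2 % of the median
before subtraction; irregular triggers are rejected with a diagnostic
rather than silently blurring the template.

**QRS detection.** R-peaks are found by band-passing the ECG to 5–25 Hz,
squaring, integrating over 120 ms, peak-picking with a 0.3 s refractory
distance, and refining each candidate to the raw-trace extremum within
±50 ms. On synthetic ECG this recovers every peak within ±1 sample at
500 Hz (±2 samples with additive noise at 10 % of the R amplitude).
Inter-beat intervals outside 0.3–2.0 s raise a warning.

**Ballistocardiogram (BCG) subtraction.** The same moving-template scheme,
with windows starting 0.21 s after each R-peak (the conventional pulse-
artifact lag; configurable) and spanning the median inter-beat interval,
averaged over 21 beats. R-R jitter limits cancellation; on simulated data
R-locked average power drops by well over 10×.

**Filters.** All filters are zero-phase forward–backward passes, so volume
triggers stay aligned. Stages: anti-alias low-pass at 70 Hz and resample
to 500 Hz (when the input is faster); 0.5–70 Hz Butterworth band-pass
(order 2 per pass; the forward–backward application yields an effective
24 dB/oct skirt, read as a minimum slope, not an exact filter order);
50 Hz notch (Q = 30); 17.5–18.5 Hz band-stop for the residual slice
harmonic (implemented at the conventional 18 Hz center; note that
30 slices per 2.1 s put the fundamental near 14.3 Hz, so the reject band
is configurable); final resample to 256 Hz with trigger re-indexing. The
measured magnitude response is ≤ −20 dB at 18 and 50 Hz and within 3 dB
over 1–15 and 20–45 Hz.

**Bad epochs and reference.** Marked volume epochs are replaced by the
nearest good epoch (earlier preferred on ties), keeping the epoch count
constant. Scalp channels are then transformed to the average reference;
ECG and EOG-like channels are excluded from the mean — the reference
should not import cardiac potentials into the scalp montage. An
ICA-based residual cleanup is deliberately not part of the chain: it
requires visual component selection, which is not reproducible, and the
artifact families simulated here are fully handled by AAS, BCG subtraction
and the filter cascade.

## Per-volume spectra and regressors

Each volume contributes one epoch starting at its trigger. A 2.1 s epoch
at 256 Hz holds 537 samples; the spectral estimator uses the first 2.0 s
(512 samples) so that DFT bins land exactly on a 0.5 Hz grid with no
padding — zero-padding can refine but never coarsen a bin spacing. A
pad-and-average dialect (0.25 Hz bins, adjacent pairs averaged) is one
switch away. The taper is a Tukey window with 10 % cosine fraction (5 %
per end), the analyzer convention for a "10 % Hanning window".

Spectra are stored as absolute amplitude (µV); band values are means over
in-band bins (inclusive edges). The squared (power) dialect is a config
switch; because regressors are z-scored before entering the GLM, the
choice only rescales the modulator monotonically. GSP is the per-epoch RMS
of band power across scalp channels; the regional regressor averages Oz,
POz and Pz, defaulting to the merged 8–13 Hz alpha band (the regional
analysis concerns "alpha" as a whole; sub-bands are available).

## First-level GLM

The canonical HRF is the SPM-style double gamma (response gamma shape 6,
undershoot shape 16, ratio 6), sampled at TR over 32 s and normalized to
unit peak, so the interest beta reads as percent signal change per unit
z-scored band power at the response peak. The modulator is z-scored before
convolution — the constant "eyes-closed" boxcar is then absorbed by the
intercept, and betas are comparable across bands.

Drift is modeled by a DCT-II basis containing every component with period
longer than 128 s (exactly 6 columns at T = 185, TR = 2.1 s). Nuisances
(six motion parameters, WM, CSF) are standardized for conditioning. Serial
correlation uses a single AR(1) coefficient pooled over the analysis mask
— one scalar per run stabilizes small simulations and matches classic
single-subject practice — followed by prewhitening of both sides (first
row scaled by sqrt(1−ρ²)); at ρ = 0 the estimator reproduces OLS exactly,
which the tests assert to 1e-8 against an explicit normal-equations solve.
Statistics with numerically zero residual variance are capped at a finite
sentinel (1e6) and flagged, so degenerate toys cannot produce infinities.

## Second level and cluster inference

Group inference operates on subject-level interest-beta maps (the summary-
statistics approach; equivalent to a full two-level model under balanced
designs and the only desk-scale option). Between-group coupling
differences are undirected F contrasts, F(1, n−2) = t², because band-power
/BOLD correlations are bidirectional — a directional test would conflate
stronger positive coupling with weaker anticoupling. Within-group
one-sample t maps are emitted for interpretation.

The extent threshold comes from a Monte-Carlo null: standard-normal noise
on the full grid, Gaussian-smoothed at the nominal applied FWHM (8 mm; an
optional residual-based smoothness estimator is out of scope), masked,
rescaled to unit variance inside the mask, thresholded two-sided at voxel
p < 0.005, and labeled with 26-connectivity. Smoothing before masking
ignores the skull boundary and is conservative at edges. k_min is the
smallest extent whose max-cluster exceedance is ≤ 0.05 over 1000
iterations. On the 3 mm MNI152 gray-matter mask bundled with nilearn
(64 292 voxels at the package's default probability threshold) this yields
k_min ≈ 38–39; the MNI GM probability map is liberal — its volume
(~1.7 L) exceeds anatomical gray matter — and a stricter 0.5 threshold
moves k_min only to ~36–37, so the default is kept. The threshold is
monotone: it grows with voxel p (a more lenient height admits larger null
clusters), with smoothing, and with mask size.

Observed maps are thresholded at the statistic value matching voxel
p < 0.005 for their df (|t| two-sided; F one-sided), clusters below k_min
are discarded, peaks are reported in world (MNI) mm via the affine, and
each cluster's corrected p is the null exceedance fraction of its size.

## ALFF / mALFF

After per-voxel OLS residualization of the six motion parameters (mean
re-added) and linear detrending, the untapered full-length DFT gives bins
at k/(T·TR) ≈ 0.00257 Hz; ALFF is the mean amplitude (square-rooted power)
over bins in 0.01–0.08 Hz. "Length = shortest" is read as transform length
= series length, no padding. mALFF defaults to the subtractive dialect
(ALFF − mask mean, so the mask mean of mALFF is zero to 1e-10); the more
common divisive dialect is a switch. Group differences are voxelwise
two-sample t-tests, whole-brain or restricted to the union of
cluster-corrected coupling-difference clusters across all bands and
regressor kinds, with the Monte-Carlo null recomputed on the tested mask.

## Synthetic cohorts

The generator emulates the study conditions: TR 2.1 s, 185 volumes in a
6 min 30 s session, 60-channel 10-10 EEG at 5 kHz, a 3 mm grid. Its grid
is a 20×20×18 ellipsoidal "gray-matter" mask (~2 750 voxels) with named
spherical ROIs — large enough for cluster geometry, small enough for
desk-scale testing.

*EEG.* Each band is a sinusoidal oscillator (delta 2, theta 6, alpha 9.5,
beta 20 Hz) whose amplitude follows a log-normal AR(1) envelope held
constant within each volume epoch, so per-epoch band power is an exact
function of the envelope. A log-normal envelope was chosen because it
guarantees positivity; oscillator frequencies sit inside their bands and
off the band edges. Carrier phases differ per channel (scalp topographies
are not spatially phase-coherent; a spatially coherent oscillation would
be largely removed by the average reference). Alpha is weighted toward
posterior channels. A 1/f background, a fixed per-TR gradient waveform
(harmonics of the 30-slices-per-TR slice frequency, ~20× signal scale,
optional timing jitter), a BCG template at 0.21 s after each simulated
R-peak (R-R 1.0 ± 0.05 s), and an ECG channel complete the recording.

*BOLD.* Baseline 100 (so raw units are percent), per-voxel linear + slow
cosine drift, stationary AR(1) noise (ρ = 0.3, SD 1 %), and in coupled
ROIs β × (HRF ⊗ z-scored band power) with β in % per unit z — the exact
generative counterpart of the analysis model. The default cohort plants a
thalamic alpha coupling of 0.8 %/z in the control group and 0 in the
patient group, and a low-frequency (0.025/0.04 Hz sinusoid) amplitude
multiplier of 1.5 in the patient group for the ALFF contrast. Motion is a
smoothed random walk and WM/CSF are low-pass noise; they are returned as
confounds but not mixed into the data — the analysis uses them as nuisance
regressors only, and their recovery is not a target.

What the generator does **not** emulate: head-model EEG forward physics,
MR physics (spikes, distortion, spin history), spatially correlated
physiological noise, realistic artifact topographies, or non-stationary
heart rate. Passing tests therefore demonstrate that the analysis recovers
what its own model class generates — correctness of the estimators and
error control — not robustness to every failure mode of real recordings.

## Problem sizes in the test suite

The suite validates estimator contracts on small random instances, EEG
properties on 500 Hz / 8-channel / 60-volume recordings, and recovery and
error control on full-length (185-volume) cohorts: 20 planted and 40 null
cohorts of n = 10+10 for cluster-corrected recovery and familywise error,
and 37 null cohorts of n = 4+4 (~10⁵ voxel draws) for voxelwise type-I
control. Recovery tests drive the GLM with the ground-truth band-power
series; the EEG-to-regressor path is validated separately (recovered
regional alpha correlates ≈ 0.9 with the generative power series, and the
planted beta is recovered through the full cleaning chain), which keeps
the cohort-level simulations focused on the inferential claim.

## Known limitations

- The AR(1) coefficient is pooled, not voxelwise; strongly heterogeneous
  autocorrelation would be mis-whitened locally.
- Cluster-null smoothness is the nominal applied FWHM, not estimated from
  residuals; if effective smoothness differs, the extent threshold is
  mis-calibrated accordingly.
- The summary-statistics second level assumes comparable first-level
  precision across subjects (balanced designs).
- Anatomical labeling of peaks is out of scope; tables report MNI
  coordinates only.
- Covariate-adjusted group models beyond the two-group contrast are not
  provided.
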