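# Methods

## The problem

Auditory brainstem responses (ABRs) to continuous, natural speech can be
recovered from scalp EEG with linear encoding models.  The temporal response
function (TRF) is the least-squares kernel `h` relating a stimulus-derived
predictor `x(t)` to the EEG `y(t)`:

    y(t) = sum_l h(l) x(t - l) + noise.

Because subcortical responses are tiny (tens of nanovolts against tens of
microvolts of background EEG) and time-locked at millisecond precision, the
quality of the recovered TRF — in particular of its dominant wave V peak at
5–10 ms lag — depends strongly on how well the predictor models the
nonlinear auditory periphery.  This package implements the full analysis:
stimulus conditioning, periphery-model predictors of increasing realism,
EEG preprocessing, frequency-domain TRF estimation, evaluation (prediction
correlations, circular-shift null models, wave V SNR), group statistics,
and a synthetic-data generator that makes every stage testable end to end.

## TRF estimator

TRFs are estimated in closed form in the frequency domain:

    TRF = IFFT[ (sum_i w_i X_i* Y_i) / ((1/N) sum_i X_i* X_i) ]

with `X_i`, `Y_i` the Fourier transforms of the trial-`i` predictor and
EEG, `*` complex conjugation, and inverse-variance trial weights
`w_i = (1/var_i) / sum_j (1/var_j)`.  The asymmetric weighting (weights in
the numerator, plain 1/N in the denominator) is implemented exactly as
stated; the estimator is unregularised apart from a denominator floor of
`1e-10 x mean(denominator)`, which protects against empty frequency bins
without acting as ridge shrinkage.  The circular kernel is reordered onto
an ascending lag axis: inverse-transform index `k` maps to lag `k` for
`k <= T/2` and `k - T` beyond.

Post-processing: a linear-phase FIR bandpass, 30–1000 Hz, 4097 taps at
4096 Hz (odd length so the group delay is an integer sample and can be
compensated exactly), then smoothing with a unit-sum Hamming window of
2 ms nominal width (9 samples at 4096 Hz — the nearest odd count to
8.19 samples), then extraction of the [-10, 30] ms segment and subtraction
of the mean over [-10, 0) ms.  Filtering and smoothing are applied to the
full-length TRF before extraction, in that order.

Inside the leave-one-out evaluator the bandpass+smoothing cascade is
applied as a zero-phase spectral gain on the TRF spectrum rather than as a
time-domain convolution.  For lags more than half a filter length away
from the ±T/2 edges — which includes every lag the metrics ever read —
this is numerically identical to the delay-compensated convolution, and it
removes one long FFT per cross-validation fold.

## Predictors

All predictors are computed for a polarity pair (original and
sign-inverted stimulus), resampled to the 4096 Hz EEG rate with
anti-aliasing, circularly shifted by the integer lag maximising their
correlation with the rectified-speech predictor (removing model-inherent
delays), and scaled to unit variance so TRF amplitudes are comparable
across models (amplitudes are therefore in arbitrary units).

* **RS** — half-wave rectified speech.  Half-wave (not full-wave) because
  the polarity-pair protocol is only informative under half-wave
  rectification.
* **GT** — gammatone filterbank (4th-order IIR, unity gain at the center
  frequency), 31 filters from 80 to 8000 Hz spaced 1 ERB apart on the
  ERB-number scale `E(f) = 21.4 log10(0.00437 f + 1)`; the absolute value
  of each band's output is averaged across bands per sample.  (A Hilbert
  envelope is a plausible alternative reading of band "amplitude"; the
  absolute value is the default because it yields the same broadband
  half-wave-like drive as RS.)
* **OSS** — as GT, but each band passes an inner-hair-cell stage:
  half-wave rectification followed by a first-order 1000 Hz lowpass
  (unit DC gain), then the band average.
* **OSSA** — as OSS with five cascaded divisive adaptation loops per band
  before averaging.  Each loop divides its input by a lowpass-filtered
  copy of its own output, with time constants {5, 50, 129, 253, 500} ms,
  a soft onset-overshoot limiter (factor 10; outputs beyond the full-scale
  steady state are compressed onto an asymptote near 11x), and a minimum
  input of 1e-5 of full scale.  For constant input `I` the steady-state
  output is proportional to `I^(1/32)`, so a 1024-fold level difference
  compresses to a factor of 1.242.  Level dependence enters through the
  configurable full-scale convention: stimuli are calibrated to unit
  r.m.s. by default, standing in for the presentation level.
* **EXTERNAL** — an adapter for predictor series computed outside the
  package (e.g. band-averaged mean firing rates of a detailed
  auditory-nerve model with 43 high-spontaneous-rate fibers log-spaced
  125 Hz–16 kHz); such series receive the same resampling, alignment and
  normalisation as the built-in kinds.  The nerve model itself is out of
  scope here.

Stimulus conditioning before any predictor: stereo channels are averaged,
a first-order Butterworth highpass at 1 kHz is applied causally (bilinear
design at the file's rate, matching real-time presentation), and the
waveform is scaled to a target r.m.s. (default 1.0) — optionally matched
against speech-shaped noise, generated by imposing the reference's
full-length Fourier magnitudes on white-noise phases.  The highpass is
applied before calibration by default; the order is configurable since
acquisition protocols differ.

## EEG preprocessing

Causal first-order Butterworth highpass at 1 Hz (zero-phase optional);
notch filtering of 50 Hz and all harmonics up to 1000 Hz with a single
linear-phase FIR comb (frequency-sampling design, 1.8 s long, each notch
reaching -6 dB at ±2.5 Hz from its center, >= 60 dB attenuation at the
centers, < 0.01 dB ripple between notches), applied with exact group-delay
compensation; anti-aliased resampling to 4096 Hz.  Artifact suppression
zeroes a 1 s window centered on every sample deviating more than 5 SD
from the trial mean — mean and SD computed once, before any zeroing, and
two-sided by default (the safer reading for EEG artifacts; one-sided is
available).  Finally each trial is trimmed to its 2–242 s span so all
trials contribute exactly 240 s.

## Evaluation

For each data length `n = 2..8` trials (8..32 minutes), taken in
presentation order, leave-one-out cross-validation fits the TRF on `n-1`
trials per fold (polarity pair fit separately and averaged), predicts the
held-out trial by convolving the extracted TRF with the polarity-averaged
predictor (edge samples without full kernel support are dropped), and
averages the Pearson correlations over folds.  The fold-averaged TRF is
the final TRF at that length.  The noise floor is the same procedure with
predictors circularly shifted by 30, 60 and 90 s, averaged over shifts.

Wave V metrics use the filtered+smoothed full-length TRF (the [-10, 30] ms
extraction would destroy the noise-estimation range): the peak is the
global argmax in [5, 10] ms (ties resolve to the earliest lag), signal
power S is the mean square over a 5 ms window centered on the peak, noise
power N the mean over 96 contiguous non-overlapping 5 ms windows tiling
[-500, -20] ms, and SNR = 10 log10(S/N), floored at 0 dB, with detection
at 3 dB (signal power twice noise power).  Reported amplitude is the peak
value referenced to the [-10, 0) ms baseline mean.

## Statistics

Pairwise predictor contrasts on per-participant wave V SNRs use two-tailed
Wilcoxon signed-rank tests reporting T, the rank sum of positive
differences.  Zero differences are dropped and ties receive average ranks
(SNR flooring at 0 dB makes both common); the p-value is exact for
n <= 25 without ties and normal-approximate otherwise.  The family of
contrasts actually run is Holm-Bonferroni corrected (step-down:
sorted p-values multiplied by m-k+1, cumulative-maximum, capped at 1).
Participants lacking the full trial count are excluded from paired tests.
Cross-predictor consistency of per-participant metrics uses Pearson
correlations with t-distribution p-values (n-2 df).

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* **Stimulus**: pink-noise carrier, 2–8 Hz "syllabic" amplitude
  modulation (band-limited Gaussian envelope), intermittent silences
  (~16 % of time, gated by a 0.05–0.4 Hz process), 16384 Hz, unit r.m.s.
  after 1 kHz highpass.  It has speech-like modulation statistics and
  broadband content, but no harmonic/pitch structure, no phonemes, and no
  speaker variability.
* **Kernel**: a causal Gabor-like biphasic pulse, maximum at 7.0 ms
  (center of the wave V search window), envelope SD 2 ms, 250 Hz carrier
  — its energy sits comfortably inside the 30–1000 Hz analysis band.
* **EEG**: the kernel is convolved with a polarity-neutral unit-variance
  drive (mean of the periphery-model outputs for the original and
  inverted stimulus — rectification in the ear is polarity-insensitive,
  and this matches the analysis's polarity-pair averaging).  The drive is
  defined at the 4096 Hz analysis rate and the response upsampled into a
  simulated 8192 Hz acquisition, so the recovered TRF amplitude equals
  the kernel amplitude by construction.  Background is 1/f noise
  (12 uV r.m.s.), 50 Hz line noise plus harmonics to 200 Hz (5 uV at the
  fundamental, 1/k at harmonic k, random phases), and Poisson artifact
  bursts (0.5/min, 0.1–0.3 s, ~30x background) whose positions are
  logged.  Trial geometry is 8 trials of 244 s (240 s after trimming).
* **Calibration**: the kernel amplitude (0.045 uV per unit drive) was set
  once so that the median wave V SNR of a full 32-minute session is
  ~14 dB, the magnitude adaptation-based predictors reach on real group
  data, which also reproduces the qualitative finding that ~12 minutes
  suffice for >3 dB SNR in nearly all simulated sessions.
* All randomness flows from one session seed through numpy
  ``SeedSequence`` spawning; fixed seeds give bit-identical sessions.

What passing tests on this generator do **not** show: robustness to real
EEG nonstationarities (drowsiness, electrode drift), to predictor-model
mismatch beyond the configured families, or to the harmonic structure of
real speech.  The generator's `predictor_kind` can be set to a different
model than the analysis uses to study mismatch, but defaults to matched
rectified speech.

## Numerical choices and problem sizes

* All long convolutions (notch comb, TRF bandpass, predictions, kernel
  convolutions) run through real FFTs padded to 5-smooth lengths; the raw
  trial length (244 s at the acquisition rate) has a large prime factor
  that slows unpadded transforms substantially.
* The leave-one-out evaluator caches per-trial cross- and auto-spectra;
  circular null-model shifts become phase ramps on the cached spectra, so
  a full 2..8-trial sweep plus a three-shift null model costs a few dozen
  inverse FFTs per session.
* Simulation-based validation uses 20 independent sessions at the full
  study geometry (8 x 240 s usable at 4096 Hz); smaller configurations
  (fewer/shorter trials) are used in unit tests where only bookkeeping,
  not statistical power, is under test.
* Degenerate inputs fail loudly: silent stimuli, zero-variance trials,
  all-zero predictors, constant test trials, zero noise power and
  too-short TRFs all raise ``ValueError`` rather than returning NaNs.

## Known limitations

* The unregularised estimator is noisy at frequencies where the predictor
  has little power; the 30–1000 Hz bandpass and 2 ms smoothing are doing
  real work, exactly as in the protocol this package follows.
* Ridge/boosting TRF estimators and multivariate predictors are out of
  scope.
* Only single-channel (vertex-to-mastoid) analysis is supported; the BDF
  reader performs the referencing at load time.
* Earlier ABR waves (I–IV) are not searched for; with a 2 ms smoothing
  window they are generally not resolvable in this kind of TRF.
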