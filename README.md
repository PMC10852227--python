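# subtrf — subcortical TRFs from continuous-speech EEG

`subtrf` estimates **subcortical (brainstem) temporal response functions**
from single-channel EEG recorded while a listener hears continuous speech,
and compares stimulus predictors derived from auditory-periphery models of
increasing realism.  It is aimed at auditory-neuroscience and hearing
researchers who want ABR-like wave V peaks from natural speech instead of
clicks, and at method developers who need a fully simulatable pipeline.

## The model

The temporal response function (TRF) is the linear kernel *h* minimising
the error between the EEG *y* and a convolution of a stimulus-derived
predictor *x*:  y(t) ≈ Σ_l h(l) x(t−l).  With trials i = 1..N it is
computed in closed form in the frequency domain,

    TRF = F⁻¹[ Σᵢ wᵢ F{xᵢ}* F{yᵢ}  /  (1/N) Σᵢ F{xᵢ}* F{xᵢ} ],

with inverse-variance trial weights wᵢ ∝ 1/var(yᵢ) normalised to sum to 1.
The TRF is bandpassed to 30–1000 Hz (delay-compensated FIR), smoothed with
a 2 ms Hamming window, and the [−10, 30] ms segment is baseline-corrected
against [−10, 0) ms.  The **wave V** peak is detected in 5–10 ms; its SNR
is `10·log10(S/N)` with S the mean-square in a 5 ms window around the peak
and N the average mean-square over 5 ms windows tiling [−500, −20] ms,
floored at 0 dB and "detected" at ≥ 3 dB (signal power twice noise power).

Predictors (each as an original/sign-inverted **polarity pair**, aligned
and variance-normalised):

| kind | transformation |
|------|----------------|
| `RS`   | half-wave rectified speech |
| `GT`   | gammatone filterbank (31 filters, 80–8000 Hz, 1 ERB spacing), band-averaged magnitudes |
| `OSS`  | gammatone + inner-hair-cell stage (rectification + 1 kHz lowpass) |
| `OSSA` | as OSS + five divisive adaptation loops (steady state ∝ input^(1/32)) |
| `EXTERNAL` | adapter for precomputed series, e.g. auditory-nerve-model firing rates |

Model fit is the leave-one-out prediction correlation over trials, with a
circular-shift null model (30/60/90 s shifts) as the noise floor; group
comparisons use Wilcoxon signed-rank tests (rank sums above zero) with
Holm–Bonferroni correction.  A synthetic-data module generates speech-like
stimuli, a known biphasic kernel peaking at 7 ms, and EEG with 1/f noise,
50 Hz harmonics and artifact bursts, so the whole pipeline is verifiable
against ground truth.  See `docs/methods.md` for the full account.

## Worked example

Simulate one participant under the study geometry (8 trials × 244 s,
4096 Hz analysis rate) and evaluate the rectified-speech predictor at
increasing data lengths:

```python
from subtrf.pipeline import RunConfig, run_experiment

cfg = RunConfig(n_participants=1, base_seed=7, kinds=("RS",), lengths=(2, 4, 6, 8))
bundle = run_experiment(cfg)
print(bundle.results[["predictor_kind", "n_trials", "minutes", "prediction_r",
                      "null_r", "snr_db", "latency_ms", "detected"]]
      .round(4).to_string(index=False))
```

```
predictor_kind  n_trials  minutes  prediction_r  null_r  snr_db  latency_ms  detected
            RS         2      8.0        0.0070  0.0055  3.5627      7.8125      True
            RS         4     16.0        0.0118  0.0001 11.8228      7.3242      True
            RS         6     24.0        0.0223 -0.0007 13.6015      7.3242      True
            RS         8     32.0        0.0218 -0.0008 15.1174      7.3242      True
```

Reading the table: prediction correlations are small (a few percent —
typical for subcortical responses buried in ongoing EEG) but rise above
the null model's chance level as data accumulates; the wave V SNR grows
from barely detectable at 8 minutes to ~15 dB at 32 minutes, and its
latency stabilises within a quarter-millisecond of the simulated 7 ms
ground truth.  The same sweep runs from the shell:

```
subtrf simulate --trials 8 --seed 1 --out session/   # WAV + columnar EEG + truth
subtrf run --seed 7 --out results/                   # results.csv, stats.csv, manifest.json
```

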