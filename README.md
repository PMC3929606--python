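# fsampen

Fixed-tolerance sample entropy (fSampEn) estimation of respiratory muscle
effort from diaphragm mechanomyographic (MMGdi) signals contaminated by
cardiac vibration, with a synthetic-record generator and an evaluation
protocol comparing fSampEn against the classical amplitude estimators ARV
and RMS.

## The problem

The diaphragm, like every skeletal muscle, vibrates laterally while it
contracts. Recording that vibration on the lower chest wall (the MMGdi
signal, main power 5–25 Hz) gives a non-invasive window on respiratory
muscle effort: the signal's amplitude grows with the inspiratory load.
Amplitude is classically tracked with a moving-window average rectified
value (ARV) or root mean square (RMS) — but the heart sits right under the
sensor. Cardiac vibrations (the mechanocardiogram, MCG) have power below
~20 Hz, squarely inside the MMGdi band, so they cannot be filtered out, and
at low effort they dominate the recording. ARV and RMS respond to *all*
power in the window, cardiac included, and their effort estimates degrade
badly at low signal-to-noise ratios.

## The method

Sample entropy of a sequence `x(1..N)` with embedding dimension `m` and
tolerance `r` is

```
SampEn(m, r, N) = -ln( A^m(r) / B^m(r) )
```

where `B^m(r)` is the probability that two length-`m` templates lie within
Chebyshev distance `r` of each other (self-matches excluded, templates
`i = 1..N-m` at both lengths, per-template counts normalised by `N-m-1`),
and `A^m(r)` the probability that matching templates still match when
extended one sample. Classically `r` is renormalised by each analysis
window's own SD, which deliberately discards amplitude. **fSampEn** keeps a
single *fixed* absolute tolerance — a factor (0.1–1, default 0.3) of the
whole signal's SD — for every moving window (here 1 s, 90% overlap,
`m = 1`). A window with large excursions relative to the fixed `r` yields
few matches and high entropy, so the trace tracks amplitude; but because
the cardiac transient is deterministic and repetitive while muscle
vibration is random, the cardiac component adds much less entropy than it
adds ARV/RMS amplitude. That asymmetry is the method: an amplitude
estimator intrinsically robust to quasi-periodic interference.

The package synthesizes the complete evaluation bench: a four-load
respiratory modulation envelope (10 cycles per load at 18 cycles/min,
half-Hanning rise / plateau / fall inspiration, 133.33 s at 200 Hz),
band-limited Gaussian MMG vibration modulated by it, a damped-sinusoid
cardiac template convolved with a jittered impulse train, and per-load
amplitude calibration to hit clean-to-cardiac SNRs of −8.7, −1.7, 0.6 and
3.8 dB. Estimators are scored by per-load Pearson correlation with the
envelope and by the per-inspiratory-cycle mean relative error (MRE) between
clean- and noisy-signal traces,

```
MRE_i = (1/N_i) * sum_n |Xc(n) - Xn(n)| / Xc(n)
```

## Worked example

```python
import numpy as np
from fsampen import (FSampEnParams, MovingWindowSpec, synthesize,
                     estimator_trace, load_correlations, mre_per_cycle,
                     paired_traces)

record = synthesize(seed=1)
print("realized per-load SNR (dB):", np.round(record.realized_snr_db(), 1).tolist())

window = MovingWindowSpec(window_length_s=1.0, overlap_fraction=0.9)
for name in ("fSampEn", "ARV", "RMS"):
    params = FSampEnParams(m=1, r_value=0.3) if name == "fSampEn" else None
    trace = estimator_trace(record.mmg_noisy, window, name, params)
    corr = load_correlations(trace, record)
    clean, noisy = paired_traces(record, window, name, params)
    mre = mre_per_cycle(clean, noisy, record)
    print(f"{name:8s} R by load: {np.round(corr.r_by_load, 3).tolist()}"
          f"   MRE by load: {np.round(mre.load_means, 3).tolist()}")
```

prints

```
realized per-load SNR (dB): [-8.7, -1.7, 0.6, 3.8]
fSampEn  R by load: [0.936, 0.971, 0.964, 0.944]   MRE by load: [0.375, 0.37, 0.379, 0.241]
ARV      R by load: [0.801, 0.948, 0.969, 0.959]   MRE by load: [1.018, 0.417, 0.288, 0.159]
RMS      R by load: [0.464, 0.876, 0.933, 0.925]   MRE by load: [1.421, 0.399, 0.233, 0.138]
```

Read the first column (load L1, SNR −8.7 dB — cardiac vibration almost
9 dB *stronger* than the muscle signal): fSampEn still correlates at 0.94
with the true effort envelope where ARV manages 0.80 and RMS 0.46, and the
cardiac noise perturbs its per-cycle estimates by ~38% versus ~100% (ARV)
and ~140% (RMS). At the highest load (3.8 dB) all three estimators do
well — exactly the regime dependence the method predicts.

A command line wraps the same pipeline:

```bash
fsampen simulate --seed 1 --out record/
fsampen estimate --signal record/mmg_noisy.csv --estimator fsampen --out trace.csv
fsampen evaluate --record record/ --out tables/
fsampen sweep    --config config.yaml --out sweep/
```

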