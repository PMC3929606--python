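# Methods

## Estimator

Sample entropy follows the Richman–Moorman counting convention: for a
window `x(1..N)` and embedding dimension `m`, the templates `i = 1..N-m`
are used at both lengths `m` and `m+1` so that the two match counts are
comparable; matches use the Chebyshev distance with an inclusive
comparison (`<= r`); self-matches are excluded; per-template counts are
normalised by `N-m-1`; the logarithm is natural. The implementation is a
vectorised O(N²) pairwise comparison per window — at the package's working
window of 200 samples this is faster and simpler than neighbour-search
acceleration, which is deliberately not provided.

The fixed-tolerance variant resolves `r` **once per signal** as
`r_value × SD(entire signal)` (sample SD, `ddof=1`; configurable via
`FSampEnParams.sd_ddof` since the convention is not universal) and applies
that absolute tolerance to every analysis window. An absolute mode
(`r_mode="absolute"`) bypasses the SD entirely. Defaults mirror the
reference setup: `m = 1`, factor 0.3, 1-s window, 90% overlap, 200 Hz.

Moving windows advance by `round(L·(1-overlap))` samples and only full
windows are emitted, keeping estimator variance uniform across the trace;
values sit at window-center times.

**Degenerate windows.** SampEn is undefined when no template pair matches
at length `m` (B = 0) or none survives extension (A = 0). The core raises
a distinguishable error; the trace layer substitutes the largest finite
value a window of that size can produce, `-ln(1/((N-m)(N-m-1)))`, when
A = 0 but B > 0 (the estimate saturates rather than disappears), and
records a flagged NaN when B = 0 (such points are excluded from
correlations — a fabricated value would manufacture correlation points).
Both cases are counted on the trace object. On band-limited Gaussian
signals at the default tolerance neither case occurs in practice.

## Synthetic records

The generator emulates an incremental inspiratory-load protocol with
everything ground-truthed:

* **Envelope.** Four loads × 10 cycles at 18 cycles/min (cycle period
  60/18 s), inspiration = 50% of the cycle, split 25/50/25 into a
  half-Hanning rise, a plateau at the load amplitude, and a half-Hanning
  fall; expiration is zero. Cycle boundaries are rounded continuous-time
  boundaries; the record length is `floor(total_duration × fs)` samples so
  that the sample count divided by the rate equals the protocol duration
  (133.33 s) rather than overshooting it by a fractional sample.
* **Clean MMG.** Unit-SD Gaussian noise band-passed 5–25 Hz (muscle
  vibration is broadband and random), multiplied by the envelope, plus
  5–50 Hz Gaussian background noise with SD = 0.1 × the smallest plateau
  amplitude, standing in for non-cardiac biological noise at rest.
* **Cardiac train.** A deterministic 0.5-s template — three exponentially
  damped sinusoids at 5, 9 and 16 Hz, unit peak, spectral centroid below
  20 Hz — convolved with a unit impulse train whose RR intervals are
  normal with mean 60/72 s and SD 3% of the mean (truncated positive).
  Heart rate and jitter are this package's choices; physiologically
  ordinary resting values. The template is synthetic by construction (no
  recorded waveform is involved) and swappable via `MCGModel.template`.
* **SNR calibration.** Per-load envelope amplitudes are solved so that the
  realized `10·log10(P_clean/P_MCG)` over each load segment equals the
  targets −8.7/−1.7/0.6/3.8 dB. Because the background noise amplitude is
  itself tied to the smallest calibrated plateau, the solve is a short
  fixed-point iteration: per load, a quadratic in the scale (including the
  modulated-noise/background cross term) with the shared background
  amplitude updated each pass. Using the exact same noise realizations the
  synthesis will use makes the realized SNRs match the targets to machine
  precision, not merely within a tolerance. SNR is defined over the whole
  load segment (inspiration plus expiration); computing it over
  inspiratory portions only is possible via `segment_snr_db` on sliced
  segments.
* **Zero-phase filtering** uses a Butterworth band-pass designed at order
  4 and applied forward-backward (`sosfiltfilt`), the standard reading of
  a "zero-phase fourth-order band-pass".
* **Reproducibility.** One seed per record, split deterministically into
  independent streams for MMG noise, background noise and RR jitter, so
  components are individually reproducible and `MMGn = MMGc + MCG` holds
  sample-exactly.

What the generator does **not** emulate: motor-unit-level MMG genesis,
load-dependent spectral changes, motion artifacts, sensor nonlinearity,
and a real inspiratory-pressure reference (the envelope plays that role).
Passing tests therefore demonstrate robustness to *quasi-periodic
deterministic interference in band-limited Gaussian activity*, not
performance on recorded human data.

## Evaluation

* **Reference alignment.** Estimator traces are 1-window aggregates, so
  the default comparison averages the reference envelope over each
  window's support before correlating ("window_mean") — the like-for-like
  pairing. Correlating instead against the instantaneous envelope at the
  window center ("center" mode) imposes a deterministic shape mismatch
  that caps clean-record per-load R near 0.94 and penalises the noisier
  baselines hardest. Both modes are exposed; per-load results use
  window_mean. Whole-record comparisons are alignment-sensitive: against
  the instantaneous envelope fSampEn (tolerance factor 0.3–0.6) beats ARV
  and RMS because its trace is smoother, while with matched aggregation
  ARV — being linear in the envelope — closes the gap.
* **Per-load correlation** assigns trace points to loads by window-center
  sample (half-open intervals); windows straddling a boundary belong to
  the load containing their center.
* **MRE** (per inspiratory cycle, then mean ± SD per load over cycles
  fully inside the load) compares the clean- and noisy-signal traces of
  *one* estimator parameterization: for fSampEn both traces share the
  absolute tolerance resolved from the noisy signal — the clean trace is
  the hypothetical noise-free output of the estimator actually applied.
  Resolving a separate tolerance from each signal's own SD changes the
  error's dependence on the tolerance factor qualitatively (the two traces
  then differ by construction, not only through the interference) and is
  not what a clean-vs-noisy robustness comparison should measure. Points
  with a zero clean estimate are excluded and tallied rather than clamped.
* **Tolerance sweep** evaluates the factor grid 0.1–1 (step 0.05 by
  default) with ARV/RMS repeated across rows as r-independent baselines;
  `cycle_maxima` extracts per-cycle reference/estimate maxima for
  effort-vs-estimate scatter summaries.

## Numerical and scale choices

Simulated records are 26,666 samples (133.33 s at 200 Hz); a full
fSampEn trace costs ~0.4 s, so the multi-seed ordering checks in the test
suite (10 records × a five-point tolerance grid) complete in well under a
minute. Stochastic ordering assertions use 10 fixed seeds and require 9/10
agreement: at −8.7 dB single-seed reversals are possible and an all-seed
requirement would test the seeds, not the method. The seed-averaged MRE
curve is used for the monotonicity-in-r check for the same reason.

## Known limitations

* The envelope amplitudes are calibrated to SNR targets, not to recorded
  MMGdi amplitudes; absolute entropy values are therefore not comparable
  to values from physical recordings.
* The cardiac template is parametric; real MCG morphology varies between
  subjects and electrode sites, and template mismatch is untested.
* fSampEn saturates for amplitudes far above the fixed tolerance
  (`-ln` of a vanishing match ratio is bounded by the window size), which
  compresses its response at the highest loads; the tolerance factor
  trades low-load sensitivity against high-load linearity, and 0.3 is a
  compromise, not an optimum for every record.
* `m` is fixed at 1 by default and the implementation is exact but
  quadratic per window; very long windows (≫10³ samples) would warrant a
  neighbour-search rewrite.
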