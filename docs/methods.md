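# Methods notes

This note records the models, the defaults and why they were chosen, what
the synthetic generator does and does not emulate, and the numerical
decisions that are not obvious from the code.

## Cardiac pipeline

**QRS detection.** The Pan–Tompkins stages are implemented with zero-phase
(forward–backward) filtering, so no group-delay compensation is applied;
final R positions are refined to the raw-waveform maximum within ±75 ms of
each integrated-signal detection. Adaptive thresholds follow the classic
running-estimate update (signal peak 0.125/0.875, noise peak symmetric),
with search-back at half threshold when 1.66× the running R–R average
elapses without a beat, and a 200 ms refractory period. On clean synthetic
ECG the detector recovers beat times within ±5 ms at 1000 Hz; the test
suite requires recall and precision ≥ 0.99 and ±10 ms.

**NN cleaning.** A physiological gate (200–3000 ms) runs before the 20 %
filter so that detector artifacts cannot poison the sequential reference.
The 20 % rule compares each interval to the previous *retained* interval,
and removal is deletion — no replacement beats — with the cubic spline
bridging the gaps. The filter is idempotent by construction (a property
test asserts it).

**Tachogram and spectrum.** Cubic-spline resampling at 4 Hz; mean and
linear trend removed before AR fitting. The AR order defaults to 16
(configurable), the common convention of MATLAB HRV toolboxes; Burg
coefficients come from `statsmodels.regression.linear_model.burg`.

Two numerical choices matter here:

1. *Degenerate series.* A (near-)noiseless periodic tachogram drives the
   high-order Burg fit to a non-positive residual variance and poles outside
   the unit circle, including spurious unstable DC resonances. The order is
   stepped down by 2 until the fitted model is stable (positive residual
   variance, all poles strictly inside the unit circle); noisy physiological
   tachograms keep the requested order. The order actually used is recorded
   on the returned spectrum.
2. *Band integration.* Spectral lines of nearly periodic series have
   Lorentzian half-widths far below any feasible grid spacing (down to
   ~1e-8 Hz), so fixed-grid integration or plain adaptive quadrature
   misses essentially all of their power. Band powers are therefore
   integrated segment-wise between pole frequencies, and any segment
   adjacent to a resonance is integrated in the substituted variable
   u = arctan((f − f₀)/γ), which maps the Lorentzian onto a flat integrand
   and converges for arbitrary widths. The spectrum is then renormalised so
   the total 0–2 Hz power equals the variance of the detrended tachogram
   (Parseval normalisation); a pure sinusoid of amplitude a recovers a²/2
   in its band to ~0.1 %.

**SDNNi.** Segments are defined on elapsed onset time (50 s), not beat
count; a trailing partial segment contributes only with ≥ 10 beats.
Segments need ≥ 2 beats for a sample SD.

## EEG coherence

Sliding 2-s Hann windows with 75 % overlap give 0.5 Hz resolution (the
minimum that resolves the 1 Hz delta edge) and 597 windows on a 5-minute
record. Coherence is the magnitude-squared averaged-cross-spectrum form;
the implementation accumulates per-window cross products, enforces exact
matrix symmetry by a single symmetrised pass, clips to [0, 1], and defines
zero-power bins as coherence 0 with a warning rather than NaN.

Band adjacency averages *per-bin coherence* across the band (the
alternative — pooling spectra first — is deliberately not the default).
Band intervals are half-open [low, high) except gamma, closed at 40 Hz, so
shared edges (4, 8, 12, 25, 30 Hz) are never double counted. Graphs use raw
coherence in [0, 1]; no log transform and no pruning by default
(proportional thresholding is available as an option).

Artifact handling replaces a proprietary rejection system with a simple
amplitude-threshold rejector on consecutive windows; sliding windows
touching a flagged sample are excluded from spectral averaging, and fewer
than 8 surviving windows is an error.

## Graph metrics

Edge lengths are d = 1/w (the cited toolbox default; −log w is available).
L^w averages shortest-path distances over *ordered* pairs, exactly as the
printed double sum with an n(n−1) denominator. t_i^w uses the cube-root
geometric mean, following the toolbox's weighted clustering routine, which
guarantees C^w ∈ [0, 1] for weights in [0, 1]. The diagonal is forced to
zero before any metric so self-coherence of 1 cannot create self-loops.
Shortest paths use Dijkstra per source (scipy); the test suite checks exact
agreement with an exhaustive Floyd–Warshall relaxation oracle on hundreds
of random complete graphs.

## Statistics

- Outlier masking is cell-wise (a flagged HF value does not delete the
  subject's other variables), matching reporting of differing effective n
  per outcome. The test is the largest externally studentized residual
  against a Bonferroni-corrected two-sided threshold, iterated to
  convergence.
- Model routing: Shapiro–Wilk p < .05 *and* strictly positive values →
  gamma GLM; otherwise OLS. The gamma GLM uses a log link: the canonical
  inverse link has domain problems for group-mean contrasts near zero.
- η²ₚ = t²/(t²+df_resid) for both model families, using the Wald t of the
  group coefficient; this mirrors the linear-model formula since no
  GLM-specific recipe is standard.
- Covariates are mean-centered in the design. This leaves the group
  coefficient unchanged and keeps the Belsley condition index (unit-normed
  columns, √(λ_max/λ_min)) from flagging every high-mean covariate against
  the intercept; designs whose index still exceeds 30 are refused.
- Benjamini–Hochberg adjustment is a direct transcription of the step-up
  definition so adjusted p-values agree bit-for-bit with it;
  `statsmodels.multipletests` is the independent cross-check in the tests.
  The FDR family is all unique variable pairs within one group's
  correlation run; cross-group pooling is a config option.
- All tests are two-sided at α = .05.

## Synthetic data: what it emulates, and what it does not

The R–R generator modulates the instantaneous interval with two sinusoids
(defaults 0.1 Hz / LF, 0.25 Hz / HF, ~30 ms amplitudes, 8–10 ms Gaussian
jitter around a mean set by the target heart rate) — enough to give the
downstream tachogram the spectral structure the frequency-domain metrics
measure. It is *not* a cardiac dynamics model: no P/T waves, no
respiration coupling, no baroreflex feedback. The ECG renderer places a
Mexican-hat QRS template at each beat with R amplitude ≥ 5× baseline noise.

The EEG generator mixes brick-wall band-limited unit-variance sources into
channels with per-channel weights plus independent white noise. Because the
in-band source PSD equals that of unit-variance white noise, two channels
with weights a, b on a shared source and noise σ have closed-form in-band
coherence (ab)²/((a²+σ²)(b²+σ²)) — the calibration fixture with a = b = σ
= 1 targets 0.25. Band-edge spectral leakage through the Hann main lobe
biases the *band-averaged* value slightly low (~0.02), well inside the
±0.05 calibration tolerance. No volume conduction, no 1/f background, no
eye-blink morphology.

Cohorts (defaults: 53 cases / 58 controls, IQ distributions matching the
published demographic summaries, control HR 68 ± 7 bpm) inject: a case
heart-rate shift (+5 bpm), HF modulation power scaled by `effect_hf`
(default 0.5), theta coupling lowered by `effect_theta_cpl` (default 0.1,
raising theta CPL), and a latent bivariate Gaussian copula between each
case subject's R–R variability scale (lognormal, σ = 0.35 in log units)
and theta coupling strength, with latent correlation |ρ| =
`rho_sdnn_cpl_case` (default −0.4, mirroring the magnitude of the reported
case-group SDNNi–slow-band-CPL correlations). Measurement noise attenuates
the latent correlation, so the *measured* case-group Spearman r fluctuates
around ≈ −0.35 at n = 50; acceptance asserts its sign consistency, not its
magnitude. Passing tests therefore demonstrate internal consistency of the
pipeline under this generative model, not clinical validity on real
recordings.

## Problem sizes used in validation

End-to-end effect-recovery runs use 20 cohorts of 50/50 subjects with
5-minute records, cardiac input as R–R series, and EEG synthesized at
250 Hz — comfortably above twice the 40 Hz top analysis band, and
statistically equivalent for coherence estimates on the 0.5 Hz grid. The
type-I error simulation uses 1000 replicate null tables of 25/25. Windowed
coherence estimates use the default 2 s / 75 % overlap configuration
throughout.

## Known limitations

- No very-low-frequency HRV band, nonlinear HRV indices, or respiration
  correction.
- Scalp-level plain coherence only: no source reconstruction, directed
  measures, or volume-conduction-robust variants.
- EDF files are read (via mne) but outputs and synthetic fixtures are
  plain text (CSV/TSV); EDF export is not provided.
- The gamma-GLM effect size uses the Wald-t analogue of η²ₚ; other
  conventions exist and will differ slightly.
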