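# Methods

`freqtag` analyses two-frequency flicker-tagged EEG from word-reading
experiments: two segments of a displayed word flicker at distinct rates, the
steady-state visual evoked potential (SSVEP) at each tagging frequency is
extracted with a spatial filter, and the time course of its signal-to-noise
ratio (SNR) is modelled with growth-curve mixed regression.  This note
documents the models, the defaults and why, the numerical conventions, and
what the synthetic-data generator does and does not emulate.

## Stimulation model

A segment flickering with `c_on` on- and `c_off` off-cycles of a monitor
running at refresh rate `R` drives a response at the fundamental

    f = R / (c_on + c_off).

The default design is `R = 75` Hz with 4-cycle (stem, `f1 = 18.75` Hz) and
6-cycle (suffix, `f2 = 12.50` Hz) periods.  Nonlinear integration of the two
drives appears at the intermodulation (IM) frequencies `f1 + f2 = 31.25` Hz
and `f2 − f1 = 6.25` Hz.  Analysis is restricted to fundamentals (no
harmonic stacking): the response is assumed strongest there, and all
downstream grids are chosen so these four frequencies fall exactly on
analysis bins.

## Synthetic data generator

The generator produces epoched multichannel EEG (µV) with the statistical
structure the analysis assumes, so every stage is testable without any
recording:

* **Evoked sources.** Per condition (TS = truly suffixed, PS =
  pseudo-suffixed, NS = non-suffixed), sinusoids at `f1`, `f2` and `f1+f2`
  are multiplied by a rise-and-sustain envelope: a Gaussian bump (FWHM
  `envelope_width_ms`, default 300 ms) peaking at the configured latency,
  decaying to a sustained plateau at 60 % of peak, zero before stimulus
  onset.  This family is smooth and makes "peak latency" well defined.
  Defaults: stem-frequency peaks at 400 ms for TS/PS and 600 ms for NS
  (morphemic segmentation speeds the response); suffix-frequency amplitude
  ordered TS > PS > NS; the IM source is strongest for TS.  The source at
  `f2 − f1` is off by default (`im_diff_scale = 0`), mirroring a null
  difference-term finding; square-wave harmonics can be enabled with
  `add_harmonics` for robustness checks.
* **Topographies.** Sources project to the scalp through Gaussian-on-sphere
  weights: the stem source focal right-posterior (O2), the suffix source
  broader and left-parietal (P3), IM and alpha occipital (Oz).  The
  parietal suffix placement keeps it only partially overlapping occipital
  alpha, which is what lets a 12.5 Hz filter separate the two.
* **Background.** ~10 Hz alpha with slow amplitude modulation on an
  occipital topography (3 µV), spatially correlated 1/f noise (6 µV RMS per
  channel), Poisson blink transients (raised cosine, 300 ms, ~130 µV at the
  lower ocular channel, decaying over frontal sites; rate 0.04/epoch), and
  per-subject bad sensors (probability 0.015/channel, noise ×8).
* **Between-subject variance.** A per-subject log-normal gain
  (σ = `subject_gain_sigma`, default 0.2) multiplies all evoked amplitudes.
* **Determinism.** One global seed spawns per-subject generators via
  `SeedSequence([seed, subject_index])`; identical (config, seed) pairs are
  bit-identical.

Source amplitudes (stem 1.3 µV; suffix 2.1/1.9/1.65 µV for TS/PS/NS; IM
0.8/0.45/0.4 µV) were calibrated once so that group-level SNR lands in the
realistic 1.5–2 range at the tagged frequencies and ~1.3–1.5 at the IM sum;
no absolute µV scale is claimed.

**Presets.**  The full-study preset is 17 subjects, 64 scalp
channels at 512 Hz, 51 trials per condition (153 epochs/subject), epochs
−200…+2000 ms.  The desk-scale preset used throughout the simulation suites
is 8 subjects, 32 channels, 24 trials/condition at 256 Hz — the package's
working size for iteration, chosen to keep all analysis frequencies and the
5–100 Hz band below Nyquist while making hundred-replicate studies cheap.

**What the generator does not emulate:** real scalp volume conduction
(sources are Gaussian blobs, not dipole forward models), non-stationary
alpha reactivity, muscle/line noise, eye movements other than blinks,
latency jitter across trials, and any lexical structure.  Passing tests
therefore demonstrate correctness and calibration of the *analysis* under
the assumed signal model, not claims about human data.

## Preprocessing

Documented chain: mastoid re-reference → band-pass → epoching → baseline →
bad-sensor replacement → amplitude rejection → detrend.

* **Re-reference:** subtract the mean of M1/M2 from every channel.
  Re-applying the operation is a no-op (the references average to zero),
  which is asserted in tests.
* **Band-pass 5–100 Hz:** zero-phase windowed-sinc FIR (Hamming), applied
  forward-backward; transition width 25 % of each band edge.
* **Epoching:** −200…+2000 ms around word onset; events that do not fit are
  reported and skipped.
* **Baseline:** "normalization" is implemented as subtraction of the
  −200…0 ms mean per trial and channel — the standard baseline correction;
  it preserves µV units.  (Division/z-scoring was considered and rejected as
  the default; subtraction is recorded in the provenance.)
* **Bad sensors:** per trial, a channel's peak-to-peak amplitude is
  z-scored robustly across scalp channels (median / 1.4826·MAD) and flagged
  above z = 5; flagged sensors are replaced by Perrin spherical-spline
  interpolation (stiffness m = 4, 50 Legendre terms, ridge 1e-5) from the
  good scalp sensors of the same trial.  The implementation is
  cross-checked against MNE's interpolation matrix.  With fewer than four
  scalp channels, detection degrades to a warning and an empty mask.
* **Rejection:** a trial is rejected when any checked sensor exceeds
  ±100 µV at any sample.  Ocular channels are checked like scalp channels;
  sensors that were interpolated on that trial are exempt.  Rejected trials
  are excluded from every downstream average.
* **Drift:** per-epoch linear detrend, removing the "sawtooth" leakage that
  slow drifts cause in the Fourier spectrum.

Under the default generator, the chain interpolates well under 5 % and
rejects well under 10 % of the data (asserted as bounds only).

## RESS spatial filtering

For each subject and target frequency, rhythmic entrainment source
separation contrasts S, the trial-averaged covariance of the data
narrowband-filtered at the target (frequency-domain Gaussian, FWHM 0.6 Hz),
against R, the mean covariance at ±2.5 Hz neighbors (FWHM 2 Hz), over the
0–1000 ms window, pooling all conditions to avoid condition-specific
overfitting.  R is shrunk by `R ← (1−γ)R + γ·mean(eig R)·I` with γ = 0.01
for numerical stability at 64 channels.  The filter is the leading
generalized eigenvector of (S, R); the spatial pattern (forward model) is
S·w, unit-normalized with its largest-magnitude entry made positive so
topographies are comparable across subjects.  Only scalp channels enter the
fit.  Filter widths are declared defaults exposed in `RESSParams`; the
neighbor placement mirrors the SNR neighborhood definition.

Properties asserted in tests: permutation equivariance over channels, scale
invariance of downstream SNR, recovery of planted mixing vectors
(|cos| > 0.95 at unit noise), and separation of planted-signal from
noise-only eigenvalues.

## SNR spectra and time courses

* **SNR definition:** power at the tagged frequency divided by the mean
  power at bins within ±2.5 Hz but strictly outside ±1 Hz of it, applied to
  the actual grid (offsets rounded at 1e-6 Hz).  On the 1.25 Hz STFT grid
  the neighbors are {−2.5, −1.25, +1.25, +2.5} Hz; on the 1 Hz static grid
  they are {−2, +2} Hz (logged per run).
* **Time-resolved power:** moving 800 ms Hann window in 32 ms steps; bin
  centers start at epoch start + 400 ms, so the 200–1000 ms statistics grid
  (26 bins) lies exactly on the lattice.  Power is evaluated by explicit
  DFT sums on the 1.25 Hz grid — exact at the tagged frequencies for any
  sampling rate — with Welch normalization (summed PSD × Δf ≈ variance),
  averaged across trials *before* the ratio (ratio of averages; stabilizes
  the denominator at realistic trial counts).  Bin centers (not window
  onsets) are the reported times.
* **Static entrainment spectrum:** one Fourier transform over 0–1000 ms
  (1 Hz resolution); the grid is offset so the filter's target frequency is
  exactly on a bin; each bin is converted to SNR for the
  per-subject entrainment check.
* **IM analysis:** identical machinery with dedicated RESS filters at
  31.25 and 6.25 Hz.  The 6.25 Hz case inherits a worse null (few low-
  frequency neighbor bins, 1/f slope, alpha leakage) and is retained for
  completeness rather than sensitivity.

**Known bias.** Because the filter is optimized and evaluated on the same
trials, the null SNR sits slightly above 1; the bias grows with the
channels-to-trials ratio (roughly 1.1–1.2 at 64 channels × 153 trials and
worse for very small configurations).  The null-calibration suite therefore
runs at study-like dimensions, and condition comparisons — which share a
single pooled filter — are unaffected.

## Growth-curve analysis

The 200–1000 ms SNR series (26 bins) per subject × condition is modelled as

    snr ~ (1 + ot1 + ot2 [+ ot3]) * condition + (1 | subject)

with centered orthonormal polynomial terms (Gram–Schmidt on t, t², t³;
zero-sum, unit-norm columns — R's `poly()` construction), condition
dummy-coded against a declared reference (TS by default, releveled to PS
for the PS–NS contrast), and by-subject random intercepts.  Stem and IM
trajectories use cubic bases (two turning points); suffix trajectories
quadratic — the order is a configuration field.  Because the basis is
centered, the intercept estimates the interval mean, the linear term the
average rate of change, the quadratic the sharpness of the central peak and
the cubic the inflection structure.  Coefficient magnitudes depend on the
unit-norm scaling convention, so comparisons with differently scaled fits
are by sign and significance pattern.

Estimation is REML via statsmodels `MixedLM`, refined by an exact
one-dimensional profile of the restricted likelihood in λ = τ00/σ² (the
random-intercept model profiles β and σ² out in closed form), which pins
variance components to near machine precision.  Satterthwaite degrees of
freedom are computed analytically: for coefficient contrast c,
`df = 2 f² / Var(f)` with `f = c'(X'V⁻¹X)⁻¹c`, the variance from the delta
method with the inverse REML Fisher information of (σ², τ00); block
structure (V_j = σ²I + τ00·11') makes all terms closed-form.  The
implementation is cross-validated against lme4 + lmerTest.  Reported
summaries: σ², τ00, ICC = τ00/(τ00+σ²), Nakagawa marginal/conditional R².

P-values of all fixed effects except the intercept form one
Benjamini–Hochberg family per fitted model (the correction family is not
uniquely determined by the design; this choice is logged per run).  BH is
statsmodels' `fdr_bh`, verified exhaustively against the literal step-up
definition.  Re-applying BH to already-adjusted values is *not* an identity
in general; the suite asserts determinism and monotonicity instead.

Within-subject error bars use Cousineau subject-centering (per time bin,
across the k = 3 condition cells) with the Morey √(k/(k−1)) correction.
Peak latency is the bin center of the series maximum (ties → earliest bin;
monotone series peak at the boundary bin; flat series warn and return the
earliest bin), or the argmax of the fitted polynomial on a 1 ms grid when
model-based smoothing is requested.

At desk scale the empirical ICC is ~0.2–0.4: the simulated between-subject
gain spread is deliberately conservative compared with human data, where
subject-level differences dominate.

## Validation simulations and problem sizes

The validation suite (also driven by `scripts/acceptance.py`) uses:

* latency recovery: full pipeline on the desk-scale preset, planted
  400 vs 600 ms stem envelopes; the NS−TS group peak-latency difference is
  summarized as the median over 100 seeds in the test suite (25 seeds in
  the reproduction script).  The measured peaks sit ~100–140 ms later than
  the planted envelope peaks — the 800 ms window integrates the sustained
  plateau — but the shift is common to conditions, so the difference is
  recovered.
* null SNR calibration: 20 noise-only simulations at 64 channels ×
  51 trials/condition.
* type-I control: 500 replicates of null SNR trajectories (common smooth
  trend + subject intercepts + noise, 8 subjects) through the cubic
  interaction model; the BH-adjusted interaction discovery rate is compared
  with the nominal 0.05 level plus binomial slack.
* pattern recovery: planted 8-channel mixtures at unit noise, 10 seeds.

These sizes were chosen as the smallest runs at which the summarized
statistics are stable across seeds.

## Limitations

* The random-effects structure is intercept-only (no random slopes, no
  autocorrelated residuals), matching the modelled design; trajectories
  with strong subject-specific shapes would violate it.
* EDF export writes 16-bit EDF with 1-second records (integer sampling
  rates only); BDF is read but not written.
* The spherical-spline interpolation assumes reasonable scalp coverage;
  with very few or clustered good channels the ridge term dominates.
* SNR at 6.25 Hz is reported but weakly calibrated (see above).
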