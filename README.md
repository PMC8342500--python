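# freqtag

Analysis of **frequency-tagged steady-state visual evoked potentials
(SSVEPs)** for two-frequency flicker designs, as used to study how readers
process the parts of a written word: the first segment of a displayed word
(the stem) flickers at one rate, the rest (the suffix) at another, and each
segment's cortical response can then be separated in the frequency domain.
The package is for EEG researchers who want a tested, scriptable pipeline
from (simulated or recorded) multichannel EEG to condition contrasts on
SSVEP time courses.

## What it computes

With a monitor refresh rate *R* and a flicker period of *c* refresh cycles,
a segment drives a response at *f = R/c*: the default design tags stems at
*f₁* = 75/4 = 18.75 Hz and suffixes at *f₂* = 75/6 = 12.50 Hz, with
intermodulation (IM) components at *f₁+f₂* = 31.25 Hz and *f₂−f₁* = 6.25 Hz
indexing nonlinear integration of the two inputs.

The pipeline:

1. **Simulation** (`freqtag.synth`) — seeded multi-subject EEG with planted
   condition-dependent SSVEP sources, alpha, 1/f noise, blinks and bad
   sensors; conditions TS/PS/NS (truly, pseudo- and non-suffixed words).
2. **Preprocessing** (`freqtag.preprocess`) — mastoid re-reference,
   5–100 Hz zero-phase FIR, −200…2000 ms epochs, baseline subtraction,
   robust bad-sensor detection with Perrin spherical-spline replacement,
   ±100 µV rejection, linear detrend.
3. **RESS** (`freqtag.ress`) — rhythmic entrainment source separation: a
   per-subject spatial filter **w** maximizing `wᵀS w / wᵀR w` (generalized
   eigendecomposition of the covariance at the tagged frequency against its
   spectral neighbors), projecting 64 channels to one component.
4. **Spectral** (`freqtag.spectral`) — SNR = P(f) / mean P(f ± 2.5 Hz,
   excluding ±1 Hz), as moving-window time courses (800 ms Hann, 32 ms
   steps) and static 0–1000 ms entrainment spectra, including the IM
   frequencies.
5. **Growth-curve analysis** (`freqtag.gca`) — the 200–1000 ms SNR series
   is fit with `snr ~ (ot1 + ot2 [+ ot3]) * condition + (1 | subject)` on
   centered orthonormal polynomials, REML with Satterthwaite degrees of
   freedom, Benjamini–Hochberg correction, Cousineau–Morey within-subject
   SEMs, and peak-latency summaries.

See `docs/methods.md` for the full model description and numerical
conventions.

## Worked example

```python
import numpy as np
import freqtag as ft

spec = ft.derive_stimulation(75.0, 1, 3, 1, 5)
print(f"tagged: f1={spec.f1} Hz, f2={spec.f2} Hz; IM: {spec.im_sum}, {spec.im_diff} Hz")

cfg = ft.desk_scale_config(seed=1)          # 8 subjects, 32 ch, 24 trials/cond
tcs = []
for i in range(cfg.n_subjects):
    ep = ft.generate_subject(cfg, i)
    ep, report = ft.preprocess_epochs(ep)
    filt = ft.fit_ress(ep, spec.f1)          # stem-frequency RESS filter
    tcs += [tc.restrict() for tc in ft.snr_timecourse(ep, filt, spec.f1)]

design = ft.build_design(tcs, reference="TS", order=3)
fit = ft.fit_lmm(design)
print(f"observations: {fit.n_obs}, subjects: {fit.n_subj}")
print(f"intercept (mean SNR 200-1000 ms): {fit.coef('Intercept')['estimate']:.2f}")
row = fit.coef("Linear:NS")
print(f"Linear:NS  b={row['estimate']:.2f}  t={row['t']:.2f}  p_adj={row['p_adj']:.4f}")

bins = tcs[0].bin_centers
for c in ("TS", "NS"):
    y = np.mean([tc.snr for tc in tcs if tc.condition == c], axis=0)
    print(f"{c} group peak latency: {ft.peak_latency(y, bins):.0f} ms")
```

prints (seed 1):

```
tagged: f1=18.75 Hz, f2=12.5 Hz; IM: 31.25, 6.25 Hz
observations: 624, subjects: 8
intercept (mean SNR 200-1000 ms): 1.92
Linear:NS  b=0.77  t=5.65  p_adj=0.0000
TS group peak latency: 552 ms
NS group peak latency: 680 ms
```

Reading the output: the intercept is the mean SNR over the analysis
interval (the basis is centered, so it is not the value at t = 0); the
positive `Linear:NS` interaction says the non-suffixed condition's SNR
rises later than the truly-suffixed reference — consistent with the planted
envelopes, whose stem-frequency response peaks 200 ms later for NS; and the
group peak latencies differ by 128 ms at this single seed (the median over
many seeds recovers the planted 200 ms difference).

The same stages are available from the shell:

```bash
freqtag simulate --seed 1 --out sim/
freqtag preprocess --in sim/S00_epochs.npz --out clean.npz
freqtag ress --in clean.npz --freq 18.75 --out filt.json
freqtag snr  --in clean.npz --filter filt.json --freq 18.75 --out snr.tsv
freqtag gca  --in snr.tsv --order 3 --reference TS --out gca.tsv
freqtag run-all --config demo.yaml --seed 1 --out out/
```

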