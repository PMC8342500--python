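"""SNR spectra and SNR time courses of RESS components.

The steady-state response is quantified as a signal-to-noise ratio: power at
the tagged frequency divided by the mean power at neighboring frequency bins
within ±2.5 Hz but outside ±1 Hz of it.  Being a ratio, the SNR is invariant
to global amplitude scaling and comparable across subjects.

Time-resolved power comes from a short-time Fourier transform with a moving
800 ms Hann window in 32 ms steps (frequency resolution 1000/800 = 1.25 Hz),
with bin centers anchored so that the 200-1000 ms statistics grid (26 bins)
lies exactly on the 32 ms lattice.  Power is averaged across trials before
the SNR is formed (ratio of averages), which stabilizes the denominator at
realistic trial counts.  The "static" entrainment spectrum is a single
Fourier transform over 0-1000 ms (resolution 1 Hz); its frequency grid is
offset so the target frequency lies exactly on a bin, which makes the
neighbor rule select offsets of ±2 Hz there.

Spectral estimates are evaluated by explicit discrete Fourier sums on the
stated frequency grid, so tagged frequencies (18.75, 12.50, 31.25, 6.25 Hz)
are measured exactly regardless of window length in samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import CONDITIONS, EpochSet
from .ress import RESSParams, SpatialFilter, apply_filter, fit_ress
from .stimulation import StimulationSpec

logger = logging.getLogger(__name__)


class SpectralError(ValueError):
    pass


@dataclass
class PowerSpectrum:
    """Per-frequency values over one analysis window (power or SNR units)."""

    freqs: np.ndarray
    power: np.ndarray
    window_ms: tuple[float, float]
    resolution: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.power < 0):
            raise SpectralError("power must be non-negative")
        if len(self.freqs) > 1 and not np.allclose(
            np.diff(self.freqs), self.resolution, atol=1e-9
        ):
            raise SpectralError("frequency grid must be uniform at `resolution`")


@dataclass
class SNRTimeCourse:
    """SNR per time bin at one frequency for one subject and condition."""

    subject_id: str
    condition: str
    freq: float
    bin_centers: np.ndarray  # ms
    snr: np.ndarray

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if np.any(self.snr < 0):
            raise SpectralError("snr must be non-negative")

    def restrict(self, t0: float = 200.0, t1: float = 1000.0) -> "SNRTimeCourse":
        m = (self.bin_centers >= t0 - 1e-9) & (self.bin_centers <= t1 + 1e-9)
        return SNRTimeCourse(
            self.subject_id, self.condition, self.freq,
            self.bin_centers[m], self.snr[m],
        )


# ---------------------------------------------------------------------------
# spectral estimation primitives


def _dft_power(
    x: np.ndarray, sfreq: float, freqs: np.ndarray, taper: np.ndarray | None = None
) -> np.ndarray:
    """Power spectral density of ``x`` (last axis) at arbitrary frequencies.

    Welch-style normalization: ``2 |DFT_w|^2 / (fs * sum(w^2))`` so that the
    sum of P(f)*Δf over the positive grid approximates the signal variance.
    """
    n = x.shape[-1]
    t = np.arange(n) / sfreq
    w = np.ones(n) if taper is None else taper
    basis = np.exp(-2j * np.pi * np.outer(freqs, t)) * w  # (freqs, samples)
    coef = x @ basis.T.conj()
    return 2.0 * np.abs(coef) ** 2 / (sfreq * np.sum(w**2))


@dataclass
class STFTPower:
    """Trial-averaged time-frequency power on a fixed bin grid."""

    bin_centers: np.ndarray  # ms
    freqs: np.ndarray  # Hz
    power: np.ndarray  # (bins, freqs)


def stft_power(
    component: np.ndarray,
    times: np.ndarray,
    sfreq: float,
    window_ms: float = 800.0,
    step_ms: float = 32.0,
    freqs: np.ndarray | None = None,
) -> STFTPower:
    """Moving-Hann-window Fourier power, averaged over trials.

    ``component`` is (trials, samples) or (samples,).  Bin centers start at
    ``times[0] + window_ms/2`` and advance in ``step_ms`` steps as long as
    the window fits the epoch.  The frequency grid defaults to multiples of
    the window's resolution (1000/window_ms Hz) up to 45 Hz.
    """
    x = np.atleast_2d(np.asarray(component, dtype=float))
    times = np.asarray(times, dtype=float)
    n = x.shape[-1]
    L = int(round(window_ms * sfreq / 1000.0))
    if L > n:
        raise SpectralError(
            f"window of {window_ms} ms ({L} samples) exceeds the epoch ({n})"
        )
    res = 1000.0 / window_ms
    if freqs is None:
        freqs = res * np.arange(1, int(45.0 / res) + 1)
    freqs = np.asarray(freqs, dtype=float)

    first = times[0] + window_ms / 2.0
    last = times[-1] - window_ms / 2.0
    n_bins = int(np.floor((last - first) / step_ms + 1e-9)) + 1
    centers = first + step_ms * np.arange(n_bins)

    taper = np.hanning(L)
    power = np.empty((n_bins, len(freqs)))
    half = L // 2
    for b, c in enumerate(centers):
        i = int(np.argmin(np.abs(times - c)))
        start = min(max(i - half, 0), n - L)
        seg = x[:, start : start + L]
        power[b] = _dft_power(seg, sfreq, freqs, taper).mean(axis=0)
    return STFTPower(bin_centers=centers, freqs=freqs, power=power)


# ---------------------------------------------------------------------------
# SNR


def neighbor_bins(
    freqs: np.ndarray, f: float, outer_hz: float = 2.5, inner_hz: float = 1.0
) -> np.ndarray:
    """Indices of the neighbor bins of ``f`` on the actual grid.

    A bin at offset Δf qualifies when ``inner_hz < |Δf| <= outer_hz``
    (offsets rounded to 1e-6 Hz before comparison).
    """
    freqs = np.asarray(freqs, dtype=float)
    d = np.round(np.abs(freqs - f), 6)
    idx = np.flatnonzero((d > inner_hz) & (d <= outer_hz))
    if idx.size == 0:
        raise SpectralError(
            f"no neighbor bins for {f} Hz with rule ({inner_hz}, {outer_hz}] "
            f"on grid step {np.diff(freqs)[0] if len(freqs) > 1 else '?'} Hz"
        )
    return idx


def snr(
    power: np.ndarray,
    freqs: np.ndarray,
    f: float,
    outer_hz: float = 2.5,
    inner_hz: float = 1.0,
) -> float | np.ndarray:
    """SNR at ``f``: P(f) / mean(P at neighbor bins).

    ``power`` may be a vector over frequencies or an array with frequencies
    on the last axis (e.g. bins x freqs), in which case a vector of SNRs is
    returned.
    """
    freqs = np.asarray(freqs, dtype=float)
    hit = np.flatnonzero(np.round(np.abs(freqs - f), 6) == 0)
    if hit.size != 1:
        raise SpectralError(f"{f} Hz is not on the frequency grid")
    idx = neighbor_bins(freqs, f, outer_hz, inner_hz)
    p = np.asarray(power, dtype=float)
    num = p[..., hit[0]]
    den = p[..., idx].mean(axis=-1)
    return num / den


# ---------------------------------------------------------------------------
# high-level operations


def snr_timecourse(
    ep: EpochSet,
    filt: SpatialFilter,
    f: float,
    window_ms: float = 800.0,
    step_ms: float = 32.0,
) -> list[SNRTimeCourse]:
    """SNR time course of the RESS component at ``f``, one per condition.

    Power is averaged over the non-rejected trials of each condition before
    the SNR ratio is formed.
    """
    comp, conds = apply_filter(filt, ep)
    out = []
    for cond in CONDITIONS:
        sel = conds == cond
        if not sel.any():
            continue
        tf = stft_power(comp[sel], ep.times, ep.sfreq, window_ms, step_ms)
        vals = snr(tf.power, tf.freqs, f)
        out.append(
            SNRTimeCourse(
                subject_id=ep.subject_id,
                condition=cond,
                freq=f,
                bin_centers=tf.bin_centers,
                snr=vals,
            )
        )
    return out


def static_snr_spectrum(
    ep: EpochSet,
    filt: SpatialFilter,
    window_ms: tuple[float, float] = (0.0, 1000.0),
    fmin: float = 5.0,
    fmax: float = 40.0,
) -> PowerSpectrum:
    """Single-window Fourier spectrum of the component, in SNR units.

    The entrainment check: a single Fourier transform over the analysis
    window (resolution = 1000 / window length, i.e. 1 Hz for 0-1000 ms),
    converted bin-wise to SNR.  The grid is offset so the filter's target
    frequency falls exactly on a bin; with a 1 Hz grid the neighbor rule
    then selects offsets of ±2 Hz (logged per run).
    """
    t0, t1 = window_ms
    res = 1000.0 / (t1 - t0)
    f0 = filt.target_freq
    start = f0 - np.floor((f0 - fmin) / res + 1e-9) * res
    freqs = np.arange(start, fmax + 1e-9, res)

    comp, _ = apply_filter(filt, ep)
    win = (ep.times >= t0) & (ep.times <= t1 - 1e-9)
    if not win.any():
        raise SpectralError(f"window {window_ms} ms outside the epoch")
    seg = comp[:, win]
    power = _dft_power(seg, ep.sfreq, freqs).mean(axis=0)

    vals = np.empty_like(power)
    for i, f in enumerate(freqs):
        idx = neighbor_bins(freqs, f)
        vals[i] = power[i] / power[idx].mean()
    logger.info(
        "static SNR spectrum at %.2f Hz: grid step %.3f Hz, neighbor offsets "
        "of the target bin: %s",
        f0, res,
        np.round(freqs[neighbor_bins(freqs, f0)] - f0, 3).tolist(),
    )
    return PowerSpectrum(freqs=freqs, power=vals, window_ms=window_ms, resolution=res)


def im_timecourses(
    ep: EpochSet,
    spec: StimulationSpec,
    params: RESSParams | None = None,
    window_ms: float = 800.0,
    step_ms: float = 32.0,
) -> dict[float, list[SNRTimeCourse]]:
    """SNR time courses at the intermodulation frequencies.

    Fits a dedicated RESS filter at ``spec.im_sum`` and ``spec.im_diff``
    (same recipe as the tagged frequencies) and computes per-condition SNR
    time courses for each.
    """
    out: dict[float, list[SNRTimeCourse]] = {}
    for f in (spec.im_sum, spec.im_diff):
        filt = fit_ress(ep, f, params)
        out[f] = snr_timecourse(ep, filt, f, window_ms, step_ms)
    return out


def timecourses_to_rows(tcs: list[SNRTimeCourse]) -> list[dict]:
    """Tidy rows (subject, condition, freq, bin_center_ms, snr) for TSV export."""
    rows = []
    for tc in tcs:
        for t, v in zip(tc.bin_centers, tc.snr):
            rows.append(
                {
                    "subject": tc.subject_id,
                    "condition": tc.condition,
                    "freq": tc.freq,
                    "bin_center_ms": float(t),
                    "snr": float(v),
                }
            )
    return rows
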