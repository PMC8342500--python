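"""Preprocessing chain for frequency-tagged EEG.

The documented order is: mastoid re-reference -> 5-100 Hz zero-phase FIR
band-pass -> epoching (-200..+2000 ms) -> prestimulus baseline subtraction ->
robust bad-sensor detection and spherical-spline replacement -> amplitude
rejection (100 µV, sensor-by-sensor) -> per-epoch linear detrend (removes the
"sawtooth" spectral-leakage artifact of slow drifts).

"Normalization" is read as prestimulus-mean subtraction: it is the standard
baseline correction and preserves µV units.  The noisy-sensor rule is a
per-trial robust z-score on peak-to-peak amplitude (median/MAD across scalp
channels).  Interpolated sensors are exempt from the rejection threshold;
ocular channels are checked like scalp channels.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from numpy.polynomial import legendre
from scipy import signal

from .containers import ContinuousRecording, EpochSet

logger = logging.getLogger(__name__)

Recording = ContinuousRecording | EpochSet


class PreprocessError(ValueError):
    pass


def _channel_axis_view(rec: Recording) -> np.ndarray:
    """Data with channels on axis -2 regardless of container type."""
    return rec.data if isinstance(rec, EpochSet) else rec.data[None, ...]


# ---------------------------------------------------------------------------
# re-referencing


def rereference(rec: Recording, ref_labels: tuple[str, str] = ("M1", "M2")):
    """Subtract the average of two reference channels from every channel.

    The canonical use is off-line re-referencing to the mean of the left and
    right mastoids.  Applying the operation twice is a no-op on the second
    pass (the re-referenced references average to zero).
    """
    labels = rec.montage.labels
    for lab in ref_labels:
        if lab not in labels:
            raise PreprocessError(f"reference channel {lab!r} not found")
    i, j = (rec.montage.index(lab) for lab in ref_labels)
    ref = 0.5 * (rec.data[..., i, :] + rec.data[..., j, :])
    data = rec.data - ref[..., None, :]
    if isinstance(rec, EpochSet):
        return rec.with_data(data, step="rereference", refs=list(ref_labels))
    return ContinuousRecording(
        data=data, sfreq=rec.sfreq, montage=rec.montage, events=list(rec.events),
        subject_id=rec.subject_id,
        provenance=rec.provenance + [{"step": "rereference",
                                      "refs": list(ref_labels)}],
    )


# ---------------------------------------------------------------------------
# band-pass filtering


def design_bandpass(low: float, high: float, sfreq: float) -> np.ndarray:
    """Windowed-sinc (Hamming) FIR band-pass taps.

    Transition width is 25 % of each band edge; the number of taps follows
    the Hamming-window approximation ``N ~ 3.3 / (Δf / fs)`` using the
    narrower (lower-edge) transition.
    """
    nyq = sfreq / 2.0
    if not (0 < low < high < nyq):
        raise PreprocessError(
            f"invalid band ({low}, {high}) Hz for sampling rate {sfreq}"
        )
    trans = 0.25 * low
    numtaps = int(np.ceil(3.3 * sfreq / trans))
    numtaps += 1 - numtaps % 2  # odd => symmetric, type-I
    return signal.firwin(
        numtaps, [low, high], pass_zero=False, fs=sfreq, window="hamming"
    )


def bandpass(rec: Recording, low: float = 5.0, high: float = 100.0):
    """Zero-phase FIR band-pass along the sample axis."""
    taps = design_bandpass(low, high, rec.sfreq)
    n = rec.data.shape[-1]
    padlen = min(3 * len(taps), n - 1)
    data = signal.filtfilt(taps, [1.0], rec.data, axis=-1, padlen=padlen)
    if isinstance(rec, EpochSet):
        return rec.with_data(data, step="bandpass", low=low, high=high)
    return ContinuousRecording(
        data=data, sfreq=rec.sfreq, montage=rec.montage, events=list(rec.events),
        subject_id=rec.subject_id,
        provenance=rec.provenance + [{"step": "bandpass",
                                      "low": low, "high": high}],
    )


# ---------------------------------------------------------------------------
# epoching


def epoch(
    rec: ContinuousRecording,
    window_ms: tuple[float, float] = (-200.0, 2000.0),
) -> EpochSet:
    """Cut one epoch per event; events too close to an edge are skipped.

    The epoch time axis is ``window_ms[0] + k / sfreq`` so that an event's
    onset sample lands exactly at t = 0 whenever ``window_ms[0]`` is an
    integer number of samples (as with -200 ms at 256/512 Hz).
    """
    t0, t1 = window_ms
    if not t0 < t1:
        raise PreprocessError("epoch window must be increasing")
    fs = rec.sfreq
    pre = int(round(-t0 * fs / 1000.0))
    n_samples = int(round((t1 - t0) * fs / 1000.0))
    step = 1000.0 / fs
    times = -pre * step + step * np.arange(n_samples)

    n_total = rec.data.shape[1]
    kept, skipped, chunks = [], [], []
    for onset, cond in rec.events:
        start = onset - pre
        if start < 0 or start + n_samples > n_total:
            skipped.append((onset, cond))
            continue
        chunks.append(rec.data[:, start : start + n_samples])
        kept.append(cond)
    for onset, cond in skipped:
        logger.warning("event at sample %d (%s) does not fit the window; skipped",
                       onset, cond)
    data = (
        np.stack(chunks, axis=0)
        if chunks
        else np.empty((0, rec.montage.n_channels, n_samples))
    )
    return EpochSet(
        data=data,
        times=times,
        conditions=np.array(kept, dtype="U8"),
        montage=rec.montage,
        sfreq=fs,
        subject_id=rec.subject_id,
        provenance=list(rec.provenance)
        + [{"step": "epoch", "window_ms": [t0, t1], "n_skipped": len(skipped)}],
    )


# ---------------------------------------------------------------------------
# baseline


def baseline_normalize(ep: EpochSet, prestim_ms: float = 200.0) -> EpochSet:
    """Subtract the mean over [-prestim_ms, 0) per trial and channel."""
    mask = (ep.times >= -prestim_ms) & (ep.times < 0)
    if not mask.any():
        raise PreprocessError(
            f"no samples in the [-{prestim_ms}, 0) ms baseline window"
        )
    base = ep.data[:, :, mask].mean(axis=-1, keepdims=True)
    return ep.with_data(ep.data - base, step="baseline", prestim_ms=prestim_ms)


# ---------------------------------------------------------------------------
# bad sensors


def detect_bad_channels(
    ep: EpochSet, z_thresh: float = 5.0
) -> tuple[np.ndarray, dict]:
    """Flag noisy scalp sensors per trial by robust peak-to-peak z-score.

    For each trial, a channel's peak-to-peak amplitude is compared to the
    median across scalp channels; the deviation is scaled by 1.4826 * MAD
    and flagged when it exceeds ``z_thresh``.  The mask is also stored on
    the returned report's ``"mask"`` key and in ``ep.bad_channels``.
    """
    scalp = ep.montage.scalp_indices
    mask = np.zeros((ep.n_trials, ep.n_channels), dtype=bool)
    if len(scalp) < 4:
        warnings.warn(
            "fewer than 4 scalp channels: bad-sensor detection skipped "
            "(interpolation would be impossible)"
        )
        report = {"percent_flagged": 0.0, "mask": mask}
        ep.bad_channels = mask
        return mask, report
    ptp = np.ptp(ep.data[:, scalp, :], axis=-1)  # trials x scalp
    med = np.median(ptp, axis=1, keepdims=True)
    mad = np.median(np.abs(ptp - med), axis=1, keepdims=True)
    mad = np.maximum(1.4826 * mad, 1e-12)
    z = (ptp - med) / mad
    mask[:, scalp] = z > z_thresh
    ep.bad_channels = mask
    pct = 100.0 * mask[:, scalp].mean() if mask.size else 0.0
    report = {"percent_flagged": float(pct), "z_thresh": z_thresh, "mask": mask}
    ep.provenance.append({"step": "detect_bad_channels",
                          "percent_flagged": float(pct)})
    return mask, report


# ---------------------------------------------------------------------------
# spherical-spline interpolation (Perrin et al.)


def _legendre_g(cosang: np.ndarray, stiffness: int = 4, n_terms: int = 50):
    """Perrin spherical-spline kernel g(cos θ) =
    (1/4π) Σ_n (2n+1) / (n (n+1))^m  P_n(cos θ)."""
    n = np.arange(1, n_terms + 1)
    coef = np.zeros(n_terms + 1)
    coef[1:] = (2 * n + 1) / (n * (n + 1.0)) ** stiffness
    return legendre.legval(np.clip(cosang, -1.0, 1.0), coef) / (4 * np.pi)


def interpolation_matrix(
    good_pos: np.ndarray, bad_pos: np.ndarray, reg: float = 1e-5
) -> np.ndarray:
    """Spherical-spline mapping from good-channel values to bad-channel
    estimates; returns (n_bad, n_good)."""
    G = _legendre_g(good_pos @ good_pos.T)
    G = G + reg * np.eye(len(good_pos))
    Gb = _legendre_g(bad_pos @ good_pos.T)
    n = len(good_pos)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    # Solve [G 1; 1' 0] [C; c0] = [I; 0] and compose with [Gb 1].
    rhs = np.zeros((n + 1, n))
    rhs[:n, :] = np.eye(n)
    sol = np.linalg.solve(A, rhs)
    return Gb @ sol[:n, :] + sol[n, :]


def interpolate_channels(ep: EpochSet, mask: np.ndarray | None = None) -> EpochSet:
    """Replace flagged scalp sensors by spherical-spline estimates from the
    good scalp sensors of the same trial."""
    if mask is None:
        mask = ep.bad_channels
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (ep.n_trials, ep.n_channels):
        raise PreprocessError("mask must be (trials, channels)")
    data = ep.data.copy()
    scalp = ep.montage.scalp_mask
    pos = ep.montage.positions
    cache: dict[tuple, np.ndarray] = {}
    for t in range(ep.n_trials):
        bad = np.flatnonzero(mask[t] & scalp)
        if bad.size == 0:
            continue
        good = np.flatnonzero(scalp & ~mask[t])
        if good.size < 4:
            raise PreprocessError(
                f"trial {t}: only {good.size} good scalp channels; "
                "need >= 4 for spherical-spline interpolation"
            )
        key = (tuple(bad), tuple(good))
        if key not in cache:
            cache[key] = interpolation_matrix(pos[good], pos[bad])
        data[t, bad, :] = cache[key] @ data[t, good, :]
    frac = float(mask[:, scalp].mean()) if mask.size else 0.0
    out = ep.with_data(data, step="interpolate", fraction=frac)
    out.bad_channels = mask.copy()
    return out


# ---------------------------------------------------------------------------
# amplitude rejection


def reject_epochs(ep: EpochSet, threshold_uv: float = 100.0) -> EpochSet:
    """Reject trials with any checked sensor exceeding ``|threshold_uv|``.

    Every channel is checked sensor-by-sensor, ocular channels included;
    sensors that were interpolated on a trial are exempt for that trial.
    """
    if not threshold_uv > 0:
        raise PreprocessError("threshold must be > 0")
    checked = ~ep.bad_channels  # (trials, channels)
    over = np.abs(ep.data) > threshold_uv
    rejected = (over & checked[:, :, None]).any(axis=(1, 2))
    out = ep.with_data(ep.data, step="reject",
                       threshold_uv=threshold_uv,
                       percent_rejected=float(100.0 * rejected.mean())
                       if len(rejected) else 0.0)
    out.rejected = ep.rejected | rejected
    return out


# ---------------------------------------------------------------------------
# drift removal


def remove_drift(ep: EpochSet) -> EpochSet:
    """Subtract the best-fit linear trend per trial and channel."""
    data = signal.detrend(ep.data, axis=-1, type="linear")
    return ep.with_data(data, step="remove_drift")


# ---------------------------------------------------------------------------
# full chain


def preprocess_epochs(
    ep: EpochSet,
    prestim_ms: float = 200.0,
    z_thresh: float = 5.0,
    reject_uv: float = 100.0,
) -> tuple[EpochSet, dict]:
    """Baseline -> bad-sensor detection/interpolation -> rejection -> detrend.

    For data that are already epoched (e.g. simulated epochs); continuous
    recordings should go through :func:`preprocess_continuous`.
    """
    ep = baseline_normalize(ep, prestim_ms)
    _, det_report = detect_bad_channels(ep, z_thresh)
    ep = interpolate_channels(ep)
    ep = reject_epochs(ep, reject_uv)
    ep = remove_drift(ep)
    report = {
        "percent_interpolated": det_report["percent_flagged"],
        "percent_rejected": float(100.0 * ep.rejected.mean())
        if ep.n_trials else 0.0,
        "n_trials": ep.n_trials,
    }
    return ep, report


def preprocess_continuous(
    rec: ContinuousRecording,
    window_ms: tuple[float, float] = (-200.0, 2000.0),
    band: tuple[float, float] = (5.0, 100.0),
    ref_labels: tuple[str, str] = ("M1", "M2"),
    **epoch_kwargs,
) -> tuple[EpochSet, dict]:
    """Full chain from a continuous recording: re-reference -> band-pass ->
    epoch -> epoch-level cleaning."""
    rec = rereference(rec, ref_labels)
    rec = bandpass(rec, *band)
    ep = epoch(rec, window_ms)
    return preprocess_epochs(ep, **epoch_kwargs)
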