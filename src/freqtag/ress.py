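"""Rhythmic entrainment source separation (RESS).

A per-subject, per-frequency spatial filter is obtained by generalized
eigendecomposition of two channel covariance matrices: S, the covariance of
the data narrowband-filtered at the target frequency, against R, the mean
covariance at flanking ("neighbor") frequencies.  The eigenvector with the
largest generalized eigenvalue maximizes target-frequency variance relative
to the surrounding broadband activity; projecting the epochs onto it yields
a single component time series per trial, bypassing electrode selection.

Conventions
-----------
* Filters are fit on scalp channels only, pooling all conditions (one filter
  per frequency per subject) over a restricted analysis window.
* Covariances use trial-wise demeaned data averaged across trials.
* R is shrinkage-regularized: R <- (1-γ) R + γ mean(eig(R)) I.
* The spatial pattern (forward model) is S·w, unit-normalized with its
  largest-magnitude entry made positive; the weights are flipped to match.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .containers import EpochSet


class RESSError(ValueError):
    pass


@dataclass
class RESSParams:
    """Filter-construction parameters (all in Hz except the window)."""

    signal_fwhm: float = 0.6
    neighbor_offsets: tuple[float, float] = (-2.5, 2.5)
    neighbor_fwhm: float = 2.0
    shrinkage: float = 0.01
    window_ms: tuple[float, float] = (0.0, 1000.0)


@dataclass
class SpatialFilter:
    """RESS weights for one subject and target frequency.

    ``weights`` has one coefficient per scalp channel (ordered as the scalp
    subset of the montage); ``pattern`` is the matching forward model used
    for topographic display; ``eigenvalues`` is the descending generalized
    eigenvalue spectrum.
    """

    target_freq: float
    weights: np.ndarray
    eigenvalues: np.ndarray
    pattern: np.ndarray
    ch_names: list[str]
    params: RESSParams = field(default_factory=RESSParams)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.pattern = np.asarray(self.pattern, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise RESSError("non-finite filter weights")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise RESSError("eigenvalues must be sorted descending")

    def save(self, path: str | Path) -> None:
        doc = {
            "target_freq": self.target_freq,
            "weights": self.weights.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "pattern": self.pattern.tolist(),
            "ch_names": self.ch_names,
            "subject_id": self.subject_id,
            "params": {
                "signal_fwhm": self.params.signal_fwhm,
                "neighbor_offsets": list(self.params.neighbor_offsets),
                "neighbor_fwhm": self.params.neighbor_fwhm,
                "shrinkage": self.params.shrinkage,
                "window_ms": list(self.params.window_ms),
            },
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SpatialFilter":
        doc = json.loads(Path(path).read_text())
        p = doc["params"]
        return cls(
            target_freq=doc["target_freq"],
            weights=np.array(doc["weights"]),
            eigenvalues=np.array(doc["eigenvalues"]),
            pattern=np.array(doc["pattern"]),
            ch_names=list(doc["ch_names"]),
            subject_id=doc.get("subject_id", ""),
            params=RESSParams(
                signal_fwhm=p["signal_fwhm"],
                neighbor_offsets=tuple(p["neighbor_offsets"]),
                neighbor_fwhm=p["neighbor_fwhm"],
                shrinkage=p["shrinkage"],
                window_ms=tuple(p["window_ms"]),
            ),
        )

    def pattern_table(self) -> list[tuple[str, float]]:
        """(channel, pattern value) pairs for external topographic plotting."""
        return list(zip(self.ch_names, self.pattern.tolist()))


# ---------------------------------------------------------------------------
# narrowband filtering


def narrowband(
    data: np.ndarray, center: float, fwhm: float, sfreq: float
) -> np.ndarray:
    """Frequency-domain Gaussian band-pass around ``center`` Hz.

    The FFT of the signal (last axis) is multiplied by a Gaussian with unit
    gain at ±``center`` and the stated full width at half maximum, then
    inverse-transformed.  Zero-phase by construction.
    """
    nyq = sfreq / 2.0
    if not 0 < center < nyq:
        raise RESSError(f"center {center} Hz outside (0, Nyquist={nyq})")
    if not fwhm > 0:
        raise RESSError("fwhm must be > 0")
    n = data.shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    # FWHM on the amplitude gain: gain = exp(-4 ln2 (f-center)^2 / fwhm^2)
    gain = np.exp(-4.0 * np.log(2.0) * (freqs - center) ** 2 / fwhm**2)
    spec = np.fft.rfft(data, axis=-1) * gain
    return np.fft.irfft(spec, n=n, axis=-1)


# ---------------------------------------------------------------------------
# filter fitting


def _trial_covariance(data: np.ndarray) -> np.ndarray:
    """Average covariance over trials of (trials, channels, samples) data,
    demeaning each trial over the window."""
    x = data - data.mean(axis=-1, keepdims=True)
    n = x.shape[-1]
    covs = np.einsum("tcs,tds->tcd", x, x) / (n - 1)
    return covs.mean(axis=0)


def fit_ress(
    ep: EpochSet,
    target: float,
    params: RESSParams | None = None,
) -> SpatialFilter:
    """Fit a RESS spatial filter for one target frequency.

    Pools all conditions and non-rejected trials over ``params.window_ms``;
    uses scalp channels only.
    """
    params = params or RESSParams()
    scalp = ep.montage.scalp_indices
    if len(scalp) < 2:
        raise RESSError("need at least 2 scalp channels")
    good = ep.good_trials
    if len(good) < 2:
        raise RESSError("need at least 2 non-rejected trials")
    t0, t1 = params.window_ms
    win = (ep.times >= t0) & (ep.times <= t1)
    if not win.any():
        raise RESSError(f"window {params.window_ms} ms outside the epoch")

    x = ep.data[np.ix_(good, scalp)]  # trials x scalp x samples

    sig = narrowband(x, target, params.signal_fwhm, ep.sfreq)
    S = _trial_covariance(sig[:, :, win])
    neigh = []
    for off in params.neighbor_offsets:
        nb = narrowband(x, target + off, params.neighbor_fwhm, ep.sfreq)
        neigh.append(_trial_covariance(nb[:, :, win]))
    R = np.mean(neigh, axis=0)
    gamma = params.shrinkage
    R = (1 - gamma) * R + gamma * (np.trace(R) / R.shape[0]) * np.eye(R.shape[0])

    try:
        evals, evecs = scipy.linalg.eigh(S, R)
    except scipy.linalg.LinAlgError as exc:
        raise RESSError(
            "generalized eigendecomposition failed (R singular after "
            "shrinkage); increase params.shrinkage"
        ) from exc
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    w = evecs[:, 0]
    pattern = S @ w
    norm = np.linalg.norm(pattern)
    if norm > 0:
        pattern = pattern / norm
    flip = np.sign(pattern[np.argmax(np.abs(pattern))]) or 1.0
    return SpatialFilter(
        target_freq=target,
        weights=w * flip,
        eigenvalues=evals,
        pattern=pattern * flip,
        ch_names=[ep.montage.labels[i] for i in scalp],
        params=params,
        subject_id=ep.subject_id,
    )


def apply_filter(filt: SpatialFilter, ep: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Project epochs onto the RESS component.

    Returns
    -------
    (component, conditions)
        ``component`` is (n_good_trials, n_samples): the weighted channel
        combination per non-rejected trial; ``conditions`` are the matching
        labels.
    """
    scalp = ep.montage.scalp_indices
    if len(scalp) != len(filt.weights):
        raise RESSError(
            f"filter has {len(filt.weights)} weights but the epochs have "
            f"{len(scalp)} scalp channels"
        )
    good = ep.good_trials
    comp = np.einsum("c,tcs->ts", filt.weights, ep.data[np.ix_(good, scalp)])
    return comp, ep.conditions[good]
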