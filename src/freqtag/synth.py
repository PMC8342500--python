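"""Seeded multi-subject simulation of two-frequency flicker-tagged EEG.

The generator emulates a word-reading frequency-tagging study: on each trial
a word is shown for 2 s whose first segment (stem) flickers at ``f1`` and
whose second segment (suffix) flickers at ``f2``.  Each tagged drive appears
in the EEG as a sinusoid at its fundamental frequency, projected to the scalp
through a fixed source topography and modulated by a smooth response envelope
whose peak latency and amplitude depend on the experimental condition
(TS = truly suffixed, PS = pseudo-suffixed, NS = non-suffixed).  A third
source at the intermodulation frequency ``f1 + f2`` carries the nonlinear
interaction of the two drives and is strongest for TS.  On top of the evoked
sources sit ~10 Hz alpha, spatially correlated 1/f ("pink") noise, occasional
blink transients on ocular/frontal channels, and the occasional noisy sensor.

Reproducibility contract: a single global seed spawns one child seed per
subject via ``numpy.random.SeedSequence([seed, subject_index])``; identical
(config, seed) pairs regenerate bit-identical data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import CONDITIONS, EpochSet
from .montage import Montage, gaussian_topography, standard_montage
from .stimulation import DEFAULT_STIMULATION, StimulationSpec


class SynthConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_peaks() -> dict:
    # Stem-frequency response peaks early for decomposable words (TS/PS)
    # and ~200 ms later when no morphemic segmentation is available (NS).
    return {
        "TS": {"f1": 400.0, "f2": 500.0, "im": 400.0},
        "PS": {"f1": 400.0, "f2": 500.0, "im": 500.0},
        "NS": {"f1": 600.0, "f2": 500.0, "im": 500.0},
    }


def _default_amplitudes() -> dict:
    # µV source amplitudes.  Suffix-frequency magnitude is ordered
    # TS > PS > NS; the intermodulation source is strongest for TS.
    return {
        "TS": {"f1": 1.3, "f2": 2.1, "im": 0.8},
        "PS": {"f1": 1.3, "f2": 1.9, "im": 0.45},
        "NS": {"f1": 1.3, "f2": 1.65, "im": 0.4},
    }


@dataclass
class SynthConfig:
    """Full parameterization of a simulated frequency-tagging study."""

    n_subjects: int = 8
    n_trials_per_condition: int = 24
    n_channels: int = 32  # scalp channels; mastoids + oculars are added
    sampling_rate: float = 256.0
    epoch_window: tuple[float, float] = (-200.0, 2000.0)  # ms
    stimulation: StimulationSpec = DEFAULT_STIMULATION
    envelope_peak_ms: dict = field(default_factory=_default_peaks)
    envelope_width_ms: float | None = 300.0  # FWHM of the rise bump; None = flat
    envelope_floor: float = 0.6  # sustained level after the peak, fraction of peak
    amplitude: dict = field(default_factory=_default_amplitudes)
    im_diff_scale: float = 0.0  # amplitude at |f2-f1| as a fraction of the im amp
    add_harmonics: bool = False  # square-wave-like harmonics at 2*f1, 2*f2
    alpha_freq: float = 10.0
    alpha_amp: float = 3.0  # µV
    pink_noise_amp: float = 6.0  # µV RMS per channel
    blink_rate: float = 0.04  # expected blink events per epoch
    blink_amp: float = 130.0  # µV at the lower ocular channel
    bad_channel_prob: float = 0.015  # per scalp channel per subject
    bad_channel_factor: float = 8.0  # noise inflation on a bad sensor
    subject_gain_sigma: float = 0.2  # log-normal sd of per-subject source gain
    topography_mode: str = "lateralized"  # or "midline"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0 or self.n_trials_per_condition < 0:
            raise SynthConfigError("counts must be non-negative")
        s, e = self.epoch_window
        if not (s < 0 < e):
            raise SynthConfigError("epoch window must straddle stimulus onset")
        for cond in CONDITIONS:
            amps = self.amplitude[cond]
            if any(a < 0 for a in amps.values()):
                raise SynthConfigError("amplitudes must be >= 0")
        for p, name in (
            (self.blink_rate, "blink_rate"),
            (self.bad_channel_prob, "bad_channel_prob"),
        ):
            if p < 0 or (name == "bad_channel_prob" and p > 1):
                raise SynthConfigError(f"invalid probability {name}={p}")
        if min(self.alpha_amp, self.pink_noise_amp) < 0:
            raise SynthConfigError("noise amplitudes must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stimulation"] = dataclasses.asdict(self.stimulation)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        if isinstance(d.get("stimulation"), dict):
            d["stimulation"] = StimulationSpec(**d["stimulation"])
        if isinstance(d.get("epoch_window"), list):
            d["epoch_window"] = tuple(d["epoch_window"])
        return cls(**d)


def full_study_config(seed: int = 0, **overrides) -> SynthConfig:
    """The full study design: 17 subjects, 64 channels @ 512 Hz, 51
    trials/condition (153 epochs per subject before rejection)."""
    kw = dict(
        n_subjects=17,
        n_trials_per_condition=51,
        n_channels=64,
        sampling_rate=512.0,
        seed=seed,
    )
    kw.update(overrides)
    return SynthConfig(**kw)


def desk_scale_config(seed: int = 0, **overrides) -> SynthConfig:
    """Reduced design for fast iteration: 8 subjects, 32 channels @ 256 Hz,
    24 trials/condition."""
    kw = dict(seed=seed)
    kw.update(overrides)
    return SynthConfig(**kw)


# ---------------------------------------------------------------------------
# topographies

_TOPO_CENTERS = {
    # (center channel, spread): stem source right-posterior and focal,
    # suffix source left-posterior and broader, IM and alpha occipital.
    "lateralized": {"f1": ("O2", 0.5), "f2": ("P3", 0.85), "im": ("Oz", 0.5),
                    "alpha": ("Oz", 0.7)},
    "midline": {"f1": ("Oz", 0.5), "f2": ("Pz", 0.85), "im": ("Oz", 0.5),
                "alpha": ("Oz", 0.7)},
}


def source_topographies(montage: Montage, mode: str = "lateralized") -> dict:
    """Per-source scalp projection vectors (max weight 1, non-scalp 0)."""
    try:
        centers = _TOPO_CENTERS[mode]
    except KeyError:
        raise SynthConfigError(f"unknown topography_mode {mode!r}") from None
    return {
        name: gaussian_topography(montage, label, spread)
        for name, (label, spread) in centers.items()
    }


# ---------------------------------------------------------------------------
# signal building blocks


def response_envelope(
    times_ms: np.ndarray,
    peak_ms: float,
    width_ms: float | None,
    floor: float = 0.6,
) -> np.ndarray:
    """Smooth rise-and-sustain response envelope.

    A Gaussian bump (FWHM ``width_ms``) rises to 1 at ``peak_ms`` and decays
    to a sustained plateau at ``floor`` of the peak; zero before stimulus
    onset.  ``width_ms=None`` gives a flat unit envelope from onset (useful
    for strictly stationary constructions).
    """
    t = np.asarray(times_ms, dtype=float)
    if width_ms is None:
        return (t >= 0).astype(float)
    sigma = width_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    g = np.exp(-((t - peak_ms) ** 2) / (2.0 * sigma**2))
    env = np.where(t <= peak_ms, g, np.maximum(g, floor))
    env[t < 0] = 0.0
    return env


def pink_noise(rng: np.random.Generator, shape: tuple, sfreq: float) -> np.ndarray:
    """1/f-power noise along the last axis, unit RMS."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / sfreq)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n=n, axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def _blink_waveform(times_ms: np.ndarray, onset_ms: float, dur_ms: float = 300.0):
    """Raised-cosine blink transient."""
    phase = (times_ms - onset_ms) / dur_ms
    w = np.zeros_like(times_ms, dtype=float)
    inside = (phase >= 0) & (phase <= 1)
    w[inside] = 0.5 * (1 - np.cos(2 * np.pi * phase[inside]))
    return w


def _spatial_mixing(montage: Montage, spread: float = 0.5) -> np.ndarray:
    """Row-normalized Gaussian channel-mixing matrix (correlates noise
    across nearby sensors while preserving per-channel RMS); ocular
    channels stay independent."""
    n = montage.n_channels
    M = np.eye(n)
    has_pos = ~np.isnan(montage.positions).any(axis=1)
    idx = np.flatnonzero(has_pos)
    p = montage.positions[idx]
    d2 = np.sum((p[:, None, :] - p[None, :, :]) ** 2, axis=-1)
    G = np.exp(-d2 / (2.0 * spread**2))
    G /= np.linalg.norm(G, axis=1, keepdims=True)
    M[np.ix_(idx, idx)] = G
    return M


# ---------------------------------------------------------------------------
# generation


def subject_rng(config: SynthConfig, subject_index: int) -> np.random.Generator:
    """Child generator for one subject: SeedSequence([seed, subject_index])."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, subject_index]))


def generate_subject(config: SynthConfig, subject_index: int) -> EpochSet:
    """Simulate all epochs for one subject.

    Trials are generated per condition (``n_trials_per_condition`` each for
    TS, PS, NS) and interleaved in a random order.  See the module docstring
    for the signal model.
    """
    if subject_index >= config.n_subjects:
        raise SynthConfigError(
            f"subject_index {subject_index} out of range (n_subjects="
            f"{config.n_subjects})"
        )
    montage = standard_montage(config.n_channels)
    topo = source_topographies(montage, config.topography_mode)
    rng = subject_rng(config, subject_index)

    fs = config.sampling_rate
    t0, t1 = config.epoch_window
    step = 1000.0 / fs
    n_samples = int(round((t1 - t0) / step))
    times = t0 + step * np.arange(n_samples)
    sec = times / 1000.0

    spec = config.stimulation
    gain = float(np.exp(rng.normal(0.0, config.subject_gain_sigma)))
    phases = {name: rng.uniform(0, 2 * np.pi) for name in ("f1", "f2", "im", "imd")}

    n_cond = config.n_trials_per_condition
    conditions = np.repeat(np.array(CONDITIONS, dtype="U8"), n_cond)
    order = rng.permutation(len(conditions))
    conditions = conditions[order]
    n_trials = len(conditions)
    n_ch = montage.n_channels

    # evoked sources: one waveform per condition, identical across trials of
    # that condition (the steady-state response is phase-locked to the drive)
    waves: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        peaks = config.envelope_peak_ms[cond]
        amps = config.amplitude[cond]
        comp = np.zeros((n_ch, n_samples))
        for name, f in (("f1", spec.f1), ("f2", spec.f2), ("im", spec.im_sum)):
            env = response_envelope(
                times, peaks[name], config.envelope_width_ms, config.envelope_floor
            )
            carrier = np.sin(2 * np.pi * f * sec + phases[name])
            if config.add_harmonics and name in ("f1", "f2"):
                carrier = carrier + np.sin(4 * np.pi * f * sec + phases[name]) / 3.0
            comp += np.outer(topo[name], amps[name] * gain * env * carrier)
        if config.im_diff_scale > 0:
            env = response_envelope(
                times, peaks["im"], config.envelope_width_ms, config.envelope_floor
            )
            comp += np.outer(
                topo["im"],
                config.im_diff_scale * config.amplitude[cond]["im"] * gain
                * env * np.sin(2 * np.pi * spec.im_diff * sec + phases["imd"]),
            )
        waves[cond] = comp

    data = np.empty((n_trials, n_ch, n_samples))
    for i, cond in enumerate(conditions):
        data[i] = waves[cond]

    # noisy sensors for this subject
    bad = rng.random(n_ch) < config.bad_channel_prob
    bad &= montage.scalp_mask
    noise_scale = np.where(bad, config.bad_channel_factor, 1.0)

    if config.pink_noise_amp > 0:
        noise = pink_noise(rng, (n_trials, n_ch, n_samples), fs)
        mix = _spatial_mixing(montage)
        noise = np.einsum("ij,tjs->tis", mix, noise)
        data += config.pink_noise_amp * noise_scale[None, :, None] * noise
    elif np.any(bad):
        data += (
            config.pink_noise_amp
            * noise_scale[None, :, None]
            * rng.standard_normal((n_trials, n_ch, n_samples))
        )

    if config.alpha_amp > 0:
        a_topo = topo["alpha"]
        for i in range(n_trials):
            phi = rng.uniform(0, 2 * np.pi, size=2)
            am = 1.0 + 0.3 * np.sin(2 * np.pi * 0.4 * sec + phi[1])
            alpha = np.sin(2 * np.pi * config.alpha_freq * sec + phi[0]) * am
            data[i] += config.alpha_amp * np.outer(a_topo, alpha)

    if config.blink_rate > 0:
        io1 = montage.index("IO1")
        lo = [montage.index("LO1"), montage.index("LO2")]
        front = np.zeros(n_ch)
        scalp = montage.scalp_mask
        fc = np.array([0.0, 0.95, 0.31224989992])
        fc = fc / np.linalg.norm(fc)
        d2 = np.sum((montage.positions[scalp] - fc) ** 2, axis=1)
        front[scalp] = 0.5 * np.exp(-d2 / (2 * 0.45**2))
        spread = front.copy()
        spread[io1] = 1.0
        for j in lo:
            spread[j] = 0.6
        for i in range(n_trials):
            for _ in range(rng.poisson(config.blink_rate)):
                onset = rng.uniform(times[0], times[-1] - 300.0)
                amp = config.blink_amp * rng.lognormal(0.0, 0.2)
                data[i] += amp * np.outer(spread, _blink_waveform(times, onset))

    return EpochSet(
        data=data,
        times=times,
        conditions=conditions,
        montage=montage,
        sfreq=fs,
        subject_id=f"S{subject_index:02d}",
        provenance=[{"step": "simulate", "seed": config.seed,
                     "subject_index": subject_index}],
    )


def generate_study(
    config: SynthConfig, out_dir: str | Path | None = None
) -> tuple[list[EpochSet], dict]:
    """Simulate every subject; optionally persist epochs + a JSON manifest.

    Returns
    -------
    (epochs, manifest)
        One EpochSet per subject and a manifest recording the seed, the
        derived stimulation frequencies, and (if written) file paths.
    """
    epochs = [generate_subject(config, i) for i in range(config.n_subjects)]
    manifest: dict = {
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "n_trials_per_condition": config.n_trials_per_condition,
        "frequencies": {
            "f1": config.stimulation.f1,
            "f2": config.stimulation.f2,
            "im_sum": config.stimulation.im_sum,
            "im_diff": config.stimulation.im_diff,
        },
        "config": config.to_dict(),
        "subjects": [ep.subject_id for ep in epochs],
        "paths": [],
    }
    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            for ep in epochs:
                path = out / f"{ep.subject_id}_epochs.npz"
                ep.save(path)
                manifest["paths"].append(str(path))
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        except OSError as exc:
            raise OSError(f"failed writing study to {out}: {exc}") from exc
    return epochs, manifest
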