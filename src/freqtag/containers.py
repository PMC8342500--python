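"""In-memory containers for continuous and epoched EEG, plus a simple
NumPy ``.npz`` epoch container with JSON-encoded metadata.

Epoched data live in an (n_trials, n_channels, n_samples) array in microvolts
with a millisecond time axis relative to stimulus onset.  Per-trial/channel
bad-channel masks, per-trial rejection flags and an ordered provenance list
(operation name + parameters) travel with the data so every preprocessing
step is auditable and rejected trials can be excluded from every average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .montage import Montage

CONDITIONS = ("TS", "PS", "NS")


@dataclass
class ContinuousRecording:
    """A continuous multichannel recording with an event table.

    ``events`` is a list of ``(onset_sample, condition)`` pairs.
    """

    data: np.ndarray  # (n_channels, n_samples), µV
    sfreq: float
    montage: Montage
    events: list[tuple[int, str]] = field(default_factory=list)
    subject_id: str = "S00"
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("continuous data must be (channels, samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} channels, montage has "
                f"{self.montage.n_channels}"
            )
        if not self.sfreq > 0:
            raise ValueError("sampling rate must be > 0")
        n = self.data.shape[1]
        for onset, _ in self.events:
            if not 0 <= onset < n:
                raise ValueError(f"event onset {onset} outside [0, {n})")

    @property
    def ch_names(self) -> list[str]:
        return self.montage.labels


@dataclass
class EpochSet:
    """Epoched EEG: trials x channels x samples with analysis metadata."""

    data: np.ndarray  # (n_trials, n_channels, n_samples), µV
    times: np.ndarray  # ms relative to stimulus onset
    conditions: np.ndarray  # (n_trials,) of str
    montage: Montage
    sfreq: float
    subject_id: str = "S00"
    bad_channels: np.ndarray | None = None  # bool (n_trials, n_channels)
    rejected: np.ndarray | None = None  # bool (n_trials,)
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype="U8")
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (trials, channels, samples)")
        n_tr, n_ch, n_sm = self.data.shape
        if n_ch != self.montage.n_channels:
            raise ValueError("channel count does not match montage")
        if len(self.times) != n_sm:
            raise ValueError("times length must equal sample count")
        if n_sm > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(
                steps, 1000.0 / self.sfreq, rtol=1e-6
            ):
                raise ValueError(
                    "times must increase in steps of 1000/sfreq milliseconds"
                )
        if len(self.conditions) != n_tr:
            raise ValueError("one condition label per trial required")
        if self.bad_channels is None:
            self.bad_channels = np.zeros((n_tr, n_ch), dtype=bool)
        else:
            self.bad_channels = np.asarray(self.bad_channels, dtype=bool)
            if self.bad_channels.shape != (n_tr, n_ch):
                raise ValueError("bad_channels must be (trials, channels)")
        if self.rejected is None:
            self.rejected = np.zeros(n_tr, dtype=bool)
        else:
            self.rejected = np.asarray(self.rejected, dtype=bool)
            if self.rejected.shape != (n_tr,):
                raise ValueError("rejected must be (trials,)")

    # -- basic views ---------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def ch_names(self) -> list[str]:
        return self.montage.labels

    @property
    def good_trials(self) -> np.ndarray:
        return np.flatnonzero(~self.rejected)

    def with_data(self, data: np.ndarray, step: str | None = None, **params) -> "EpochSet":
        """Copy with new data and (optionally) a provenance entry appended."""
        new = replace(
            self,
            data=np.asarray(data, dtype=float),
            bad_channels=self.bad_channels.copy(),
            rejected=self.rejected.copy(),
            provenance=list(self.provenance),
        )
        if step is not None:
            new.provenance.append({"step": step, **params})
        return new

    def time_index(self, t_ms: float) -> int:
        """Index of the sample nearest ``t_ms``."""
        return int(np.argmin(np.abs(self.times - t_ms)))

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write to a ``.npz`` container (arrays + JSON metadata)."""
        meta = {
            "subject_id": self.subject_id,
            "sfreq": self.sfreq,
            "labels": self.montage.labels,
            "kinds": self.montage.kinds,
            "provenance": self.provenance,
        }
        np.savez(
            Path(path),
            data=self.data,
            times=self.times,
            conditions=self.conditions,
            positions=self.montage.positions,
            bad_channels=self.bad_channels,
            rejected=self.rejected,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        with np.load(Path(path)) as f:
            meta = json.loads(bytes(f["meta"]).decode())
            montage = Montage(
                labels=list(meta["labels"]),
                positions=f["positions"],
                kinds=list(meta["kinds"]),
            )
            return cls(
                data=f["data"],
                times=f["times"],
                conditions=f["conditions"],
                montage=montage,
                sfreq=float(meta["sfreq"]),
                subject_id=meta["subject_id"],
                bad_channels=f["bad_channels"],
                rejected=f["rejected"],
                provenance=list(meta["provenance"]),
            )
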