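"""File I/O: EDF continuous recordings, event tables, epoch containers.

Continuous recordings are read from EDF/BDF via MNE and written as plain
16-bit EDF by a minimal writer (1-second data records, physical units µV).
Event tables are TSV with columns ``onset_sample`` and ``condition``.
Epoched data use the ``.npz`` container implemented on
:class:`~freqtag.containers.EpochSet`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ContinuousRecording
from .montage import MASTOID_LABELS, OCULAR_LABELS, Montage, _unit


def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, rec: ContinuousRecording) -> None:
    """Write a continuous recording as 16-bit EDF.

    Uses 1-second data records, so the sampling rate must be an integer;
    the last partial record is zero-padded.  Physical ranges are per-channel
    symmetric around zero.
    """
    fs = rec.sfreq
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = rec.data.shape
    n_rec = int(np.ceil(n_samp / fs))
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :n_samp] = rec.data

    phys_max = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    # the reader reconstructs amplitudes from the 8-char header strings, so
    # scale with the string-rounded values to keep the roundtrip exact
    phys_max = np.array([float(f"{m:.6g}"[:8]) for m in phys_max])
    dig_max, dig_min = 32767, -32768

    header = b"0".ljust(8)
    header += _ascii_field(f"X X X {rec.subject_id}", 80)
    header += _ascii_field("Startdate 01-JAN-2000", 80)
    header += b"01.01.00" + b"00.00.00"
    header += _ascii_field(256 * (1 + n_ch), 8)
    header += b" " * 44
    header += _ascii_field(n_rec, 8)
    header += _ascii_field(1, 8)  # record duration, seconds
    header += _ascii_field(n_ch, 4)

    fields = [
        (16, list(rec.ch_names)),
        (80, ["AgAgCl electrode"] * n_ch),
        (8, ["uV"] * n_ch),
        (8, [f"{-m:.6g}"[:8] for m in phys_max]),
        (8, [f"{m:.6g}"[:8] for m in phys_max]),
        (8, [str(dig_min)] * n_ch),
        (8, [str(dig_max)] * n_ch),
        (80, [""] * n_ch),
        (8, [str(fs)] * n_ch),
        (32, [""] * n_ch),
    ]
    for width, values in fields:
        for v in values:
            header += _ascii_field(v, width)

    # exact inverse of the EDF affine decoding:
    # phys = (dig - dig_min) * (phys_max - phys_min)/(dig_max - dig_min) + phys_min
    slope = 2.0 * phys_max / (dig_max - dig_min)
    with open(Path(path), "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            block = padded[:, r * fs : (r + 1) * fs]
            digital = np.clip(
                np.round((block + phys_max[:, None]) / slope[:, None]) + dig_min,
                dig_min,
                dig_max,
            ).astype("<i2")
            fh.write(digital.tobytes())


def _montage_from_labels(labels: list[str]) -> Montage:
    """Reconstruct a montage from channel names using standard templates."""
    import mne

    pos_lookup: dict[str, np.ndarray] = {}
    for tmpl in ("biosemi64", "biosemi32", "biosemi16"):
        try:
            m = mne.channels.make_standard_montage(tmpl)
        except ValueError:
            continue
        for name, p in m.get_positions()["ch_pos"].items():
            pos_lookup.setdefault(name, _unit(np.asarray(p, dtype=float)))
    pos_lookup.setdefault("M1", _unit(np.array([-0.85, -0.30, -0.44])))
    pos_lookup.setdefault("M2", _unit(np.array([0.85, -0.30, -0.44])))

    positions, kinds = [], []
    for lab in labels:
        if lab in MASTOID_LABELS:
            kinds.append("mastoid")
            positions.append(pos_lookup[lab])
        elif lab in OCULAR_LABELS or lab not in pos_lookup:
            kinds.append("ocular")
            positions.append(np.full(3, np.nan))
        else:
            kinds.append("scalp")
            positions.append(pos_lookup[lab])
    return Montage(labels=list(labels), positions=np.array(positions), kinds=kinds)


def read_continuous(
    path: str | Path, events: list[tuple[int, str]] | None = None
) -> ContinuousRecording:
    """Read an EDF/BDF recording into a ContinuousRecording (µV)."""
    import mne

    path = Path(path)
    reader = (
        mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    )
    raw = reader(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> µV
    montage = _montage_from_labels(raw.ch_names)
    return ContinuousRecording(
        data=data,
        sfreq=float(raw.info["sfreq"]),
        montage=montage,
        events=list(events or []),
        subject_id=path.stem,
    )


def write_events_tsv(path: str | Path, events: list[tuple[int, str]]) -> None:
    pd.DataFrame(events, columns=["onset_sample", "condition"]).to_csv(
        Path(path), sep="\t", index=False
    )


def read_events_tsv(path: str | Path) -> list[tuple[int, str]]:
    df = pd.read_csv(Path(path), sep="\t")
    missing = {"onset_sample", "condition"} - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return [(int(r.onset_sample), str(r.condition)) for r in df.itertuples()]
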