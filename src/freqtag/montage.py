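"""Channel montages: 10-20 scalp layouts plus mastoid and ocular channels.

Scalp positions come from MNE's standard BioSemi templates and are projected
onto the unit sphere, which is the natural domain for spherical-spline
interpolation and for the Gaussian-on-sphere source topographies used by the
synthetic-data generator.  Mastoids carry positions too (they sit on the
sphere behind the ears); ocular channels have no scalp position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MASTOID_LABELS = ("M1", "M2")
OCULAR_LABELS = ("LO1", "LO2", "IO1")  # outer canthi + below left eye


@dataclass
class Montage:
    """Electrode labels, unit-sphere positions and channel kinds.

    ``positions`` rows for channels without a scalp location (ocular) are NaN.
    ``kinds`` entries are one of ``"scalp"``, ``"mastoid"``, ``"ocular"``.
    """

    labels: list[str]
    positions: np.ndarray  # (n_channels, 3); NaN rows for position-less channels
    kinds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_channels, 3)")
        if not self.kinds:
            self.kinds = ["scalp"] * len(self.labels)
        norms = np.linalg.norm(self.positions, axis=1)
        scalp = self.scalp_mask
        if not np.allclose(norms[scalp], 1.0, atol=1e-9):
            raise ValueError("scalp positions must lie on the unit sphere")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def scalp_mask(self) -> np.ndarray:
        return np.array([k == "scalp" for k in self.kinds])

    @property
    def scalp_indices(self) -> np.ndarray:
        return np.flatnonzero(self.scalp_mask)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def position(self, label: str) -> np.ndarray:
        return self.positions[self.index(label)]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def standard_montage(n_scalp: int = 64) -> Montage:
    """Build a BioSemi-style scalp montage plus mastoids and ocular channels.

    Parameters
    ----------
    n_scalp : int
        Number of scalp electrodes; must match an MNE BioSemi template
        (16, 32, 64, 128).

    Returns
    -------
    Montage
        ``n_scalp`` scalp channels with unit-sphere positions, two mastoids
        (M1/M2, behind the ears) and three ocular channels without positions.
    """
    import mne

    try:
        tmpl = mne.channels.make_standard_montage(f"biosemi{n_scalp}")
    except ValueError as exc:
        raise ValueError(f"no standard template with {n_scalp} scalp channels") from exc
    ch_pos = tmpl.get_positions()["ch_pos"]
    labels = list(ch_pos)
    pos = np.array([_unit(np.asarray(ch_pos[c], dtype=float)) for c in labels])

    # Mastoid positions: on the sphere, low and lateral behind the ears.
    m1 = _unit(np.array([-0.85, -0.30, -0.44]))
    m2 = _unit(np.array([0.85, -0.30, -0.44]))
    labels += list(MASTOID_LABELS)
    pos = np.vstack([pos, m1, m2])
    kinds = ["scalp"] * n_scalp + ["mastoid", "mastoid"]

    labels += list(OCULAR_LABELS)
    pos = np.vstack([pos, np.full((len(OCULAR_LABELS), 3), np.nan)])
    kinds += ["ocular"] * len(OCULAR_LABELS)

    return Montage(labels=labels, positions=pos, kinds=kinds)


def gaussian_topography(
    montage: Montage, center_label: str, spread: float
) -> np.ndarray:
    """Gaussian-on-sphere projection weights over scalp channels.

    Weight for channel *i* is ``exp(-||p_i - c||^2 / (2 spread^2))`` with the
    maximum normalized to 1; non-scalp channels get weight 0.

    Parameters
    ----------
    center_label : str
        Scalp channel at the topography's maximum (e.g. ``"O2"``).
    spread : float
        Gaussian width in unit-sphere chord distance (~0.5 focal, ~0.9 broad).
    """
    c = montage.position(center_label)
    if np.any(np.isnan(c)):
        raise ValueError(f"{center_label!r} has no scalp position")
    w = np.zeros(montage.n_channels)
    scalp = montage.scalp_mask
    d2 = np.sum((montage.positions[scalp] - c) ** 2, axis=1)
    w[scalp] = np.exp(-d2 / (2.0 * spread**2))
    return w / w.max()
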