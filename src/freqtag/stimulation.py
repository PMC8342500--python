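"""Flicker-frequency arithmetic for two-frequency tagging designs.

A segment of the display flickers on/off with a period expressed in whole
monitor refresh cycles, so its fundamental frequency is
``refresh_rate / (cycles_on + cycles_off)``.  With two tagged segments the
nonlinear interaction of the two drives shows up at the intermodulation
frequencies ``f1 + f2`` and ``|f2 - f1|``.
"""

from __future__ import annotations

from dataclasses import dataclass


class StimulationError(ValueError):
    """Invalid flicker parameterization."""


@dataclass(frozen=True)
class StimulationSpec:
    """Two-segment flicker design and its derived analysis frequencies.

    Attributes
    ----------
    refresh_rate : float
        Monitor refresh rate in Hz.
    segment1_cycles_on, segment1_cycles_off : int
        On/off refresh cycles per flicker period of the first segment
        (the embedded stem in a word-reading design).
    segment2_cycles_on, segment2_cycles_off : int
        Same for the second segment (the suffix).
    f1, f2 : float
        Fundamental tagging frequencies in Hz.
    im_sum, im_diff : float
        Intermodulation frequencies ``f1 + f2`` and ``|f2 - f1|`` in Hz.
    """

    refresh_rate: float
    segment1_cycles_on: int
    segment1_cycles_off: int
    segment2_cycles_on: int
    segment2_cycles_off: int
    f1: float
    f2: float
    im_sum: float
    im_diff: float


def derive_stimulation(
    refresh_rate: float,
    seg1_on: int,
    seg1_off: int,
    seg2_on: int,
    seg2_off: int,
) -> StimulationSpec:
    """Derive fundamental and intermodulation frequencies from cycle counts.

    Parameters
    ----------
    refresh_rate : float
        Monitor refresh rate in Hz, > 0.
    seg1_on, seg1_off, seg2_on, seg2_off : int
        Refresh cycles on/off per period for the two segments; each >= 1.

    Returns
    -------
    StimulationSpec

    Examples
    --------
    >>> spec = derive_stimulation(75.0, 1, 3, 1, 5)
    >>> spec.f1, spec.f2, spec.im_sum, spec.im_diff
    (18.75, 12.5, 31.25, 6.25)
    """
    if not refresh_rate > 0:
        raise StimulationError(f"refresh_rate must be > 0, got {refresh_rate}")
    cycles = {
        "seg1_on": seg1_on,
        "seg1_off": seg1_off,
        "seg2_on": seg2_on,
        "seg2_off": seg2_off,
    }
    for name, c in cycles.items():
        if not isinstance(c, (int,)) or isinstance(c, bool):
            raise StimulationError(f"{name} must be an integer cycle count, got {c!r}")
        if c < 1:
            raise StimulationError(f"{name} must be >= 1, got {c}")

    f1 = refresh_rate / (seg1_on + seg1_off)
    f2 = refresh_rate / (seg2_on + seg2_off)
    im_sum = f1 + f2
    im_diff = abs(f2 - f1)
    # cycle counts >= 1 already bound the fundamentals by refresh/2;
    # the difference term must still be nonzero to be analyzable
    if im_diff <= 0:
        raise StimulationError(
            "the two segments flicker at the same frequency; "
            "the difference intermodulation term vanishes"
        )
    return StimulationSpec(
        refresh_rate=refresh_rate,
        segment1_cycles_on=seg1_on,
        segment1_cycles_off=seg1_off,
        segment2_cycles_on=seg2_on,
        segment2_cycles_off=seg2_off,
        f1=f1,
        f2=f2,
        im_sum=im_sum,
        im_diff=im_diff,
    )


#: The word-reading design: 75 Hz refresh, stems at 1 on / 3 off cycles
#: (18.75 Hz), suffixes at 1 on / 5 off cycles (12.50 Hz).
DEFAULT_STIMULATION = derive_stimulation(75.0, 1, 3, 1, 5)
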