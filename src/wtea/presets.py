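"""Published constraint-box criteria for the two group comparisons."""

from __future__ import annotations

import math

from .types import ConstraintBox

__all__ = ["preset_immature_vs_background", "preset_immature_vs_spindle"]


def preset_immature_vs_background() -> tuple[ConstraintBox, ConstraintBox]:
    """(red, blue) boxes separating immature discharges from background EEG.

    Red (trains typical of immature discharges): maximum PSD of
    50,000 uV^2/Hz and higher.  Blue (typical of background EEG): frequency
    bandwidth of 2 Hz and higher.  All other characteristics unbounded.
    """
    red = ConstraintBox(max_psd=(50_000.0, None))
    blue = ConstraintBox(bandwidth=(2.0, None))
    return red, blue


def preset_immature_vs_spindle() -> tuple[ConstraintBox, ConstraintBox]:
    """(red, blue) boxes separating immature discharges from sleep spindles.

    Red: central frequency no more than 8.5 Hz, duration at least 1.6
    periods, bandwidth at least 1.7 Hz, instantaneous phase from -pi to
    +1.5 rad.  Blue: central frequency no more than 15 Hz, bandwidth at
    least 4 Hz, instantaneous phase from -2.5 to +2.5 rad.
    """
    red = ConstraintBox(
        central_frequency=(None, 8.5),
        duration_periods=(1.6, None),
        bandwidth=(1.7, None),
        phase=(-math.pi, 1.5),
    )
    blue = ConstraintBox(
        central_frequency=(None, 15.0),
        bandwidth=(4.0, None),
        phase=(-2.5, 2.5),
    )
    return red, blue
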