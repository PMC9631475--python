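"""Time-varying elastance with a squared-sine activation waveform."""

from __future__ import annotations

import numpy as np

from .parameters import ChamberParams, InvalidParameterError

__all__ = ["activation", "elastance_at"]


def activation(phase, onset: float, duration: float):
    """Normalized activation a(phase) in [0, 1] for phase in [0, 1).

    Squared sine over the active window, zero elsewhere; continuous and
    periodic.  Accepts scalars or numpy arrays.
    """
    phi = np.mod(np.asarray(phase, dtype=float) - onset, 1.0)
    a = np.where(phi < duration, np.sin(np.pi * np.minimum(phi, duration) / duration) ** 2, 0.0)
    if a.ndim == 0:
        return float(a)
    return a


def elastance_at(chamber: ChamberParams, t, T: float):
    """Chamber elastance E(t) = e_min + (e_max - e_min) * a(t/T), mmHg/ml.

    ``t`` is time within the cycle (scalar or array); ``T`` the cycle length
    in seconds.
    """
    if T <= 0.0:
        raise InvalidParameterError(f"cycle length must be > 0, got {T}")
    a = activation(np.asarray(t, dtype=float) / T, chamber.onset, chamber.duration)
    return chamber.e_min + (chamber.e_max - chamber.e_min) * a
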