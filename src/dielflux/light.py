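"""Diel irradiance forcing.

The culture light regime is a smooth half-cosine: irradiance rises from zero
at dawn to a peak at a fixed clock hour and returns to zero at dusk, with
darkness for the remainder of the 24-h cycle.  A ``constant`` shape is also
provided for steady-state and fixed-point tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["IrradianceProfile", "irradiance"]


@dataclass(frozen=True)
class IrradianceProfile:
    """Diel light function.

    Parameters
    ----------
    peak_intensity:
        Maximum irradiance, µmol photon m⁻² s⁻¹.
    photoperiod:
        Hours of light per 24-h cycle.
    peak_time:
        Clock hour of maximum irradiance (default noon).
    shape:
        ``"half-cosine"`` (zero outside the photoperiod) or ``"constant"``
        (always ``peak_intensity``; useful for steady-state analysis).
    """

    peak_intensity: float = 150.0
    photoperiod: float = 16.0
    peak_time: float = 12.0
    shape: str = "half-cosine"

    def __post_init__(self) -> None:
        if self.peak_intensity < 0:
            raise ValueError(f"peak_intensity must be >= 0, got {self.peak_intensity}")
        if not 0 < self.photoperiod <= 24:
            raise ValueError(f"photoperiod must be in (0, 24], got {self.photoperiod}")
        if self.shape not in ("half-cosine", "constant"):
            raise ValueError(f"unknown irradiance shape {self.shape!r}")


def clock_hour(t, offset: float = 0.0):
    """Map elapsed hours to clock hours in [0, 24)."""
    return np.mod(np.asarray(t, dtype=float) + offset, 24.0)


def irradiance(t, profile: IrradianceProfile = IrradianceProfile()):
    """Irradiance at elapsed time ``t`` (hours); periodic with 24 h.

    Half-cosine shape: ``peak · cos(π (clock − peak_time) / photoperiod)``
    within half a photoperiod of the peak, zero otherwise.
    """
    if profile.shape == "constant":
        return np.broadcast_to(
            np.float64(profile.peak_intensity), np.shape(np.asarray(t))
        ).copy() if np.ndim(t) else float(profile.peak_intensity)
    clock = clock_hour(t)
    # signed distance from the peak, wrapped to [-12, 12)
    delta = np.mod(clock - profile.peak_time + 12.0, 24.0) - 12.0
    lit = np.abs(delta) <= profile.photoperiod / 2.0
    value = profile.peak_intensity * np.cos(math.pi * delta / profile.photoperiod)
    out = np.where(lit, value, 0.0)
    if np.ndim(t) == 0:
        return float(out)
    return out
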