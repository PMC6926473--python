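"""Amplitude/phase vectors in the 2D (cos, sin) plane.

An oscillation A·cos(2πft + φ) maps to the vector (A·cos φ, A·sin φ);
vector averaging across subjects or bootstrap draws then averages the
underlying sinusoids, and the mean vector's length/angle give the group
amplitude and phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def wrap_deg(phi: float | np.ndarray) -> float | np.ndarray:
    """Reduce an angle in degrees to [0, 360)."""
    out = np.mod(phi, 360.0)
    return np.where(out >= 360.0, 0.0, out) if np.ndim(out) else (0.0 if out >= 360.0 else out)


def wrap_diff_deg(dphi: float | np.ndarray) -> float | np.ndarray:
    """Reduce an angular difference in degrees to (-180, 180]."""
    out = np.mod(dphi, 360.0)
    return np.where(out > 180.0, out - 360.0, out) if np.ndim(out) else (
        out - 360.0 if out > 180.0 else out
    )


@dataclass(frozen=True)
class Vector2D:
    amp: float
    phase_deg: float

    @property
    def x(self) -> float:
        return self.amp * np.cos(np.deg2rad(self.phase_deg))

    @property
    def y(self) -> float:
        return self.amp * np.sin(np.deg2rad(self.phase_deg))

    @property
    def components(self) -> tuple[float, float]:
        return (self.x, self.y)

    @classmethod
    def from_components(cls, x: float, y: float) -> "Vector2D":
        return cls(amp=float(np.hypot(x, y)), phase_deg=float(wrap_deg(np.rad2deg(np.arctan2(y, x)))))


def mean_vector(xy: np.ndarray) -> Vector2D:
    """Component-wise mean of an (n, 2) array of vectors."""
    m = np.asarray(xy, float).mean(axis=0)
    return Vector2D.from_components(m[0], m[1])
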