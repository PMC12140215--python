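"""Circular-statistics primitives: phase wrapping, equal phase bins, Rayleigh test.

Phases are radians wrapped to the half-open interval [-pi, pi). Phase bins are
equally spaced with bin 0 centered at phase 0 (centers at 2*pi*j/n, wrapped),
so that for an odd bin count the center bin straddles zero symmetrically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


def wrap_phase(x):
    """Wrap angle(s) to [-pi, pi).

    Idempotent; preserves the value modulo 2*pi. Raises on non-finite input.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("wrap_phase requires finite input")
    out = np.mod(x + np.pi, 2.0 * np.pi) - np.pi
    # mod can return 2*pi - eps -> out == pi for values just below -pi
    out = np.where(out >= np.pi, -np.pi, out)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class PhaseBinning:
    """Equally spaced partition of [-pi, pi) into ``n_bins`` half-open bins.

    Bin ``j`` is centered at wrap(2*pi*j/n); its edges lie at center +/- pi/n.
    Every finite phase maps to exactly one bin.
    """

    n_bins: int
    bin_centers: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        centers = wrap_phase(2.0 * np.pi * np.arange(self.n_bins) / self.n_bins)
        object.__setattr__(self, "bin_centers", np.atleast_1d(centers))

    @property
    def width(self) -> float:
        return 2.0 * np.pi / self.n_bins

    def assign(self, phases) -> np.ndarray:
        """Map phases to bin indices in {0, ..., n_bins-1}."""
        p = wrap_phase(np.asarray(phases, dtype=float))
        idx = np.floor((np.atleast_1d(p) + self.width / 2.0) / self.width)
        return (idx.astype(int)) % self.n_bins

    def centers_for(self, indices) -> np.ndarray:
        return self.bin_centers[np.asarray(indices, dtype=int)]


def resultant_length(angles) -> float:
    """Length of the mean unit phasor, in [0, 1]."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle array")
    return float(np.abs(np.mean(np.exp(1j * a))))


def circular_mean(angles) -> float:
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle array")
    return float(np.angle(np.mean(np.exp(1j * a))))


def rayleigh_test(angles):
    """Rayleigh test for non-uniformity of circular data.

    Returns ``(R, z, p)`` where R is the resultant vector length, z = n*R**2,
    and p uses the standard small-sample series approximation.
    """
    a = np.asarray(angles, dtype=float)
    if a.size < 2:
        raise ValueError("rayleigh_test needs at least 2 angles")
    if np.any(~np.isfinite(a)):
        raise ValueError("rayleigh_test requires finite angles")
    n = a.size
    R = resultant_length(a)
    z = n * R * R
    # Zar (1999) approximation, as in the common circular-statistics toolboxes
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - (R * n) ** 2)) - (1.0 + 2.0 * n))
    return R, z, min(p, 1.0)
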