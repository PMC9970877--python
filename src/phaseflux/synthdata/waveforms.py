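"""Dimensionless activity waveforms on the unit cell-cycle phase.

Waveforms are non-negative periodic functions of phase in [0, 1].  The
canonical shapes are a two-peak profile (protein biosynthesis: one wave
around START, one in mid S/G2/M) and a one-peak profile (lipid and
polysaccharide biosynthesis: a single wave in S/G2/M), built from wrapped
Gaussian bumps so that periodicity holds exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["PeriodicWaveform", "two_peak_waveform", "one_peak_waveform", "constant_waveform"]


class PeriodicWaveform:
    """Callable waveform of phase with an enforced period of one.

    Raises ``ValueError`` at construction when the supplied function is not
    periodic (checked at the period boundary and a quarter-phase offset).
    """

    def __init__(self, fn, name="waveform"):
        self.fn = fn
        self.name = name
        for p in (0.0, 0.25):
            if not np.allclose(fn(np.asarray([p])), fn(np.asarray([p + 1.0])), atol=1e-9):
                raise ValueError(f"{name} is not periodic with period 1")
        if np.any(fn(np.linspace(0, 1, 257)) < -1e-12):
            raise ValueError(f"{name} must be non-negative")

    def __call__(self, phase):
        phase = np.asarray(phase, dtype=float)
        return np.asarray(self.fn(np.mod(phase, 1.0)), dtype=float)

    def peak_phases(self, n_grid=2048):
        """Phases of local maxima on a dense periodic grid."""
        phi = np.arange(n_grid) / n_grid
        v = self(phi)
        prev, nxt = np.roll(v, 1), np.roll(v, -1)
        peaks = phi[(v > prev) & (v >= nxt)]
        return np.sort(peaks)


def _wrapped_bumps(centers, widths, heights, floor):
    centers = np.asarray(centers, float)
    widths = np.asarray(widths, float)
    heights = np.asarray(heights, float)

    def fn(phi):
        phi = np.asarray(phi, dtype=float)
        out = np.full_like(phi, float(floor))
        for c, w, h in zip(centers, widths, heights):
            for k in (-1, 0, 1):  # wrap neighbouring periods
                out = out + h * np.exp(-0.5 * ((phi - c - k) / w) ** 2)
        return out

    return fn


def two_peak_waveform(centers=(0.15, 0.6), widths=(0.07, 0.09), heights=(1.0, 0.8), floor=0.15):
    """Two-wave activity profile (protein biosynthesis archetype)."""
    return PeriodicWaveform(_wrapped_bumps(centers, widths, heights, floor), name="two-peak")


def one_peak_waveform(center=0.6, width=0.1, height=1.0, floor=0.1):
    """Single-wave activity profile (lipid/polysaccharide archetype)."""
    return PeriodicWaveform(_wrapped_bumps([center], [width], [height], floor), name="one-peak")


def constant_waveform(level=1.0):
    return PeriodicWaveform(lambda phi: np.full_like(np.asarray(phi, float), float(level)), name="constant")
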