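"""Geometric regime diagnostics: peak sets, Poincaré sections, spectra.

These are the classical, picture-level tools: the bifurcation diagram is
the projection of local maxima of a state variable against the swept flow
rate; the Poincaré section intersects the 3-D orbit with a transversal
plane (finitely many points for a periodic orbit, a band for a chaotic
one); the Fourier amplitude spectrum separates harmonic combs from
broadband chaos.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.cluster.hierarchy import fcluster, single
from scipy.spatial.distance import pdist

from .simulate import ScalarSignal, Trajectory

__all__ = [
    "PoincarePlane", "SpectrumResult", "local_maxima", "poincare_points",
    "count_distinct_points", "amplitude_spectrum", "peak_amplitude_fraction",
]

_COORDS = {"x": 0, "z": 1, "v": 2}


@dataclass(frozen=True)
class PoincarePlane:
    """Section plane: ``coordinate = level`` crossed in ``direction``.

    The adopted convention for the GF attractor is coordinate ``x`` at the
    midrange (min+max)/2 of its kept window, both crossing directions: a
    simple closed loop then meets the plane in exactly 2 points and a
    period-doubled loop in 4.  (At the kept-window *mean* level two
    branches of the period-doubled loop nearly coincide and the count
    degenerates to 3.)
    """

    coordinate: Literal["x", "z", "v"] = "x"
    level: float = 0.0
    direction: Literal["up", "down", "both"] = "both"

    def __post_init__(self) -> None:
        if self.coordinate not in _COORDS:
            raise ValueError(f"unknown coordinate {self.coordinate!r}")
        if self.direction not in ("up", "down", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class SpectrumResult:
    """One-sided amplitude spectrum with a Parseval bookkeeping pair."""

    frequencies: np.ndarray   # 1/tau, ascending from 0
    amplitudes: np.ndarray    # signal units
    energy_time: float        # sum of squared windowed samples
    energy_freq: float        # the same energy from the DFT coefficients

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequencies) <= 0) or self.frequencies[0] < 0:
            raise ValueError("frequencies must be non-negative ascending")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")

    def to_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.frequencies, self.amplitudes]),
                   header="frequency amplitude", comments="")


def local_maxima(series: np.ndarray) -> np.ndarray:
    """Values of strict local maxima: s[k-1] < s[k] >= s[k+1].

    A flat plateau contributes its first sample.  A monotone series has no
    maxima and yields an empty array.
    """
    s = np.asarray(series, dtype=float)
    if s.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    mask = (s[1:-1] > s[:-2]) & (s[1:-1] >= s[2:])
    return s[1:-1][mask]


def poincare_points(traj: Trajectory, plane: PoincarePlane) -> np.ndarray:
    """Linearly interpolated crossings; rows hold the two non-section
    coordinates in (x, z, v) order."""
    ci = _COORDS[plane.coordinate]
    others = [i for i in range(3) if i != ci]
    g = traj.states[:, ci] - plane.level
    up = (g[:-1] < 0) & (g[1:] >= 0)
    down = (g[:-1] > 0) & (g[1:] <= 0)
    if plane.direction == "up":
        hits = up
    elif plane.direction == "down":
        hits = down
    else:
        hits = up | down
    idx = np.nonzero(hits)[0]
    if idx.size == 0:
        raise ValueError(
            f"plane {plane.coordinate}={plane.level:.6g} never crossed")
    frac = g[idx] / (g[idx] - g[idx + 1])
    pts = np.empty((idx.size, 2))
    for col, oi in enumerate(others):
        a = traj.states[idx, oi]
        b = traj.states[idx + 1, oi]
        pts[:, col] = a + frac * (b - a)
    return pts


def count_distinct_points(points: np.ndarray, tol: float = 1e-3) -> int:
    """Single-linkage cluster count with radius tol * attractor diameter.

    Periodic orbits produce a tolerance-stable small count; chaotic bands
    keep growing with the number of retained crossings.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 0:
        raise ValueError("need at least one point")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if points.shape[0] == 1:
        return 1
    d = pdist(points)
    diameter = float(d.max())
    if diameter == 0.0:
        return 1
    labels = fcluster(single(d), t=tol * diameter, criterion="distance")
    return int(labels.max())


def amplitude_spectrum(sig: ScalarSignal) -> SpectrumResult:
    """One-sided amplitude spectrum of the mean-removed, Hann-tapered
    signal.

    Amplitudes are normalized by the window gain so an A*sin(2 pi f t)
    component reports amplitude ~A at the bin nearest f.  The Hann taper
    suppresses leakage from the non-integer number of periods in the kept
    window.
    """
    s = sig.values
    n = s.shape[0]
    if n < 64:
        raise ValueError("need at least 64 samples")
    w = np.hanning(n)
    sw = (s - np.mean(s)) * w
    spec = np.fft.rfft(sw)
    freqs = np.fft.rfftfreq(n, d=sig.dt)
    amps = np.abs(spec) * (2.0 / w.sum())
    amps[0] /= 2.0
    if n % 2 == 0:
        amps[-1] /= 2.0
    power = np.abs(spec) ** 2
    energy_freq = (power[0] + 2.0 * power[1:-1].sum()
                   + (power[-1] if n % 2 == 0 else 2.0 * power[-1])) / n
    return SpectrumResult(frequencies=freqs, amplitudes=amps,
                          energy_time=float(np.sum(sw * sw)),
                          energy_freq=float(energy_freq))


def peak_amplitude_fraction(spec: SpectrumResult, n_peaks: int = 5,
                            halfwidth: int = 4) -> float:
    """Fraction of total spectral amplitude carried by the strongest
    ``n_peaks`` spectral lines (each line summed over +-halfwidth bins).

    A harmonic comb concentrates nearly everything in a few lines; a
    chaotic broadband spectrum does not.
    """
    a = spec.amplitudes
    total = float(a.sum())
    if total == 0.0:
        return 0.0
    is_peak = np.zeros(a.shape[0], dtype=bool)
    is_peak[1:-1] = (a[1:-1] > a[:-2]) & (a[1:-1] >= a[2:])
    order = np.argsort(a)[::-1]
    taken = np.zeros(a.shape[0], dtype=bool)
    captured = 0.0
    found = 0
    for idx in order:
        if found >= n_peaks:
            break
        if not is_peak[idx] or taken[idx]:
            continue
        lo = max(0, idx - halfwidth)
        hi = min(a.shape[0], idx + halfwidth + 1)
        window = np.arange(lo, hi)
        fresh = window[~taken[window]]
        captured += float(a[fresh].sum())
        taken[window] = True
        found += 1
    return captured / total
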