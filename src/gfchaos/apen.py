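"""Approximate entropy (Pincus) of a scalar series.

ApEn(m, r, N) = Phi^m(r) - Phi^{m+1}(r), where Phi^m averages the log
frequency with which m-length embedded vectors stay within a Chebyshev
distance r of each other.  Low values mean the series is predictable
(regular); higher values mean new patterns keep appearing (complex or
chaotic).  Self-matches are counted, which keeps every log argument
positive and makes ApEn non-negative in practice.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .simulate import ScalarSignal

__all__ = ["ApEnConfig", "embedded_distance", "phi_m", "apen"]


@dataclass(frozen=True)
class ApEnConfig:
    """Embedding dimension, threshold and length guard.

    ``r`` is interpreted on the standardized signal (threshold = r standard
    deviations), which makes the statistic invariant under affine scaling
    of the observable; set ``standardize=False`` to apply ``r`` on the raw
    scale.
    """

    m: int = 2
    r: float = 0.1
    min_N: int = 1000
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("threshold r must be positive")
        if self.min_N < 100:
            raise ValueError("min_N must be >= 100")

    def replace(self, **changes) -> "ApEnConfig":
        return dataclasses.replace(self, **changes)


def embedded_distance(s: np.ndarray, i: int, j: int, m: int) -> float:
    """Chebyshev distance of the m-length embedded vectors at i and j
    (0-based starts)."""
    s = np.asarray(s, dtype=float)
    n_vec = s.shape[0] - (m - 1)
    if not (0 <= i < n_vec and 0 <= j < n_vec):
        raise IndexError(
            f"embedded starts must lie in [0, {n_vec}), got {i}, {j}")
    return float(np.max(np.abs(s[i:i + m] - s[j:j + m])))


@njit(cache=True)
def _phi_m_kernel(s, m, r):
    N = s.shape[0]
    n_vec = N - (m - 1)
    acc = 0.0
    for i in range(n_vec):
        count = 0
        for j in range(n_vec):
            dmax = 0.0
            for k in range(m):
                d = abs(s[i + k] - s[j + k])
                if d > dmax:
                    dmax = d
            if dmax < r:
                count += 1
        acc += np.log(count / n_vec)
    return acc / n_vec


def phi_m(s: np.ndarray, m: int, r: float) -> float:
    """Phi^m(r): mean log fraction of embedded vectors within r.

    Includes the self-match i = j, so every correlation count is positive
    and Phi^m(r) <= 0.
    """
    s = np.ascontiguousarray(s, dtype=float)
    if s.shape[0] < m + 1:
        raise ValueError(f"series of length {s.shape[0]} too short for m={m}")
    return float(_phi_m_kernel(s, m, r))


def apen(sig: ScalarSignal | np.ndarray, cfg: ApEnConfig | None = None
         ) -> float:
    """Approximate entropy of the signal under the given configuration."""
    cfg = cfg or ApEnConfig()
    s = sig.values if isinstance(sig, ScalarSignal) else np.asarray(sig, float)
    N = s.shape[0]
    if N < 100:
        raise ValueError(f"apen needs at least 100 samples, got {N}")
    if N < cfg.min_N:
        warnings.warn(
            f"apen on {N} < {cfg.min_N} samples; estimate may be biased",
            RuntimeWarning, stacklevel=2)
    if cfg.standardize:
        sd = float(np.std(s))
        if sd == 0.0:
            return 0.0
        s = (s - np.mean(s)) / sd
    return phi_m(s, cfg.m, cfg.r) - phi_m(s, cfg.m + 1, cfg.r)
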