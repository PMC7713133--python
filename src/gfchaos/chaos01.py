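"""The 0-1 test for chaos (Gottwald-Melbourne, correlation variant).

A scalar observation series phi(j) is mapped, for a phase angle c, to the
translation variables

    p_c(n) = sum_{j<=n} phi(j) cos(jc),   q_c(n) = sum_{j<=n} phi(j) sin(jc).

For regular dynamics the (p, q) trajectory stays bounded; chaotic dynamics
make it diffuse, so its mean-square displacement M(n) grows linearly in the
lag n.  The statistic K_c is the Pearson correlation between the lag index
and the (mean-corrected) displacement D(n); the test output K is the median
of K_c over randomly drawn angles c.  K near 0 flags regular motion, K near
1 chaos.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from numba import njit

from .simulate import ScalarSignal

__all__ = [
    "Chaos01Config", "Chaos01Result", "translation_components",
    "mean_square_displacement", "modified_msd", "kc_statistic", "k_test",
    "pq_diameter",
]


@dataclass(frozen=True)
class Chaos01Config:
    """Angles, lag window and seed of the test.

    ``c`` is drawn away from 0 and 2*pi (and from the resonant
    neighbourhood of pi) because those angles produce spurious verdicts;
    the default range (pi/5, 4*pi/5) follows common practice.  ``ncut`` is
    ``floor(N * ncut_fraction)`` with the advised ceiling of N/10.
    """

    n_c: int = 100
    c_range: tuple[float, float] = (np.pi / 5, 4 * np.pi / 5)
    ncut_fraction: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.c_range
        if not 0.0 < lo < hi < 2 * np.pi:
            raise ValueError("c_range must satisfy 0 < lo < hi < 2*pi")
        if not 0.0 < self.ncut_fraction <= 0.1:
            raise ValueError("ncut_fraction must lie in (0, 0.1]")
        if self.n_c < 1:
            raise ValueError("n_c must be at least 1")

    def replace(self, **changes) -> "Chaos01Config":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class Chaos01Result:
    """Per-angle statistics and their median."""

    kc_values: np.ndarray   # shape (n_c, 2): columns c, K_c
    K: float

    def __post_init__(self) -> None:
        kc = self.kc_values[:, 1]
        if np.any(np.abs(kc) > 1 + 1e-9) or abs(self.K) > 1 + 1e-9:
            raise ValueError("K_c values must lie in [-1, 1]")
        if not np.isclose(self.K, np.median(kc)):
            raise ValueError("K must equal the median of the K_c values")

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("c K_c\n")
            for c, kc in self.kc_values:
                fh.write(f"{c:.10g} {kc:.10g}\n")
            fh.write(f"median {self.K:.10g}\n")


def translation_components(phi: np.ndarray, c: float
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative translation variables; the index j starts at 1."""
    phi = np.asarray(phi, dtype=float)
    if phi.size == 0:
        raise ValueError("empty observation series")
    j = np.arange(1, phi.size + 1)
    return np.cumsum(phi * np.cos(j * c)), np.cumsum(phi * np.sin(j * c))


def mean_square_displacement(p: np.ndarray, q: np.ndarray, n: int) -> float:
    """Finite-sample M(n): the average squared displacement over the
    N - n available start positions."""
    N = p.shape[0]
    if not 1 <= n < N:
        raise ValueError(f"lag n={n} must satisfy 1 <= n < N={N}")
    dp = p[n:] - p[:-n]
    dq = q[n:] - q[:-n]
    return float(np.mean(dp * dp + dq * dq))


def modified_msd(m_n: float, mean_phi: float, n: int, c: float) -> float:
    """D(n) = M(n) - E(phi)^2 (1 - cos nc) / (1 - cos c)."""
    if np.isclose(np.cos(c), 1.0):
        raise ValueError("cos(c) = 1 makes the correction term singular")
    if n == 0:
        return float(m_n)
    return float(m_n - mean_phi ** 2 * (1 - np.cos(n * c)) / (1 - np.cos(c)))


def kc_statistic(phi: np.ndarray, c: float,
                 cfg: Chaos01Config | None = None) -> float:
    """K_c: Pearson correlation of the lag index against D(n), n <= ncut.

    A zero-variance displacement vector (a constant signal) has no defined
    correlation; such series are regular, so K_c = 0 by convention.
    """
    cfg = cfg or Chaos01Config()
    phi = np.asarray(phi, dtype=float)
    ncut = int(np.floor(phi.size * cfg.ncut_fraction))
    if ncut < 3:
        raise ValueError(f"ncut={ncut} < 3; series too short")
    p, q = translation_components(phi, c)
    mean_phi = float(np.mean(phi))
    D = np.array([modified_msd(mean_square_displacement(p, q, n),
                               mean_phi, n, c)
                  for n in range(1, ncut + 1)])
    xi = np.arange(1, ncut + 1, dtype=float)
    if np.std(D) == 0.0:
        return 0.0
    return float(np.corrcoef(xi, D)[0, 1])


@njit(cache=True)
def _kc_batch(phi, cs, ncut):
    """K_c for every angle in ``cs`` (the hot path of :func:`k_test`)."""
    N = phi.shape[0]
    mean_phi = np.mean(phi)
    out = np.empty(cs.shape[0])
    p = np.empty(N)
    q = np.empty(N)
    D = np.empty(ncut)
    for ic in range(cs.shape[0]):
        c = cs[ic]
        cp, sp = 0.0, 0.0
        cosc, sinc = np.cos(c), np.sin(c)
        # incremental rotation avoids N trig calls per angle
        cj, sj = 1.0, 0.0
        for j in range(N):
            new_cj = cj * cosc - sj * sinc
            new_sj = sj * cosc + cj * sinc
            cj, sj = new_cj, new_sj
            cp += phi[j] * cj
            sp += phi[j] * sj
            p[j] = cp
            q[j] = sp
        corr_den = 1.0 - cosc
        for n in range(1, ncut + 1):
            acc = 0.0
            for j in range(N - n):
                dp = p[j + n] - p[j]
                dq = q[j + n] - q[j]
                acc += dp * dp + dq * dq
            m_n = acc / (N - n)
            D[n - 1] = m_n - mean_phi * mean_phi \
                * (1.0 - np.cos(n * c)) / corr_den
        # Pearson correlation of (1..ncut) vs D
        mx = (ncut + 1) / 2.0
        my = np.mean(D)
        sxy, sxx, syy = 0.0, 0.0, 0.0
        for n in range(1, ncut + 1):
            dx = n - mx
            dy = D[n - 1] - my
            sxy += dx * dy
            sxx += dx * dx
            syy += dy * dy
        if syy <= 0.0:
            out[ic] = 0.0
        else:
            out[ic] = sxy / np.sqrt(sxx * syy)
    return out


def k_test(sig: ScalarSignal | np.ndarray,
           cfg: Chaos01Config | None = None) -> Chaos01Result:
    """Run the full test: draw angles, compute every K_c, return the median.

    The input is expected to be sampled map-like (roughly ten samples per
    oscillation or fewer); heavily oversampled flows bias K toward zero,
    see :func:`gfchaos.simulate.resample`.
    """
    cfg = cfg or Chaos01Config()
    phi = sig.values if isinstance(sig, ScalarSignal) else np.asarray(sig, float)
    if phi.shape[0] < 100:
        raise ValueError("k_test needs at least 100 samples")
    ncut = int(np.floor(phi.shape[0] * cfg.ncut_fraction))
    rng = np.random.default_rng(cfg.rng_seed)
    cs = rng.uniform(cfg.c_range[0], cfg.c_range[1], size=cfg.n_c)
    kc = _kc_batch(np.ascontiguousarray(phi, dtype=float), cs, ncut)
    kc = np.clip(kc, -1.0, 1.0)
    return Chaos01Result(kc_values=np.column_stack([cs, kc]),
                         K=float(np.median(kc)))


def pq_diameter(phi: np.ndarray, c: float) -> float:
    """Bounding-box diagonal of the (p, q) trajectory.

    Bounded (regular) dynamics keep this at the scale of a few signal
    amplitudes; diffusive (chaotic) dynamics grow it like sqrt(N)."""
    p, q = translation_components(np.asarray(phi, float), c)
    return float(np.hypot(p.max() - p.min(), q.max() - q.min()))
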