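"""The Györgyi-Field three-variable model of the BZ reaction in a CSTR.

The Belousov-Zhabotinsky (BZ) reaction in a continuous-flow stirred-tank
reactor (CSTR) is described here by the dimensionless three-variable
reduction of Györgyi and Field: the state ``(x, z, v)`` tracks scaled
concentrations of HBrO2, Ce(4+) and bromomalonic acid (BrMA), while bromide
is eliminated algebraically through its quasi-steady state ``ytilde``.  The
single free parameter is the reactor flow rate ``kf`` (the inverse residence
time, in 1/s); every other constant is a measured rate constant or a feed
concentration.

The vector field is exposed three ways: the readable reference functions
:func:`ytilde`, :func:`gf_rhs` and :func:`gf_jacobian`, and numba-compiled
kernels (:data:`gf_rhs_kernel` etc.) used by the integrators.  Both paths
evaluate the identical expressions and the test-suite holds them together.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from numba import njit

__all__ = [
    "GFParameters", "GFState", "DomainError", "ytilde", "gf_rhs",
    "gf_jacobian", "gf_rhs_kernel", "gf_jac_kernel", "gf_ext_rhs_kernel",
    "DEFAULT_SCALINGS",
]


class DomainError(ValueError):
    """State outside the physical domain of the vector field."""


# Concentration/time scales of the dimensionless formulation.  The rate
# constants and feed concentrations below are tabulated; the scales are the
# combinations used by Györgyi & Field's three-variable reduction:
#
#   X0 = k2*A*H^2/k5,   Z0 = C*A/(40*M),   V0 = 4*A*H*C/M^2,
#   Y0 = 4*k2*A*H^2*C/(k5*M^2),   T0 = 1/(k4*A^0.5*H^1.5*X0^0.5)
#
# Y0 cancels identically from the flow (each Y0*ytilde product collapses to
# the dimensional quasi-steady-state bromide concentration), so it only sets
# the reporting scale of `ytilde`.  T0, the unit of dimensionless time,
# rescales the whole vector field uniformly: it cannot move bifurcation
# points in kf, only the scale of rates and Lyapunov exponents.  The value
# above normalizes the cerium autocatalysis coefficient of the z-equation
# to unity and is pinned by the pipeline's validation gate (regime
# classification at the showcase flow rates together with the magnitude of
# the maximal Lyapunov exponent in 1/tau units).
_K1, _K2, _K3, _K4, _K5, _K6, _K7 = 4.0e6, 2.0, 3000.0, 55.2, 7000.0, 0.09, 0.23
_A, _M, _H, _C = 0.1, 0.25, 0.26, 0.000833

_X0 = _K2 * _A * _H ** 2 / _K5
DEFAULT_SCALINGS = {
    "X0": _X0,
    "Z0": _C * _A / (40.0 * _M),
    "V0": 4.0 * _A * _H * _C / _M ** 2,
    "Y0": 4.0 * _K2 * _A * _H ** 2 * _C / (_K5 * _M ** 2),
    "T0": 1.0 / (_K4 * _A ** 0.5 * _H ** 1.5 * _X0 ** 0.5),
}

_PARAM_KEYS = ("k1", "k2", "k3", "k4", "k5", "k6", "k7",
               "A", "H", "M", "C", "alpha", "beta", "kf",
               "T0", "X0", "Y0", "Z0", "V0")


@dataclass(frozen=True)
class GFParameters:
    """Rate constants, feed concentrations and scalings of the GF model.

    Units: ``k1..k7`` are rate constants (M^-n s^-1), ``A, H, M, C`` molar
    feed/total concentrations, ``alpha, beta`` dimensionless stoichiometric
    factors, ``kf`` the flow rate in 1/s, ``T0`` a time scale in s and
    ``X0, Y0, Z0, V0`` concentration scales in M.
    """

    k1: float = _K1
    k2: float = _K2
    k3: float = _K3
    k4: float = _K4
    k5: float = _K5
    k6: float = _K6
    k7: float = _K7
    A: float = _A
    H: float = _H
    M: float = _M
    C: float = _C
    alpha: float = 666.7
    beta: float = 0.3478
    kf: float = 3.0e-4
    T0: float = DEFAULT_SCALINGS["T0"]
    X0: float = DEFAULT_SCALINGS["X0"]
    Y0: float = DEFAULT_SCALINGS["Y0"]
    Z0: float = DEFAULT_SCALINGS["Z0"]
    V0: float = DEFAULT_SCALINGS["V0"]

    def __post_init__(self) -> None:
        for key in _PARAM_KEYS:
            val = getattr(self, key)
            if not (np.isfinite(val) and val > 0):
                raise ValueError(
                    f"GFParameters.{key} must be strictly positive and "
                    f"finite, got {val!r}")

    def replace(self, **changes: float) -> "GFParameters":
        return dataclasses.replace(self, **changes)

    def as_vector(self) -> np.ndarray:
        """Pack into the flat float64 layout used by the compiled kernels."""
        return np.array([getattr(self, k) for k in _PARAM_KEYS], dtype=float)

    # -- flat key-value config round trip ---------------------------------
    def to_config(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{k} = {getattr(self, k)!r}\n" for k in _PARAM_KEYS))

    @classmethod
    def from_config(cls, path: str | Path) -> "GFParameters":
        return cls(**_read_kv(Path(path), _PARAM_KEYS))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "GFParameters":
        return cls(**{k: float(v) for k, v in mapping.items()})


def _read_kv(path: Path, allowed: Iterable[str]) -> dict[str, float]:
    allowed = set(allowed)
    out: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in allowed:
            raise KeyError(f"{path}:{lineno}: unknown key {key!r}")
        out[key] = float(value)
    return out


@dataclass(frozen=True)
class GFState:
    """Dimensionless concentrations (x, z, v) = (HBrO2, Ce4+, BrMA)/scales."""

    x: float
    z: float
    v: float

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.x, self.z, self.v))):
            raise ValueError(f"non-finite state {self}")
        if self.x < 0 or self.z < 0 or self.v < 0:
            raise DomainError(
                f"state components must be non-negative, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.z, self.v], dtype=float)


def _coerce_state(state) -> np.ndarray:
    if isinstance(state, GFState):
        return state.as_array()
    arr = np.asarray(state, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"state must have shape (3,), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite state {arr}")
    # absorb solver round-off slightly below zero; reject real excursions
    if np.any(arr < -1e-12):
        raise DomainError(f"negative state component in {arr}")
    return arr


# ---------------------------------------------------------------------------
# compiled kernels (flat parameter vector layout: see _PARAM_KEYS)
# ---------------------------------------------------------------------------

@njit(cache=True)
def gf_rhs_kernel(tau, y, p):
    """Dimensionless GF vector field d(x,z,v)/dtau.  Autonomous in tau."""
    k1, k2, k3, k4, k5, k6, k7 = p[0], p[1], p[2], p[3], p[4], p[5], p[6]
    A, H, M, C = p[7], p[8], p[9], p[10]
    alpha, beta, kf = p[11], p[12], p[13]
    T0, X0, Z0, V0 = p[14], p[15], p[17], p[18]

    x = y[0]
    if x < 0.0:
        x = 0.0  # clamp solver round-off; the sqrt below needs x >= 0
    z, v = y[1], y[2]
    sx = np.sqrt(x)

    # dimensional quasi-steady-state bromide, Ytil = Y0 * ytilde
    ytil = alpha * k6 * Z0 * V0 * z * v / (k1 * H * X0 * x + k2 * A * H ** 2 + kf)

    out = np.empty(3)
    out[0] = T0 * (-k1 * H * x * ytil
                   + (k2 * A * H ** 2 / X0) * ytil
                   - 2.0 * k3 * X0 * x * x
                   + 0.5 * k4 * np.sqrt(A) * H ** 1.5 * X0 ** -0.5
                   * (C - Z0 * z) * sx
                   - 0.5 * k5 * Z0 * x * z
                   - kf * x)
    out[1] = T0 * (k4 * np.sqrt(A) * H ** 1.5 * np.sqrt(X0)
                   * (C / Z0 - z) * sx
                   - k5 * X0 * x * z
                   - alpha * k6 * V0 * z * v
                   - beta * k7 * M * z
                   - kf * z)
    out[2] = T0 * ((2.0 * k1 * H * X0 / V0) * x * ytil
                   + (k2 * A * H ** 2 / V0) * ytil
                   + (k3 * X0 ** 2 / V0) * x * x
                   - alpha * k6 * Z0 * z * v
                   - kf * v)
    return out


@njit(cache=True)
def gf_jac_kernel(y, p):
    """Analytic Jacobian of :func:`gf_rhs_kernel` w.r.t. (x, z, v)."""
    k1, k2, k3, k4, k5, k6, k7 = p[0], p[1], p[2], p[3], p[4], p[5], p[6]
    A, H, M, C = p[7], p[8], p[9], p[10]
    alpha, beta, kf = p[11], p[12], p[13]
    T0, X0, Z0, V0 = p[14], p[15], p[17], p[18]

    x, z, v = y[0], y[1], y[2]
    if x < 1e-12:
        x = 1e-12  # keep 1/sqrt(x) finite on solver trial states
    sx = np.sqrt(x)

    den = k1 * H * X0 * x + k2 * A * H ** 2 + kf
    ytil = alpha * k6 * Z0 * V0 * z * v / den
    dytil_dx = -ytil * k1 * H * X0 / den
    dytil_dz = alpha * k6 * Z0 * V0 * v / den
    dytil_dv = alpha * k6 * Z0 * V0 * z / den

    a1 = -k1 * H            # coefficient of x*Ytil in dx/dtau
    a2 = k2 * A * H ** 2 / X0
    a4 = 0.5 * k4 * np.sqrt(A) * H ** 1.5 * X0 ** -0.5
    b4 = k4 * np.sqrt(A) * H ** 1.5 * np.sqrt(X0)
    c1 = 2.0 * k1 * H * X0 / V0
    c2 = k2 * A * H ** 2 / V0
    c3 = k3 * X0 ** 2 / V0

    J = np.empty((3, 3))
    J[0, 0] = T0 * (a1 * ytil + (a1 * x + a2) * dytil_dx
                    - 4.0 * k3 * X0 * x
                    + a4 * (C - Z0 * z) * 0.5 / sx
                    - 0.5 * k5 * Z0 * z - kf)
    J[0, 1] = T0 * ((a1 * x + a2) * dytil_dz - a4 * Z0 * sx
                    - 0.5 * k5 * Z0 * x)
    J[0, 2] = T0 * ((a1 * x + a2) * dytil_dv)
    J[1, 0] = T0 * (b4 * (C / Z0 - z) * 0.5 / sx - k5 * X0 * z)
    J[1, 1] = T0 * (-b4 * sx - k5 * X0 * x - alpha * k6 * V0 * v
                    - beta * k7 * M - kf)
    J[1, 2] = T0 * (-alpha * k6 * V0 * z)
    J[2, 0] = T0 * (c1 * ytil + (c1 * x + c2) * dytil_dx + 2.0 * c3 * x)
    J[2, 1] = T0 * ((c1 * x + c2) * dytil_dz - alpha * k6 * Z0 * v)
    J[2, 2] = T0 * ((c1 * x + c2) * dytil_dv - alpha * k6 * Z0 * z - kf)
    return J


@njit(cache=True)
def gf_ext_rhs_kernel(tau, u, p):
    """Flow plus three tangent vectors, for Lyapunov-spectrum integration.

    Layout: ``u[0:3]`` is the state, ``u[3:6], u[6:9], u[9:12]`` the tangent
    vectors, each advected by the Jacobian along the trajectory.
    """
    out = np.empty(12)
    y = u[0:3]
    out[0:3] = gf_rhs_kernel(tau, y, p)
    J = gf_jac_kernel(y, p)
    for m in range(3):
        w = u[3 + 3 * m:6 + 3 * m]
        out[3 + 3 * m:6 + 3 * m] = J @ w
    return out


# ---------------------------------------------------------------------------
# reference interface
# ---------------------------------------------------------------------------

def ytilde(state, p: GFParameters) -> float:
    """Dimensionless quasi-steady-state bromide concentration.

    ``ytilde = (alpha k6 Z0 V0 z v / (k1 H X0 x + k2 A H^2 + kf)) / Y0``.
    """
    x, z, v = _coerce_state(state)
    num = p.alpha * p.k6 * p.Z0 * p.V0 * z * v
    den = p.k1 * p.H * p.X0 * max(x, 0.0) + p.k2 * p.A * p.H ** 2 + p.kf
    return (num / den) / p.Y0


def gf_rhs(tau: float, state, p: GFParameters) -> np.ndarray:
    """Right-hand side d(x,z,v)/dtau of the dimensionless GF model.

    ``tau`` is accepted for solver interfaces; the flow is autonomous.
    Raises :class:`DomainError` for states below the tolerated round-off
    band (x < -1e-12) and :class:`OverflowError` if the result is not
    finite.
    """
    y = _coerce_state(state)
    out = gf_rhs_kernel(float(tau), y, p.as_vector())
    if not np.all(np.isfinite(out)):
        raise OverflowError(
            f"vector field overflow at state {y} (kf={p.kf})")
    return out


def gf_jacobian(state, p: GFParameters) -> np.ndarray:
    """Analytic 3x3 Jacobian of :func:`gf_rhs` at a strictly interior state.

    The derivative of the x^0.5 autocatalysis term diverges at x = 0, so
    the state must satisfy x > 0.
    """
    y = _coerce_state(state)
    if y[0] <= 0.0:
        raise DomainError("gf_jacobian requires x > 0 (x^0.5 derivative)")
    return gf_jac_kernel(y, p.as_vector())
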