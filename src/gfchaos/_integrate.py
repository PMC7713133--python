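"""Adaptive Dormand-Prince 5(4) integration kernel.

The flow-rate sweeps integrate the same three-variable vector field hundreds
of times at a 1e-4 output step, which rules out driving a Python-level
right-hand side through ``scipy.integrate.solve_ivp`` (per-call dispatch
dominates).  This module provides a numba-compiled embedded Runge-Kutta
5(4) pair with the Shampine quartic dense-output interpolant -- the same
tableau as MATLAB's ode45 and scipy's ``RK45`` -- that accepts any
numba-compiled right-hand side ``f(t, y, p)``.

The scipy solvers remain available through the ``stiff`` solver path in
:mod:`gfchaos.simulate`, and the test-suite cross-checks this kernel against
them on the same problems.
"""

import numpy as np
from numba import njit

__all__ = ["dp45_dense", "dp45_final", "STATUS_OK", "STATUS_STEP_UNDERFLOW",
           "STATUS_MAX_STEPS"]

STATUS_OK = 0
STATUS_STEP_UNDERFLOW = 1
STATUS_MAX_STEPS = 2

# Dormand-Prince 5(4) tableau.
_C2, _C3, _C4, _C5 = 1 / 5, 3 / 10, 4 / 5, 8 / 9
_A21 = 1 / 5
_A31, _A32 = 3 / 40, 9 / 40
_A41, _A42, _A43 = 44 / 45, -56 / 15, 32 / 9
_A51, _A52, _A53, _A54 = 19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729
_A61, _A62, _A63, _A64, _A65 = (9017 / 3168, -355 / 33, 46732 / 5247,
                                49 / 176, -5103 / 18656)
_B1, _B3, _B4, _B5, _B6 = 35 / 384, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84
# Error weights: 5th-order solution minus 4th-order embedded solution.
_E1, _E3, _E4, _E5, _E6, _E7 = (71 / 57600, -71 / 16695, 71 / 1920,
                                -17253 / 339200, 22 / 525, -1 / 40)
# Shampine dense-output interpolant (quartic in the step fraction).
_P = np.array([
    [1.0, -8048581381 / 2820520608, 8663915743 / 2820520608,
     -12715105075 / 11282082432],
    [0.0, 0.0, 0.0, 0.0],
    [0.0, 131558114200 / 32700410799, -68118460800 / 10900136933,
     87487479700 / 32700410799],
    [0.0, -1754552775 / 470086768, 14199869525 / 1410260304,
     -10690763975 / 1880347072],
    [0.0, 127303824393 / 49829197408, -318862633887 / 49829197408,
     701980252875 / 199316789632],
    [0.0, -282668133 / 205662961, 2019193451 / 616988883,
     -1453857185 / 822651844],
    [0.0, 40617522 / 29380423, -110615467 / 29380423, 69997945 / 29380423],
])

_SAFETY = 0.9
_MIN_FACTOR = 0.2
_MAX_FACTOR = 10.0
_MAX_STEPS = 200_000_000


@njit(cache=False)
def _error_norm(err, y0, y1, rtol, atol):
    dim = y0.shape[0]
    acc = 0.0
    for i in range(dim):
        scale = atol + rtol * max(abs(y0[i]), abs(y1[i]))
        acc += (err[i] / scale) ** 2
    if not np.isfinite(acc):
        return 1e6  # force rejection through the normal controller
    return np.sqrt(acc / dim)


@njit(cache=False)
def dp45_dense(rhs, p, y0, t0, t1, t_out, rtol, atol, h0, max_step):
    """Integrate ``dy/dt = rhs(t, y, p)`` and interpolate onto ``t_out``.

    Returns ``(status, t_reached, y_out, n_steps)`` where ``y_out`` has shape
    ``(len(t_out), dim)``.  ``t_out`` must be non-decreasing and contained in
    ``[t0, t1]``.
    """
    dim = y0.shape[0]
    n_out = t_out.shape[0]
    y_out = np.full((n_out, dim), np.nan)
    k = np.empty((7, dim))
    q = np.empty((dim, 4))

    t = t0
    y = y0.copy()
    k[0] = rhs(t, y, p)
    i_out = 0
    # emit any output points coinciding with t0
    while i_out < n_out and t_out[i_out] <= t0:
        y_out[i_out] = y
        i_out += 1

    h = h0
    if h <= 0.0:
        h = 1e-6
    n_steps = 0
    while t < t1:
        if n_steps > _MAX_STEPS:
            return STATUS_MAX_STEPS, t, y_out, n_steps
        if h > max_step:
            h = max_step
        if t + h > t1:
            h = t1 - t
        # stages
        ytmp = y + h * (_A21 * k[0])
        k[1] = rhs(t + _C2 * h, ytmp, p)
        ytmp = y + h * (_A31 * k[0] + _A32 * k[1])
        k[2] = rhs(t + _C3 * h, ytmp, p)
        ytmp = y + h * (_A41 * k[0] + _A42 * k[1] + _A43 * k[2])
        k[3] = rhs(t + _C4 * h, ytmp, p)
        ytmp = y + h * (_A51 * k[0] + _A52 * k[1] + _A53 * k[2] + _A54 * k[3])
        k[4] = rhs(t + _C5 * h, ytmp, p)
        ytmp = y + h * (_A61 * k[0] + _A62 * k[1] + _A63 * k[2]
                        + _A64 * k[3] + _A65 * k[4])
        k[5] = rhs(t + h, ytmp, p)
        y_new = y + h * (_B1 * k[0] + _B3 * k[2] + _B4 * k[3]
                         + _B5 * k[4] + _B6 * k[5])
        k[6] = rhs(t + h, y_new, p)
        err = h * (_E1 * k[0] + _E3 * k[2] + _E4 * k[3]
                   + _E5 * k[4] + _E6 * k[5] + _E7 * k[6])

        finite = True
        for j in range(dim):
            if not np.isfinite(y_new[j]):
                finite = False
                break
        if not finite:
            h *= 0.5
            if h < 1e-14:
                return STATUS_STEP_UNDERFLOW, t, y_out, n_steps
            n_steps += 1
            continue

        enorm = _error_norm(err, y, y_new, rtol, atol)
        if enorm <= 1.0:
            # accepted: dense output for points inside (t, t+h]
            if i_out < n_out and t_out[i_out] <= t + h:
                for ii in range(dim):
                    for jj in range(4):
                        acc = 0.0
                        for ss in range(7):
                            acc += k[ss, ii] * _P[ss, jj]
                        q[ii, jj] = acc
                while i_out < n_out and t_out[i_out] <= t + h:
                    theta = (t_out[i_out] - t) / h
                    t2 = theta * theta
                    t3 = t2 * theta
                    t4 = t3 * theta
                    for ii in range(dim):
                        y_out[i_out, ii] = y[ii] + h * (
                            theta * q[ii, 0] + t2 * q[ii, 1]
                            + t3 * q[ii, 2] + t4 * q[ii, 3])
                    i_out += 1
            t += h
            y = y_new
            k[0] = k[6]  # FSAL
            if enorm == 0.0:
                factor = _MAX_FACTOR
            else:
                factor = min(_MAX_FACTOR,
                             max(_MIN_FACTOR, _SAFETY * enorm ** -0.2))
            h *= factor
        else:
            h *= max(_MIN_FACTOR, _SAFETY * enorm ** -0.2)
            if h < 1e-14:
                return STATUS_STEP_UNDERFLOW, t, y_out, n_steps
        n_steps += 1
    # flush output points the rounding of the final step may have skipped
    # (they sit within one ulp of t1)
    while i_out < n_out:
        y_out[i_out] = y
        i_out += 1
    return STATUS_OK, t, y_out, n_steps


@njit(cache=False)
def dp45_final(rhs, p, y0, t0, t1, rtol, atol, h0, max_step):
    """Integrate to ``t1`` and return only the final state."""
    t_out = np.empty(1)
    t_out[0] = t1
    status, t, y_out, n = dp45_dense(rhs, p, y0, t0, t1, t_out, rtol, atol,
                                     h0, max_step)
    return status, t, y_out[0], n
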