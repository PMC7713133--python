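"""Vector-field correctness: printed constants, algebraic bromide term,
Jacobian consistency and closed-form limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gfchaos.gf_model import (DEFAULT_SCALINGS, DomainError, GFParameters,
                              GFState, gf_jacobian, gf_rhs, ytilde)

# Frozen from an independent exact-rational evaluation of the printed
# expressions (sympy, default constants, kf = 3e-4, state (1,1,1)).
YTILDE_ORACLE = 3.3267709848223306
RHS_ORACLE = (90.701156620605155, 62.624580735107861, 0.063556840269277466)


class TestParameters:
    def test_tabulated_defaults(self):
        p = GFParameters()
        assert (p.k1, p.k2, p.k3, p.k4, p.k5, p.k6, p.k7) == \
            (4.0e6, 2.0, 3000.0, 55.2, 7000.0, 0.09, 0.23)
        assert (p.A, p.M, p.H, p.C) == (0.1, 0.25, 0.26, 0.000833)
        assert (p.alpha, p.beta) == (666.7, 0.3478)

    def test_scaling_defaults_are_the_documented_combinations(self):
        p = GFParameters()
        assert p.X0 == pytest.approx(p.k2 * p.A * p.H ** 2 / p.k5, rel=1e-14)
        assert p.Z0 == pytest.approx(p.C * p.A / (40 * p.M), rel=1e-14)
        assert p.V0 == pytest.approx(4 * p.A * p.H * p.C / p.M ** 2, rel=1e-14)
        assert p.T0 == pytest.approx(
            1.0 / (p.k4 * p.A ** 0.5 * p.H ** 1.5 * p.X0 ** 0.5), rel=1e-14)

    @pytest.mark.parametrize("bad", [{"k1": 0.0}, {"kf": -1e-4},
                                     {"H": np.inf}, {"T0": 0.0}])
    def test_positivity_invariant(self, bad):
        with pytest.raises(ValueError):
            GFParameters(**bad)

    def test_config_round_trip(self, tmp_path):
        p = GFParameters(kf=3.7e-4)
        path = tmp_path / "params.cfg"
        p.to_config(path)
        assert GFParameters.from_config(path) == p

    def test_config_rejects_unknown_key(self, tmp_path):
        path = tmp_path / "bad.cfg"
        path.write_text("k1 = 1.0\nbogus = 2\n")
        with pytest.raises(KeyError):
            GFParameters.from_config(path)


class TestYtilde:
    @pytest.mark.parametrize("state", [(1, 0, 1), (1, 1, 0)])
    def test_zero_when_z_or_v_vanish(self, state, default_params):
        assert ytilde(GFState(*state), default_params) == 0.0

    def test_matches_independent_arithmetic(self):
        p = GFParameters(kf=3e-4)
        assert ytilde(GFState(1, 1, 1), p) == \
            pytest.approx(YTILDE_ORACLE, rel=1e-12)

    def test_nonnegative_on_random_states(self, rng, default_params):
        for _ in range(50):
            s = rng.uniform(0, 3, size=3)
            assert ytilde(s, default_params) >= 0.0

    def test_negative_state_rejected(self, default_params):
        with pytest.raises((DomainError, ValueError)):
            ytilde(np.array([-0.5, 1.0, 1.0]), default_params)


class TestRhs:
    def test_all_rates_zero_gives_zero_field(self):
        p = GFParameters(**{k: 1e-300 for k in
                            ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "kf")})
        out = gf_rhs(0.0, (1.0, 2.0, 3.0), p)
        assert np.allclose(out, 0.0, atol=1e-290)

    def test_pure_outflow_limit(self):
        kf = 3e-4
        p = GFParameters(kf=kf, **{k: 1e-300 for k in
                                   ("k1", "k2", "k3", "k4", "k5", "k6", "k7")})
        state = np.array([0.5, 1.5, 2.5])
        out = gf_rhs(0.0, state, p)
        assert np.allclose(out, -p.T0 * kf * state, rtol=1e-12)

    def test_matches_independent_term_by_term_evaluation(self):
        p = GFParameters(kf=3e-4)
        out = gf_rhs(0.0, (1.0, 1.0, 1.0), p)
        assert out == pytest.approx(RHS_ORACLE, rel=1e-12)

    def test_autonomous(self, default_params):
        s = (0.3, 0.9, 1.4)
        assert np.array_equal(gf_rhs(0.0, s, default_params),
                              gf_rhs(57.3, s, default_params))

    def test_domain_error_below_roundoff_band(self, default_params):
        with pytest.raises((DomainError, ValueError)):
            gf_rhs(0.0, np.array([-1e-6, 1.0, 1.0]), default_params)

    def test_roundoff_band_clamped(self, default_params):
        out = gf_rhs(0.0, np.array([-1e-13, 1.0, 1.0]), default_params)
        assert np.all(np.isfinite(out))


def _fd_jacobian(state, p, eps=1e-6):
    J = np.empty((3, 3))
    for j in range(3):
        hi = np.array(state, dtype=float)
        lo = hi.copy()
        h = eps * max(1.0, abs(state[j]))
        hi[j] += h
        lo[j] -= h
        J[:, j] = (gf_rhs(0.0, hi, p) - gf_rhs(0.0, lo, p)) / (2 * h)
    return J


class TestJacobian:
    def test_pure_outflow_jacobian_is_scaled_identity(self):
        kf = 2e-4
        p = GFParameters(kf=kf, **{k: 1e-300 for k in
                                   ("k1", "k2", "k3", "k4", "k5", "k6", "k7")})
        J = gf_jacobian((1.0, 1.0, 1.0), p)
        assert np.allclose(J, -p.T0 * kf * np.eye(3), atol=1e-290)

    def test_matches_finite_differences_at_showcase_state(self):
        p = GFParameters(kf=3.5e-4)
        state = (1.0, 1.0, 1.0)
        J = gf_jacobian(state, p)
        assert np.allclose(J, _fd_jacobian(state, p), rtol=1e-4)

    def test_bromide_coupling_appears_in_dxdot_dv(self, default_params):
        J = gf_jacobian((1.0, 1.0, 1.0), default_params)
        assert J[0, 2] != 0.0

    def test_rejects_boundary_state(self, default_params):
        with pytest.raises(DomainError):
            gf_jacobian((0.0, 1.0, 1.0), default_params)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(x=st.floats(0.01, 3.0), z=st.floats(0.01, 3.0),
           v=st.floats(0.01, 3.0),
           kf=st.floats(3e-4, 5e-4))
    def test_matches_finite_differences_everywhere(self, x, z, v, kf):
        # interior states only: the central difference steps across the
        # boundary otherwise
        p = GFParameters(kf=kf)
        state = (x, z, v)
        J = gf_jacobian(state, p)
        Jfd = _fd_jacobian(state, p)
        scale = np.abs(Jfd) + 1e-3 * np.abs(Jfd).max()
        assert np.all(np.abs(J - Jfd) / scale < 1e-4)


def test_state_validation():
    with pytest.raises(DomainError):
        GFState(-0.1, 1.0, 1.0)
    with pytest.raises(ValueError):
        GFState(np.nan, 1.0, 1.0)
    assert np.array_equal(GFState(1, 2, 3).as_array(), [1.0, 2.0, 3.0])
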