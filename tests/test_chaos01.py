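"""0-1 test: brute-force oracles for the displacement statistics and the
documented behaviour on signals of known class."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gfchaos.chaos01 import (Chaos01Config, Chaos01Result, _kc_batch,
                             k_test, kc_statistic, mean_square_displacement,
                             modified_msd, pq_diameter,
                             translation_components)
from gfchaos.validation_signals import SignalSpec, generate

TOY = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
TOY_C = 1.1


def brute_force_msd(phi, c, n):
    """Direct double-loop evaluation of the finite-sample M(n)."""
    N = len(phi)
    p = [sum(phi[j] * np.cos((j + 1) * c) for j in range(k + 1))
         for k in range(N)]
    q = [sum(phi[j] * np.sin((j + 1) * c) for j in range(k + 1))
         for k in range(N)]
    acc = [(p[j + n] - p[j]) ** 2 + (q[j + n] - q[j]) ** 2
           for j in range(N - n)]
    return sum(acc) / (N - n)


class TestTranslationComponents:
    def test_zero_series(self):
        p, q = translation_components(np.zeros(5), 0.7)
        assert np.all(p == 0) and np.all(q == 0)

    def test_single_sample_index_starts_at_one(self):
        p, q = translation_components(np.array([1.0]), 0.7)
        assert p[0] == pytest.approx(np.cos(0.7))
        assert q[0] == pytest.approx(np.sin(0.7))

    def test_constant_series_matches_dirichlet_partial_sum(self):
        c = 0.9
        p, _ = translation_components(np.ones(50), c)
        n = np.arange(1, 51)
        closed = (np.sin(n * c / 2) * np.cos((n + 1) * c / 2)
                  / np.sin(c / 2))
        assert np.allclose(p, closed, atol=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            translation_components(np.array([]), 1.0)


class TestDisplacementStatistics:
    def test_zero_series_msd(self):
        p, q = translation_components(np.zeros(10), 0.5)
        assert mean_square_displacement(p, q, 3) == 0.0

    @pytest.mark.parametrize("n", [1, 2])
    def test_toy_series_matches_brute_force(self, n):
        p, q = translation_components(TOY, TOY_C)
        assert mean_square_displacement(p, q, n) == \
            pytest.approx(brute_force_msd(TOY, TOY_C, n), rel=1e-12)

    def test_msd_nonnegative_on_random_series(self, rng):
        phi = rng.normal(size=60)
        p, q = translation_components(phi, 1.3)
        assert all(mean_square_displacement(p, q, n) >= 0
                   for n in range(1, 6))

    def test_lag_out_of_range(self):
        p, q = translation_components(TOY, TOY_C)
        with pytest.raises(ValueError):
            mean_square_displacement(p, q, 5)

    def test_modified_msd_reduces_to_msd_for_centred_signal(self):
        assert modified_msd(2.5, 0.0, 3, 1.1) == 2.5

    def test_modified_msd_zero_lag(self):
        assert modified_msd(1.7, 0.9, 0, 1.1) == 1.7

    @pytest.mark.parametrize("n", [1, 2])
    def test_modified_msd_toy_oracle(self, n):
        p, q = translation_components(TOY, TOY_C)
        m_n = mean_square_displacement(p, q, n)
        expected = brute_force_msd(TOY, TOY_C, n) \
            - np.mean(TOY) ** 2 * (1 - np.cos(n * TOY_C)) / (1 - np.cos(TOY_C))
        assert modified_msd(m_n, np.mean(TOY), n, TOY_C) == \
            pytest.approx(expected, rel=1e-12)

    def test_resonant_angle_rejected(self):
        with pytest.raises(ValueError):
            modified_msd(1.0, 1.0, 2, 0.0)


class TestKcStatistic:
    def test_batch_kernel_matches_reference_path(self, rng):
        phi = rng.uniform(0, 2, size=300)
        cs = rng.uniform(np.pi / 5, 4 * np.pi / 5, size=5)
        ncut = 30
        batch = _kc_batch(phi, cs, ncut)
        cfg = Chaos01Config(ncut_fraction=0.1)
        ref = [kc_statistic(phi, c, cfg) for c in cs]
        assert np.allclose(batch, ref, atol=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            kc_statistic(np.arange(10.0), 1.0)


class TestKTest:
    def test_median_contract_and_range(self, rng):
        phi = rng.uniform(0, 1, size=400)
        res = k_test(phi, Chaos01Config(n_c=11, rng_seed=2))
        kc = res.kc_values[:, 1]
        assert res.K == np.median(kc)
        assert np.all(np.abs(kc) <= 1.0)

    def test_result_invariant_validation(self):
        with pytest.raises(ValueError):
            Chaos01Result(kc_values=np.array([[1.0, 0.3], [1.2, 0.5]]),
                          K=0.9)

    def test_logistic_chaos_vs_sine(self):
        chaotic = generate(SignalSpec("logistic-map", n=2000,
                                      parameters={"r": 4.0}))
        regular = generate(SignalSpec("sine", n=2000,
                                      parameters={"frequency": 0.013,
                                                  "amplitude": 1.0,
                                                  "offset": 1.5}))
        cfg = Chaos01Config(rng_seed=0)
        assert k_test(chaotic, cfg).K > 0.9
        assert k_test(regular, cfg).K < 0.1

    def test_seed_invariance(self):
        sig = generate(SignalSpec("logistic-map", n=1500,
                                  parameters={"r": 3.9}))
        k0 = k_test(sig, Chaos01Config(rng_seed=0)).K
        k1 = k_test(sig, Chaos01Config(rng_seed=123)).K
        assert abs(k0 - k1) <= 0.05

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100.0))
    def test_amplitude_scaling_invariance(self, scale):
        sig = generate(SignalSpec("logistic-map", n=800,
                                  parameters={"r": 4.0}))
        cfg = Chaos01Config(n_c=20, rng_seed=4)
        k_ref = k_test(sig.values, cfg).K
        k_scaled = k_test(sig.values * scale, cfg).K
        assert abs(k_ref - k_scaled) <= 0.05

    def test_zero_variance_displacement_is_regular_by_convention(self):
        # the zero series gives exactly constant (zero) displacements, the
        # declared K_c = 0 case
        assert k_test(np.zeros(500), Chaos01Config(n_c=9, rng_seed=0)).K == 0.0

    def test_export_round_trip(self, tmp_path, rng):
        res = k_test(rng.uniform(0, 1, 300), Chaos01Config(n_c=5, rng_seed=1))
        path = tmp_path / "k.txt"
        res.to_text(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "c K_c"
        assert lines[-1].startswith("median")
        assert len(lines) == 7


def test_pq_diameter_orders_regimes():
    chaotic = generate(SignalSpec("logistic-map", n=2000,
                                  parameters={"r": 4.0}))
    regular = generate(SignalSpec("sine", n=2000,
                                  parameters={"frequency": 0.013,
                                              "amplitude": 1.0,
                                              "offset": 1.5}))
    c = 1.569853
    assert pq_diameter(chaotic.values, c) > 2 * pq_diameter(regular.values, c)
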