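"""Shared fixtures.

The expensive objects (showcase trajectories, Lyapunov spectra, the regime
sweep) are session-scoped so that every test, including the acceptance
suite, reuses one computation per configuration.
"""

import warnings

import numpy as np
import pytest

from gfchaos import (GFParameters, PipelineConfig, SimulationConfig,
                     SweepGrid, discard_transient, integrate, norm_signal,
                     resample, run_sweep)
from gfchaos.lyapunov import LyapunovConfig, lyapunov_spectrum

SHOWCASE_KF = {"period1": 3e-4, "period2": 3.2e-4, "chaotic": 3.5e-4}


@pytest.fixture(scope="session")
def default_params():
    return GFParameters()


@pytest.fixture(scope="session")
def kept_trajectories():
    """Post-transient showcase trajectories keyed by regime name."""
    out = {}
    for name, kf in SHOWCASE_KF.items():
        traj = integrate(GFParameters(kf=kf), SimulationConfig())
        out[name] = discard_transient(traj)
    return out


@pytest.fixture(scope="session")
def kept_signals(kept_trajectories):
    """Norm observables resampled to map-like density (stride 100)."""
    return {name: resample(norm_signal(traj), 100)
            for name, traj in kept_trajectories.items()}


@pytest.fixture(scope="session")
def lyapunov_spectra():
    """Full spectra at the limit-cycle and chaotic showcase flow rates."""
    cfg = LyapunovConfig(horizon=500.0, transient=80.0)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for name in ("period2", "chaotic"):
            out[name] = lyapunov_spectrum(
                GFParameters(kf=SHOWCASE_KF[name]), cfg)
    return out


@pytest.fixture(scope="session")
def regime_sweep():
    """The 201-point indicator sweep over the full study interval."""
    grid = SweepGrid(3e-4, 5e-4, 201)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        table = run_sweep(grid, PipelineConfig(rng_seed=1))
    assert (table["verdict"] != "failed").all(), \
        table.loc[table["verdict"] == "failed", "error"].tolist()
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
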