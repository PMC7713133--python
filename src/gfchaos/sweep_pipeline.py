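"""Flow-rate sweeps, nested zooms and the K-ApEn coupling.

Each flow rate kf is processed independently with the same protocol:
integrate, drop the transient, form the norm observable, resample it to
map-like density, then attach the 0-1 test statistic K, approximate
entropy, the peak set of each state variable, the Poincaré cluster count
and (optionally) the maximal Lyapunov exponent.  A sweep is a table of
such records over a kf grid; a nested zoom repeats the sweep on strictly
contained sub-intervals to probe the self-similar interleaving of regular
and chaotic flow rates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .apen import ApEnConfig, apen
from .chaos01 import Chaos01Config, k_test
from .gf_model import GFParameters
from .lyapunov import LyapunovConfig, lyapunov_spectrum, maximal_lyapunov
from .signal_geometry import (PoincarePlane, count_distinct_points,
                              local_maxima, poincare_points)
from .simulate import (SimulationConfig, discard_transient, integrate,
                       norm_signal, resample)

__all__ = [
    "SweepGrid", "IndicatorRecord", "NestedScan", "PipelineConfig",
    "indicator_record", "run_sweep", "nested_zoom", "k_apen_correlation",
    "classify",
]

CHAOS_THRESHOLD = 0.5       # K at or above this counts as chaotic
SETTLED_BAND = (0.2, 0.8)   # K inside this band is flagged unsettled

PAPER_KF_MIN = 3e-4
PAPER_KF_MAX = 5e-4


@dataclass(frozen=True)
class SweepGrid:
    """A strictly increasing kf grid with a zoom-depth label."""

    kf_min: float
    kf_max: float
    n_points: int = 201
    level: str = "level-0"

    def __post_init__(self) -> None:
        if not 0 < self.kf_min < self.kf_max:
            raise ValueError("need 0 < kf_min < kf_max")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    def values(self) -> np.ndarray:
        return np.linspace(self.kf_min, self.kf_max, self.n_points)

    def in_paper_range(self) -> bool:
        return PAPER_KF_MIN <= self.kf_min < self.kf_max <= PAPER_KF_MAX

    def contains(self, other: "SweepGrid") -> bool:
        """Strict containment of the other grid's interval."""
        return (self.kf_min < other.kf_min and other.kf_max < self.kf_max)


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of per-stage configurations shared by a sweep."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    chaos: Chaos01Config = field(default_factory=Chaos01Config)
    apen_cfg: ApEnConfig = field(default_factory=ApEnConfig)
    lyap: LyapunovConfig = field(default_factory=LyapunovConfig)
    stride: int = 100          # resampling before the map-like indicators
    cluster_tol: float = 1e-3  # Poincaré cluster radius (x attractor diam)
    with_lyapunov: bool = False
    rng_seed: int = 0

    def replace(self, **changes) -> "PipelineConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class IndicatorRecord:
    """All regime indicators for a single flow rate."""

    kf: float
    K: float
    apen: float
    L1: float | None
    maxima: dict[str, np.ndarray]
    poincare_count: int

    @property
    def verdict(self) -> str:
        return classify(self.K)

    @property
    def settled(self) -> bool:
        return not (SETTLED_BAND[0] < self.K < SETTLED_BAND[1])

    def to_row(self) -> dict:
        row = {"kf": self.kf, "K": self.K, "apen": self.apen,
               "L1": np.nan if self.L1 is None else self.L1,
               "poincare_count": self.poincare_count,
               "verdict": self.verdict, "settled": self.settled}
        for name, vals in self.maxima.items():
            row[f"n_maxima_{name}"] = vals.size
            row[f"maxima_min_{name}"] = vals.min() if vals.size else np.nan
            row[f"maxima_max_{name}"] = vals.max() if vals.size else np.nan
        return row


def classify(K: float) -> str:
    return "chaotic" if K >= CHAOS_THRESHOLD else "regular"


def _seed_for(global_seed: int, index: int) -> int:
    """Stable per-kf seed, independent of evaluation order."""
    ss = np.random.SeedSequence((int(global_seed), int(index)))
    return int(ss.generate_state(1)[0] % 2 ** 31)


def indicator_record(kf: float, cfg: PipelineConfig | None = None,
                     params: GFParameters | None = None,
                     rng_seed: int | None = None) -> IndicatorRecord:
    """Compute the full indicator bundle for one flow rate."""
    cfg = cfg or PipelineConfig()
    p = (params or GFParameters()).replace(kf=kf)
    seed = cfg.rng_seed if rng_seed is None else rng_seed
    traj = discard_transient(integrate(p, cfg.sim))
    sig = resample(norm_signal(traj), cfg.stride)

    K = k_test(sig, cfg.chaos.replace(rng_seed=seed)).K
    a = apen(sig, cfg.apen_cfg)
    maxima = {name: local_maxima(getattr(traj, name))
              for name in ("x", "z", "v")}
    plane = PoincarePlane("x", float((traj.x.min() + traj.x.max()) / 2),
                          "both")
    try:
        pts = poincare_points(traj, plane)
        n_poincare = count_distinct_points(pts, cfg.cluster_tol)
    except ValueError:
        n_poincare = 0  # steady state: the section is never crossed
    L1 = None
    if cfg.with_lyapunov:
        L1 = maximal_lyapunov(lyapunov_spectrum(p, cfg.lyap))
    return IndicatorRecord(kf=float(kf), K=float(K), apen=float(a), L1=L1,
                           maxima=maxima, poincare_count=n_poincare)


def run_sweep(grid, cfg: PipelineConfig | None = None,
              params: GFParameters | None = None,
              resume: pd.DataFrame | None = None) -> pd.DataFrame:
    """One indicator record per grid point, as a DataFrame sorted by kf.

    ``grid`` is a :class:`SweepGrid` or an explicit sequence of flow
    rates.  Records are computed independently with per-kf seeds derived
    from ``cfg.rng_seed`` and the grid index, so the result does not
    depend on evaluation order.  Failures are recorded in the ``error``
    column rather than aborting the sweep.  Passing a previous (possibly
    partial) result as ``resume`` recomputes only the missing grid
    points.
    """
    cfg = cfg or PipelineConfig()
    kf_values = grid.values() if isinstance(grid, SweepGrid) \
        else np.asarray(grid, dtype=float)
    if np.any(np.diff(kf_values) <= 0) or np.any(kf_values <= 0):
        raise ValueError("flow-rate grid must be positive and increasing")
    done: dict[float, dict] = {}
    if resume is not None:
        for _, row in resume.iterrows():
            done[round(float(row["kf"]), 12)] = row.to_dict()
    rows = []
    for index, kf in enumerate(kf_values):
        key = round(float(kf), 12)
        if key in done:
            rows.append(done[key])
            continue
        seed = _seed_for(cfg.rng_seed, index)
        try:
            rec = indicator_record(kf, cfg, params, rng_seed=seed)
            row = rec.to_row()
            row["error"] = ""
        except Exception as exc:  # per-kf failure is data, not fatal
            row = {"kf": float(kf), "K": np.nan, "apen": np.nan,
                   "L1": np.nan, "poincare_count": 0, "verdict": "failed",
                   "settled": False, "error": f"{type(exc).__name__}: {exc}"}
        rows.append(row)
    frame = pd.DataFrame(rows).sort_values("kf").reset_index(drop=True)
    return frame


@dataclass(frozen=True)
class NestedScan:
    """Ordered zoom levels: (grid, indicator table) pairs."""

    levels: tuple[tuple[SweepGrid, pd.DataFrame], ...]

    def mixture_report(self) -> pd.DataFrame:
        """Per-level fractions of regular and chaotic verdicts."""
        rows = []
        for grid, table in self.levels:
            ok = table[table["verdict"] != "failed"]
            n = len(ok)
            chaotic = float((ok["verdict"] == "chaotic").sum())
            rows.append({"level": grid.level, "kf_min": grid.kf_min,
                         "kf_max": grid.kf_max, "n": n,
                         "frac_chaotic": chaotic / n if n else np.nan,
                         "frac_regular": (n - chaotic) / n if n else np.nan})
        return pd.DataFrame(rows)


def nested_zoom(levels: list[SweepGrid], cfg: PipelineConfig | None = None,
                params: GFParameters | None = None) -> NestedScan:
    """Sweep every level of a strictly nested sequence of kf intervals."""
    for parent, child in zip(levels, levels[1:]):
        if not parent.contains(child):
            raise ValueError(
                f"zoom level ({child.kf_min}, {child.kf_max}) is not "
                f"strictly inside ({parent.kf_min}, {parent.kf_max})")
    out = tuple((grid, run_sweep(grid, cfg, params)) for grid in levels)
    return NestedScan(levels=out)


def k_apen_correlation(table: pd.DataFrame) -> float:
    """Pearson correlation of K against ApEn across a sweep table."""
    ok = table[np.isfinite(table["K"]) & np.isfinite(table["apen"])]
    if len(ok) < 10:
        raise ValueError(f"need >= 10 finite records, got {len(ok)}")
    if np.std(ok["K"]) == 0 or np.std(ok["apen"]) == 0:
        raise ValueError("degenerate variance: K or ApEn is constant")
    r, _ = stats.pearsonr(ok["K"], ok["apen"])
    return float(r)
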