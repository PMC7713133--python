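"""Synthetic signals of known dynamical class.

Every regime indicator in this package can be validated without touching
the reaction model: a sine is regular, a period-doubled logistic-map orbit
is regular with two states, the logistic map at r = 4 is chaotic, and
white noise is maximally irregular.  Sine fixtures carry a positive offset
so the test exercises the mean-correction term of the 0-1 test, and the
offset also keeps the series non-negative as :class:`ScalarSignal`
requires of a norm observable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .simulate import ScalarSignal

__all__ = ["SignalSpec", "generate", "EXPECTED_VERDICTS"]

Kind = Literal["sine", "multi-harmonic", "logistic-map", "white-noise"]

_LOGISTIC_BURN_IN = 1000
_LOGISTIC_S0 = 0.4


@dataclass(frozen=True)
class SignalSpec:
    """Recipe for one synthetic series.

    ``parameters`` by kind -- sine: frequency, amplitude, offset;
    multi-harmonic: frequency, amplitudes (list, one per harmonic), offset;
    logistic-map: r; white-noise: low, high.  All generators are seeded and
    bit-reproducible; the deterministic kinds ignore the seed.
    """

    kind: Kind
    n: int = 2000
    dt: float = 1.0
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 100:
            raise ValueError("n must be >= 100")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.kind not in ("sine", "multi-harmonic", "logistic-map",
                             "white-noise"):
            raise ValueError(f"unknown signal kind {self.kind!r}")

    def to_config(self, path: str | Path) -> None:
        lines = [f"kind = {self.kind}\n", f"n = {self.n}\n",
                 f"dt = {self.dt!r}\n", f"seed = {self.seed}\n"]
        for key, val in sorted(self.parameters.items()):
            if isinstance(val, (list, tuple, np.ndarray)):
                val = ",".join(repr(float(x)) for x in val)
            lines.append(f"param.{key} = {val}\n")
        Path(path).write_text("".join(lines))

    @classmethod
    def from_config(cls, path: str | Path) -> "SignalSpec":
        fields: dict = {"parameters": {}}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("param."):
                name = key[6:]
                if "," in value:
                    fields["parameters"][name] = [
                        float(x) for x in value.split(",")]
                else:
                    fields["parameters"][name] = float(value)
            elif key == "kind":
                fields["kind"] = value
            elif key == "n":
                fields["n"] = int(value)
            elif key == "dt":
                fields["dt"] = float(value)
            elif key == "seed":
                fields["seed"] = int(value)
            else:
                raise KeyError(f"unknown key {key!r} in {path}")
        return cls(**fields)


def generate(spec: SignalSpec) -> ScalarSignal:
    """Materialize the series described by ``spec``."""
    j = np.arange(spec.n)
    pr = spec.parameters
    if spec.kind == "sine":
        f = pr.get("frequency", 0.05)
        a = pr.get("amplitude", 1.0)
        offset = pr.get("offset", a)  # keeps the series non-negative
        values = a * np.sin(2 * np.pi * f * j * spec.dt) + offset
    elif spec.kind == "multi-harmonic":
        f = pr.get("frequency", 0.03)
        amps = np.asarray(pr.get("amplitudes", [1.0, 0.5, 0.25]), float)
        offset = pr.get("offset", float(np.sum(np.abs(amps))))
        values = np.full(spec.n, offset, dtype=float)
        for h, a in enumerate(amps, start=1):
            values += a * np.sin(2 * np.pi * h * f * j * spec.dt)
    elif spec.kind == "logistic-map":
        r = pr.get("r", 4.0)
        values = np.empty(spec.n)
        s = _LOGISTIC_S0
        for _ in range(_LOGISTIC_BURN_IN):
            s = r * s * (1.0 - s)
        for i in range(spec.n):
            values[i] = s
            s = r * s * (1.0 - s)
    else:  # white-noise
        low = pr.get("low", 0.0)
        high = pr.get("high", 1.0)
        rng = np.random.default_rng(spec.seed)
        values = rng.uniform(low, high, size=spec.n)
    if np.any(values < 0):
        raise ValueError(
            "spec produces negative values; add an offset (ScalarSignal "
            "models a norm observable)")
    return ScalarSignal(values=values, dt=spec.dt)


# Canonical fixtures with their expected indicator verdicts, asserted by
# the validation suite (`gfchaos validate` and the tests).
EXPECTED_VERDICTS: dict[str, tuple[SignalSpec, str]] = {
    "sine": (SignalSpec("sine", n=2000,
                        parameters={"frequency": 0.013, "amplitude": 1.0,
                                    "offset": 1.5}),
             "regular"),
    "multi-harmonic": (SignalSpec("multi-harmonic", n=2000,
                                  parameters={"frequency": 0.017}),
                       "regular"),
    "logistic-period2": (SignalSpec("logistic-map", n=2000,
                                    parameters={"r": 3.2}),
                         "regular"),
    "logistic-chaotic": (SignalSpec("logistic-map", n=2000,
                                    parameters={"r": 4.0}),
                         "chaotic"),
    "white-noise": (SignalSpec("white-noise", n=2000, seed=7),
                    "chaotic"),
}
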