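"""Synthetic traces with known ground truth for the analysis operations.

Each fixture emulates the qualitative shape of one simulator output —
staircase stepping of a single head, tension recovery after a length
step, steady shortening of the backbone — with closed-form parameters
stored alongside, so the step detector and the T1/T2/velocity extractors
can be validated independently of any simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import _require
from .trace import Trace

FIXTURE_KINDS = (
    "staircase",
    "exponential_recovery",
    "two_exponential",
    "linear_shortening",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parametrized synthetic trace; ``params`` depend on ``kind``.

    staircase: d (nm), directions (sequence of +-1), dwell (s), dt (s)
    exponential_recovery: T_inf, amplitude, tau (s), duration, dt
    two_exponential: T0, T1, T2, tau_fast, tau_slow, duration, dt
    linear_shortening: Z0, velocity (nm/s, shortening > 0), duration, dt
    All kinds accept noise_sd (default 0).
    """

    kind: str
    params: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.kind in FIXTURE_KINDS, "kind", f"must be one of {FIXTURE_KINDS}")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")


def make_fixture(spec: FixtureSpec) -> tuple[Trace, dict]:
    """Deterministic synthetic trace plus its ground-truth record."""
    rng = np.random.default_rng(spec.seed)
    p = dict(spec.params)
    if spec.kind == "staircase":
        d = p.get("d", 5.5)
        _require(d > 0, "d", "must be positive")
        directions = np.asarray(p.get("directions", [1, 1, 1]), dtype=int)
        dwell = p.get("dwell", 1e-3)
        dt = p.get("dt", 1e-5)
        n_per = int(round(dwell / dt))
        levels = np.concatenate([[0], np.cumsum(directions)]) * d
        x = np.repeat(levels, n_per)
        t = np.arange(len(x)) * dt
        truth = {
            "n_forward": int((directions > 0).sum()),
            "n_backward": int((directions < 0).sum()),
            "step_times": (np.arange(1, len(directions) + 1) * dwell).tolist(),
            "levels_nm": levels.tolist(),
        }
        data = {"x_nm": x + rng.normal(0.0, spec.noise_sd, len(x))}
    elif spec.kind == "exponential_recovery":
        T_inf = p.get("T_inf", 100.0)
        amp = p.get("amplitude", 40.0)
        tau = p.get("tau", 1e-3)
        duration = p.get("duration", 6 * tau)
        dt = p.get("dt", tau / 200)
        t = np.arange(0.0, duration, dt)
        y = T_inf - amp * np.exp(-t / tau)
        truth = {"T1": T_inf - amp, "T_inf": T_inf, "tau": tau}
        data = {"tension_pN": y + rng.normal(0.0, spec.noise_sd, len(t))}
    elif spec.kind == "two_exponential":
        T0 = p.get("T0", 100.0)
        T1 = p.get("T1", 40.0)
        T2 = p.get("T2", 85.0)
        tau_fast = p.get("tau_fast", 1e-4)
        tau_slow = p.get("tau_slow", 1e-1)
        duration = p.get("duration", 20 * tau_fast)
        dt = p.get("dt", tau_fast / 100)
        t = np.arange(0.0, duration, dt)
        y = (
            T2
            - (T2 - T1) * np.exp(-t / tau_fast)
            + (T0 - T2) * (1.0 - np.exp(-t / tau_slow))
        )
        truth = {"T0": T0, "T1": T1, "T2": T2,
                 "tau_fast": tau_fast, "tau_slow": tau_slow}
        data = {"tension_pN": y + rng.normal(0.0, spec.noise_sd, len(t))}
    else:  # linear_shortening
        Z0 = p.get("Z0", 0.0)
        v = p.get("velocity", 1e5)
        duration = p.get("duration", 1e-3)
        dt = p.get("dt", 1e-6)
        t = np.arange(0.0, duration, dt)
        z = Z0 + v * t
        truth = {"velocity": v, "Z0": Z0}
        data = {"Z_nm": z + rng.normal(0.0, spec.noise_sd, len(t))}
    tr = Trace(t=t, data=data, meta={"fixture": spec.kind, "seed": spec.seed,
                                     "noise_sd": spec.noise_sd})
    return tr, truth
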