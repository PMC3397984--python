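"""Overdamped Langevin integration and the non-equilibrium jump process.

The attached/detached flag of each head follows a jump process whose
rates break detailed balance (Brownian search-and-catch attachment,
Huxley-1957-shaped detachment), turning the globally flat periodic
landscape into a flashing ratchet.  This module also carries the
first-passage machinery: the closed-form mean first-passage time against
a constant force, an exact quadrature oracle on arbitrary piecewise
landscapes, Monte-Carlo dwell times, and the barrier-reduction
calibration used to speed up macroscopic runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from . import _kernels
from .model_core import (
    ConfigurationError,
    ElasticSpec,
    MotorState,
    PhysicalEnv,
    PiecewisePotential,
    PotentialSpec,
    attachment_allowed,
    build_potential,
    elastic_energy,
    potential_energy,
    _require,
)
from .trace import Trace, events_frame

RATE_MODES = ("search_catch", "detailed_balance")


@dataclass(frozen=True)
class RateSpec:
    """Jump-process rates (1/s) and the strain window for attachment.

    f1 is the maximum attachment rate, active only while the elastic
    element is stretched forward by up to ``attach_window`` (Brownian
    search-and-catch); g1/g2 are the positive-/negative-strain detachment
    levels of the Huxley-1957-shaped rate; ``rate_scale`` is the
    dimensionless macroscopic speed-up multiplier.  The defaults are the
    sped-up macroscopic values (about 150x the physiological attachment
    rate), chosen together with the reduced barrier so that rising phase
    and maximum velocity stay mutually coherent.
    """

    f1: float = 6000.0
    attach_window: float = 5.5
    g1: float = 150.0
    g2: float = 3000.0
    rate_scale: float = 1.0
    mode: str = "search_catch"

    def __post_init__(self) -> None:
        for name in ("f1", "g1", "g2"):
            _require(getattr(self, name) >= 0, name, "rates must be >= 0")
        _require(self.g2 >= self.g1, "g2", "must be >= g1")
        _require(self.attach_window > 0, "attach_window", "must be positive")
        _require(self.rate_scale > 0, "rate_scale", "must be positive")
        _require(self.mode in RATE_MODES, "mode", f"must be one of {RATE_MODES}")

    @property
    def max_rate(self) -> float:
        base = max(self.f1, self.g1, self.g2)
        if self.mode == "detailed_balance":
            # detailed-balance rates are modulated by exp(+-G/2kBT); the
            # caller-side cross-check bounds G by the barrier height
            return base * self.rate_scale
        return base * self.rate_scale

    def zeroed(self) -> "RateSpec":
        return replace(self, f1=0.0, g1=0.0, g2=0.0)


@dataclass(frozen=True)
class IntegratorSpec:
    """Time step, seed and recording stride for Euler-Maruyama runs.

    The step must sit at least two orders of magnitude below the fastest
    characteristic time of the system (elastic relaxation gamma/kappa and
    diffusion across the short potential face (lambda d)^2 / 2D), and
    every jump rate r must satisfy r*dt <= 0.01.
    """

    dt: float = 7e-11
    seed: int = 0
    record_stride: int = 200

    def __post_init__(self) -> None:
        _require(self.dt > 0, "dt", "must be positive")
        _require(self.record_stride >= 1, "record_stride", "must be >= 1")

    def validate_against(
        self,
        env: PhysicalEnv,
        pspec: PotentialSpec | None = None,
        el: ElasticSpec | None = None,
        rates: RateSpec | None = None,
    ) -> None:
        limits = []
        if el is not None:
            limits.append(("elastic.kappa_plus", env.gamma_head / el.kappa_plus))
        if pspec is not None:
            ell = pspec.asymmetry_lambda * pspec.d
            limits.append(("potential.asymmetry_lambda*d", ell**2 / (2 * env.D_head)))
        for name, tau in limits:
            if self.dt > tau / 100.0 * (1 + 1e-9):
                raise ConfigurationError(
                    f"integrator.dt: {self.dt:g} s exceeds 1/100 of the "
                    f"characteristic time {tau:g} s set by {name}"
                )
        if rates is not None:
            rmax = rates.max_rate
            if rates.mode == "detailed_balance" and pspec is not None:
                rmax *= float(np.exp(pspec.barrier / (2 * env.kBT)))
            if rmax * self.dt > 0.01:
                raise ConfigurationError(
                    f"integrator.dt: rate*dt = {rmax * self.dt:g} > 0.01 for "
                    f"max rate {rmax:g}/s (rates.f1/g2 vs integrator.dt)"
                )


@dataclass(frozen=True)
class JumpEvent:
    """A timestamped attach/detach flip with total motor energies."""

    t: float
    motor_id: int
    kind: str
    x_at_event: float
    E_before: float
    E_after: float

    def __post_init__(self) -> None:
        _require(self.kind in ("attach", "detach"), "kind", "attach or detach")


# ---------------------------------------------------------------------------
# elementary operations (validated python mirrors of the kernel logic)
# ---------------------------------------------------------------------------

def langevin_step(x, total_force, env: PhysicalEnv, dt: float, noise):
    """One Euler-Maruyama update x' = x + (F/gamma) dt + sqrt(2 kBT dt/gamma) xi."""
    return (
        np.asarray(x)
        + np.asarray(total_force) * dt / env.gamma_head
        + np.sqrt(2.0 * env.kBT * dt / env.gamma_head) * np.asarray(noise)
    )


def attach_rate(rs: RateSpec, strain: float, x: float, spec: PotentialSpec) -> float:
    """Search-and-catch: f1 only with forward-stretched element at an allowed site."""
    if 0.0 < strain <= rs.attach_window and attachment_allowed(spec, x):
        return rs.f1 * rs.rate_scale
    return 0.0


def detach_rate(rs: RateSpec, strain: float) -> float:
    """Huxley-1957 shape: g2 for strain <= 0, linear-capped g1 branch above."""
    if strain <= 0.0:
        return rs.g2 * rs.rate_scale
    return rs.g1 * rs.rate_scale * min(strain / rs.attach_window, 1.0)


def jump_update(
    state: MotorState,
    rates: tuple[float, float],
    dt: float,
    u: float,
    *,
    t: float = 0.0,
    motor_id: int = 0,
    pot: PiecewisePotential | None = None,
    el: ElasticSpec | None = None,
    anchor: float = 0.0,
) -> tuple[MotorState, JumpEvent | None]:
    """Bernoulli flip of the attachment flag with probability rate*dt.

    The head position is continuous across flips (flashing potential);
    each detachment consumes one ATP.  If ``pot``/``el`` are supplied the
    returned event carries the total motor energy before/after the flip.
    """
    r = rates[0] if state.psi == 0 else rates[1]
    if r * dt > 0.01:
        raise ConfigurationError(
            f"dt: rate*dt = {r * dt:g} > 0.01 violates the integrator contract"
        )
    if r <= 0.0 or u >= r * dt:
        return state, None
    s = state.x - anchor
    eel = elastic_energy(el, s) if el is not None else 0.0
    g = potential_energy(pot, state.x) if pot is not None else 0.0
    if state.psi == 0:
        new = MotorState(x=state.x, psi=1, c=state.c, atp_used=state.atp_used)
        ev = JumpEvent(t, motor_id, "attach", state.x, eel, eel + g)
    else:
        new = MotorState(x=state.x, psi=0, c=state.c, atp_used=state.atp_used + 1)
        ev = JumpEvent(t, motor_id, "detach", state.x, eel + g, eel)
    return new, ev


# ---------------------------------------------------------------------------
# single-motor simulation
# ---------------------------------------------------------------------------

def simulate_motor(
    env: PhysicalEnv,
    pot: PiecewisePotential,
    el: ElasticSpec | None,
    rates: RateSpec | None,
    integ: IntegratorSpec,
    duration: float,
    external_force: float = 0.0,
    *,
    x0: float = 0.0,
    psi0: int = 1,
    anchor: float = 0.0,
    domain: tuple[float, float] | None = None,
    pspec: PotentialSpec | None = None,
    event_capacity: int = 100_000,
) -> Trace:
    """Simulate one head; reproducible given the integrator seed.

    ``domain`` installs reflecting boundaries (used by the equilibrium
    oracle tests); ``rates=None`` or an all-zero RateSpec freezes the
    attachment flag.  The attachment steric region is taken from
    ``pspec`` when given, otherwise from the potential's binding span.
    """
    n_steps = int(round(duration / integ.dt))
    rec_steps = np.arange(
        integ.record_stride - 1, n_steps, integ.record_stride, dtype=np.int64
    )
    rs = rates if rates is not None else RateSpec(f1=0.0, g1=0.0, g2=0.0)
    jumps_on = rs.f1 > 0 or rs.g1 > 0 or rs.g2 > 0
    allow_hi = (
        pspec.allowed_span if pspec is not None else pot.binding_sites * pot.d
    )
    out = _kernels.motor_kernel(
        integ.seed,
        n_steps,
        integ.dt,
        env.gamma_head,
        env.kBT,
        pot.breakpoints_x,
        pot.breakpoints_e,
        pot.slopes,
        pot.period,
        float(allow_hi),
        float(x0),
        int(psi0),
        el is not None,
        float(anchor),
        el.kappa_plus if el is not None else 0.0,
        el.kappa_minus if el is not None else 0.0,
        jumps_on,
        RATE_MODES.index(rs.mode),
        rs.f1,
        rs.attach_window,
        rs.g1,
        rs.g2,
        rs.rate_scale,
        float(external_force),
        domain is not None,
        domain[0] if domain is not None else 0.0,
        domain[1] if domain is not None else 0.0,
        rec_steps,
        event_capacity,
    )
    rt, rx, rpsi, atp, x_end, psi_end, ev_t, ev_kind, ev_x, ev_eb, ev_ea = out
    events = events_frame(ev_t, np.zeros(len(ev_t), np.int64), ev_kind, ev_x, ev_eb, ev_ea)
    return Trace(
        t=rt,
        data={"x_nm": rx, "psi": rpsi.astype(np.int64)},
        events=events,
        meta={
            "seed": integ.seed,
            "dt_s": integ.dt,
            "atp_used": int(atp),
            "x_end_nm": float(x_end),
            "psi_end": int(psi_end),
        },
    )


# ---------------------------------------------------------------------------
# first-passage machinery
# ---------------------------------------------------------------------------

def mfpt_closed_form(ell: float, F_opposing: float, D: float, kBT: float) -> float:
    """Mean first-passage time over distance ell against a constant force.

    tau = (ell^2/D) (e^u - u - 1)/u^2 with u = F*ell/kBT (reflecting at
    the start, absorbing at ell); the u -> 0 limit is ell^2/2D.
    """
    _require(ell > 0, "ell", "must be positive")
    _require(D > 0, "D", "must be positive")
    u = F_opposing * ell / kBT
    if abs(u) < 1e-5:
        frac = 0.5 + u / 6.0 + u * u / 24.0
    else:
        frac = (np.expm1(u) - u) / (u * u)
    return ell * ell / D * frac


def mfpt_quadrature(
    U,
    a: float,
    b: float,
    x0: float,
    D: float,
    kBT: float,
    left: str = "reflecting",
    n: int = 40001,
) -> float:
    """Exact MFPT to leave (a, b) starting from x0, by quadrature.

    ``U`` maps positions to energies (pN*nm).  With psi = exp(U/kBT) and
    m = exp(-U/kBT), the mean exit time solves D psi (m T')' = -1, so
    T'(x) = psi(x) (C - M(x)/D) with M(x) = int_a^x m.  ``left`` selects
    a reflecting (C = 0) or absorbing boundary at ``a`` (the right
    boundary is always absorbing).
    """
    grid = np.linspace(a, b, n)
    u = np.asarray(U(grid), dtype=float)
    u = u - u.min()
    psi = np.exp(u / kBT)
    m = np.exp(-u / kBT)
    M = cumulative_trapezoid(m, grid, initial=0.0)
    if left == "reflecting":
        C = 0.0
    elif left == "absorbing":
        C = np.trapezoid(psi * M, grid) / (D * np.trapezoid(psi, grid))
    else:
        raise ConfigurationError("left: must be 'reflecting' or 'absorbing'")
    Tprime = psi * (C - M / D)
    T = cumulative_trapezoid(Tprime, grid, initial=0.0)
    T = T - T[-1]  # enforce T(b) = 0
    return float(np.interp(x0, grid, T))


def dwell_time_quadrature(
    env: PhysicalEnv, pot: PiecewisePotential, minimum_index: int = 1
) -> float:
    """MFPT from an interior minimum to either adjacent minimum (quadrature)."""
    mins = pot.minima
    _require(
        1 <= minimum_index < len(mins) - 1,
        "minimum_index",
        "need an interior minimum with neighbours on both sides",
    )
    a = mins[minimum_index - 1]
    b = mins[minimum_index + 1]
    x0 = mins[minimum_index]
    return mfpt_quadrature(
        lambda g: potential_energy(pot, g), a, b, x0,
        env.D_head, env.kBT, left="absorbing",
    )


def simulate_fpt_constant_force(
    env: PhysicalEnv,
    ell: float,
    F_opposing: float,
    integ: IntegratorSpec,
    n: int = 200,
    max_steps: int = 500_000_000,
) -> np.ndarray:
    """Monte-Carlo passage times matching :func:`mfpt_closed_form` geometry."""
    times = _kernels.fpt_constant_force_kernel(
        integ.seed, n, ell, F_opposing, env.gamma_head, env.kBT, integ.dt, max_steps
    )
    return times


def mean_dwell_time(
    env: PhysicalEnv,
    pot: PiecewisePotential,
    integ: IntegratorSpec,
    n_escapes: int = 200,
    minimum_index: int = 1,
    max_steps: int = 2_000_000_000,
) -> tuple[float, float]:
    """Monte-Carlo mean residence time in a minimum (free attached particle).

    Returns (mean, standard error) over ``n_escapes`` independent escapes
    to an adjacent minimum.
    """
    _require(n_escapes >= 30, "n_escapes", "need at least 30 escapes")
    mins = pot.minima
    a = mins[minimum_index - 1]
    b = mins[minimum_index + 1]
    times = _kernels.dwell_kernel(
        integ.seed,
        n_escapes,
        pot.breakpoints_x,
        pot.breakpoints_e,
        pot.slopes,
        pot.period,
        float(mins[minimum_index]),
        float(a),
        float(b),
        env.gamma_head,
        env.kBT,
        integ.dt,
        max_steps,
    )
    times = times[np.isfinite(times)]
    return float(times.mean()), float(times.std(ddof=1) / np.sqrt(len(times)))


def calibrate_reduced_barrier(
    env: PhysicalEnv,
    spec_sme: PotentialSpec,
    target_ratio: float = 150.0,
    rtol: float = 1e-3,
) -> float:
    """Barrier height whose dwell time is ``target_ratio`` times shorter.

    Macroscopic runs reduce the barrier to speed hopping; the reduction is
    calibrated with the full-potential MFPT quadrature (both escape
    directions) against the single-molecule barrier.
    """
    _require(target_ratio >= 1.0, "target_ratio", "must be >= 1")
    tau_ref = dwell_time_quadrature(env, build_potential(spec_sme))
    if target_ratio == 1.0:
        return spec_sme.barrier

    def f(B: float) -> float:
        tau = dwell_time_quadrature(env, build_potential(spec_sme.replace(barrier=B)))
        return np.log(tau_ref / tau) - np.log(target_ratio)

    lo = spec_sme.deltaG + 1e-3 * env.kBT + 1e-9
    hi = spec_sme.barrier
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ConfigurationError(
            "target_ratio: no reduced barrier in (deltaG, barrier) achieves "
            f"a dwell-time ratio of {target_ratio}"
        )
    return float(brentq(f, lo, hi, rtol=rtol))
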