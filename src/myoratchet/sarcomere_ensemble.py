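"""Half-sarcomere ensemble: N parallel heads on a rigid backbone.

The backbone (thick filament) carries the heads at anchor offsets spread
uniformly over one potential period (the two filament periodicities are
incommensurate).  Three drivings are implemented: isometric (backbone
held), length clamp (a small, fast length step applied as a short linear
ramp on top of the isometric hold) and force clamp (deterministic
backbone obeying Gamma_b dZ/dt = total tension - beta*T0; backbone
thermal noise is omitted because its variance scales as kBT/Gamma_b,
negligible at filament drag — switchable in principle by lowering
Gamma_b).

Gauge: the backbone coordinate Z increases during shortening (+x is the
direction of head motion that shortens the half-sarcomere), strains are
s_i = x_i - (Z + c_i), and a length step of size delta (delta < 0 =
release) is applied as a backbone displacement of -delta, so releases
drop the tension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model_core import (
    ElasticSpec,
    MotorState,
    PhysicalEnv,
    PiecewisePotential,
    PotentialSpec,
    elastic_force,
    _require,
)
from .stochastic_engine import IntegratorSpec, RateSpec, RATE_MODES
from .trace import Trace, events_frame

PROTOCOL_KINDS = ("isometric", "length_clamp", "force_clamp")


@dataclass(frozen=True)
class ProtocolSpec:
    """One macroscopic protocol: kind, step/load parameters, trials.

    ``delta`` is the per-half-sarcomere length step (nm, negative =
    release) applied at ``t_step`` after the isometric pre-equilibration
    of ``pre_duration``; ``beta`` is the clamped load in units of the
    isometric tension T0; ``n_trials`` replicates are averaged (the
    11-trial convention).
    """

    kind: str
    duration: float
    delta: float = 0.0
    t_step: float = 0.0
    beta: float = 0.0
    n_trials: int = 11
    pre_duration: float = 0.0

    def __post_init__(self) -> None:
        _require(self.kind in PROTOCOL_KINDS, "kind", f"must be one of {PROTOCOL_KINDS}")
        _require(self.duration > 0, "duration", "must be positive")
        _require(self.n_trials >= 1, "n_trials", "must be >= 1")
        _require(self.beta >= 0, "beta", "must be >= 0")
        if self.kind == "force_clamp":
            _require(self.beta <= 2.5, "beta", "load range is [0, 2.5] x T0")
        if self.kind == "length_clamp":
            _require(
                0 <= self.t_step < self.duration, "t_step", "must lie in the run"
            )


@dataclass
class SarcomereState:
    """Backbone position + N motor states + time (array-backed)."""

    Z: float
    t: float
    x: np.ndarray
    psi: np.ndarray
    c: np.ndarray
    atp: np.ndarray

    @property
    def N(self) -> int:
        return len(self.x)

    @property
    def anchors(self) -> np.ndarray:
        """z_i = Z + c_i."""
        return self.Z + self.c

    @property
    def strains(self) -> np.ndarray:
        return self.x - self.anchors

    @property
    def motors(self) -> list[MotorState]:
        return [
            MotorState(x=float(xi), psi=int(p), c=float(ci), atp_used=int(a))
            for xi, p, ci, a in zip(self.x, self.psi, self.c, self.atp)
        ]

    def tension(self, el: ElasticSpec) -> float:
        """Total force generated by the heads: sum of elastic forces."""
        return float(np.sum(elastic_force(el, self.strains)))

    def copy(self) -> "SarcomereState":
        return SarcomereState(
            Z=self.Z,
            t=self.t,
            x=self.x.copy(),
            psi=self.psi.copy(),
            c=self.c.copy(),
            atp=self.atp.copy(),
        )


def init_ensemble(
    N: int, L: float, seed: int = 0, random_placement: bool = False
) -> SarcomereState:
    """Fresh half-sarcomere: all heads detached at their anchors.

    Anchor offsets are stratified, c_i = (i - 1/2) L / N, honouring the
    uniform coverage of one period without O(1/sqrt(N)) placement noise;
    ``random_placement`` draws them uniformly instead.
    """
    _require(N >= 1, "N", "need at least one motor")
    if random_placement:
        rng = np.random.default_rng(seed)
        c = np.sort(rng.uniform(0.0, L, size=N))
    else:
        c = (np.arange(N) + 0.5) * L / N
    return SarcomereState(
        Z=0.0,
        t=0.0,
        x=c.copy(),
        psi=np.zeros(N, dtype=np.int64),
        c=c,
        atp=np.zeros(N, dtype=np.int64),
    )


def default_backbone_drag(env: PhysicalEnv, N: int) -> float:
    """Thick-filament drag scaling with the motor count (100 gamma per head)."""
    return 100.0 * env.gamma_head * N


def _record_plan(
    n_steps: int,
    stride: int,
    dense_window: tuple[float, float] | None,
    dense_stride: int,
    dt: float,
) -> np.ndarray:
    base = np.arange(stride - 1, n_steps, stride, dtype=np.int64)
    last = np.array([n_steps - 1], dtype=np.int64)  # end state always sampled
    if dense_window is None:
        return np.unique(np.concatenate([base, last]))
    lo = max(0, int(dense_window[0] / dt))
    hi = min(n_steps, int(dense_window[1] / dt))
    dense = np.arange(lo, hi, dense_stride, dtype=np.int64)
    return np.unique(np.concatenate([base, dense, last]))


def _run_segment(
    state: SarcomereState,
    env: PhysicalEnv,
    pot: PiecewisePotential,
    pspec: PotentialSpec,
    el: ElasticSpec,
    rates: RateSpec,
    integ: IntegratorSpec,
    duration: float,
    mode: int,
    seed: int,
    *,
    ramp_t0: float = 0.0,
    ramp_dur: float = 0.0,
    ramp_dZ: float = 0.0,
    Gamma_b: float = 0.0,
    load: float = 0.0,
    dense_window: tuple[float, float] | None = None,
    dense_stride: int = 20,
    event_capacity: int | None = None,
) -> Trace:
    """Advance the ensemble in place for ``duration`` and record a trace."""
    integ.validate_against(env, pspec, el, rates)
    n_steps = int(round(duration / integ.dt))
    rec_steps = _record_plan(
        n_steps, integ.record_stride, dense_window, dense_stride, integ.dt
    )
    if event_capacity is None:
        # generous bound: fastest rate times duration times motors, padded
        event_capacity = int(4 * state.N * (rates.max_rate * duration + 10) + 1000)
    out = _kernels.ensemble_kernel(
        seed,
        n_steps,
        integ.dt,
        state.t,
        state.x,
        state.psi,
        state.c,
        state.atp,
        state.Z,
        pot.breakpoints_x,
        pot.breakpoints_e,
        pot.slopes,
        pot.period,
        pot.d,
        pot.binding_sites,
        float(pspec.allowed_span),
        env.gamma_head,
        env.kBT,
        el.kappa_plus,
        el.kappa_minus,
        RATE_MODES.index(rates.mode),
        rates.f1,
        rates.attach_window,
        rates.g1,
        rates.g2,
        rates.rate_scale,
        mode,
        ramp_t0,
        ramp_dur,
        ramp_dZ,
        Gamma_b,
        load,
        rec_steps,
        event_capacity,
    )
    (rt, rZ, rT, rnatt, rnstr, rocc, ratp, rssum, Z_end,
     ev_t, ev_motor, ev_kind, ev_x, ev_eb, ev_ea, overflow) = out
    state.Z = float(Z_end)
    state.t += n_steps * integ.dt
    data = {
        "Z_nm": rZ,
        "tension_pN": rT,
        "n_attached": rnatt.astype(np.int64),
        "n_stretched": rnstr.astype(np.int64),
        "atp_cum": ratp,
        "strain_sum_nm": rssum,
    }
    for k in range(pot.binding_sites):
        data[f"occupancy_m{k + 1}"] = rocc[:, k].astype(np.int64)
    return Trace(
        t=rt,
        data=data,
        events=events_frame(ev_t, ev_motor, ev_kind, ev_x, ev_eb, ev_ea),
        meta={
            "seed": seed,
            "dt_s": integ.dt,
            "N": state.N,
            "mode": mode,
            "event_overflow": bool(overflow),
        },
    )


def run_isometric(
    state: SarcomereState,
    env: PhysicalEnv,
    pot: PiecewisePotential,
    pspec: PotentialSpec,
    el: ElasticSpec,
    rates: RateSpec,
    integ: IntegratorSpec,
    duration: float,
    seed: int | None = None,
) -> Trace:
    """Backbone held fixed; tension rises to the isometric plateau T0."""
    return _run_segment(
        state, env, pot, pspec, el, rates, integ, duration,
        _kernels.MODE_ISOMETRIC, integ.seed if seed is None else seed,
    )


def run_length_clamp(
    state: SarcomereState,
    env: PhysicalEnv,
    pot: PiecewisePotential,
    pspec: PotentialSpec,
    el: ElasticSpec,
    rates: RateSpec,
    integ: IntegratorSpec,
    delta: float,
    t_step: float,
    duration: float,
    ramp_duration: float = 1e-8,
    seed: int | None = None,
    dense_span: float = 5e-6,
    dense_stride: int = 20,
) -> Trace:
    """Small fast length step ``delta`` (nm per half-sarcomere) at ``t_step``.

    The step is a linear ramp of ``ramp_duration`` (fast relative to the
    attached-state hopping time, mirroring the microsecond experimental
    steps that are fast relative to phase-2 recovery).  Recording is
    densified around the step for the T1/T2 extraction.  ``t_step`` and
    the returned trace times are relative to the segment start.
    """
    t0 = state.t
    tr = _run_segment(
        state, env, pot, pspec, el, rates, integ, duration,
        _kernels.MODE_LENGTH_RAMP, integ.seed if seed is None else seed,
        ramp_t0=t_step, ramp_dur=ramp_duration, ramp_dZ=-delta,
        dense_window=(t_step, t_step + ramp_duration + dense_span),
        dense_stride=dense_stride,
    )
    tr.t = tr.t - t0  # segment-relative times for the extractors
    if len(tr.events):
        tr.events["t_s"] -= t0
    tr.meta.update(delta_nm=delta, t_step_s=t_step, ramp_duration_s=ramp_duration)
    return tr


def run_force_clamp(
    state: SarcomereState,
    env: PhysicalEnv,
    pot: PiecewisePotential,
    pspec: PotentialSpec,
    el: ElasticSpec,
    rates: RateSpec,
    integ: IntegratorSpec,
    beta: float,
    T0: float,
    duration: float,
    Gamma_b: float | None = None,
    seed: int | None = None,
) -> Trace:
    """Constant external tension beta*T0; backbone free to slide.

    Z increases during shortening; beta = 1 stalls the ensemble, beta = 0
    gives unloaded (maximal) shortening, beta > 1 lengthens (eccentric).
    """
    _require(0 <= beta <= 2.5, "beta", "load range is [0, 2.5] x T0")
    t0 = state.t
    tr = _run_segment(
        state, env, pot, pspec, el, rates, integ, duration,
        _kernels.MODE_FORCE_CLAMP, integ.seed if seed is None else seed,
        Gamma_b=default_backbone_drag(env, state.N) if Gamma_b is None else Gamma_b,
        load=beta * T0,
    )
    tr.t = tr.t - t0
    if len(tr.events):
        tr.events["t_s"] -= t0
    tr.meta.update(beta=beta, T0_pN=T0)
    return tr


def estimate_T0(trace: Trace, fraction: float = 1 / 3) -> float:
    """Isometric tension: mean over the final ``fraction`` of the trace."""
    n = len(trace)
    return float(np.mean(trace["tension_pN"][int(n * (1 - fraction)):]))


def run_protocol(
    protocol: ProtocolSpec,
    env: PhysicalEnv,
    pspec: PotentialSpec,
    pot: PiecewisePotential,
    el: ElasticSpec,
    rates: RateSpec,
    integ: IntegratorSpec,
    master_seed: int,
    N: int = 64,
    Gamma_b: float | None = None,
) -> list[Trace]:
    """Independent seeded replicates of one protocol (default 11 trials).

    Each trial initializes a fresh detached ensemble, pre-equilibrates
    isometrically for ``protocol.pre_duration`` (defining T0 for clamps),
    then runs the protocol segment.  Per-trial seeds derive from the
    master seed by counter.
    """
    ss = np.random.SeedSequence(master_seed)
    seeds = ss.generate_state(3 * protocol.n_trials) % (2**31)
    traces: list[Trace] = []
    for trial in range(protocol.n_trials):
        s_init, s_pre, s_run = (int(s) for s in seeds[3 * trial: 3 * trial + 3])
        state = init_ensemble(N, pspec.period, seed=s_init)
        if protocol.pre_duration > 0:
            pre = run_isometric(
                state, env, pot, pspec, el, rates, integ,
                protocol.pre_duration, seed=s_pre,
            )
            T0 = estimate_T0(pre)
        else:
            pre = None
            T0 = np.nan
        if protocol.kind == "isometric":
            tr = run_isometric(
                state, env, pot, pspec, el, rates, integ,
                protocol.duration, seed=s_run,
            )
        elif protocol.kind == "length_clamp":
            tr = run_length_clamp(
                state, env, pot, pspec, el, rates, integ,
                protocol.delta, protocol.t_step, protocol.duration, seed=s_run,
            )
        else:
            tr = run_force_clamp(
                state, env, pot, pspec, el, rates, integ,
                protocol.beta, T0, protocol.duration, seed=s_run,
            )
        tr.meta.update(trial=trial, master_seed=master_seed, T0_pN=T0)
        traces.append(tr)
    return traces


def summarize_trials(values) -> tuple[float, float]:
    """Mean and standard deviation over trials (the reported convention)."""
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
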