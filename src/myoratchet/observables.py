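"""Extract the reported observables from simulation traces.

Tension transients (T1 by the tangent method, T2 from the fast-recovery
plateau), force-velocity points from the linear portion of shortening
traces, attached/stretched motor counts and mean strain, occupancy of the
four binding minima, and the two thermodynamic efficiencies: the direct
one (work rate over ATP consumption) and its upper bound from the energy
injected at every attach/detach switch of the flashing potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import _require
from .sarcomere_ensemble import SarcomereState
from .trace import Trace

#: free energy of ATP hydrolysis routed through one cross-bridge cycle,
#: pN*nm (~25 kBT); config-exposed.
DELTA_G_ATP = 100.0


@dataclass(frozen=True)
class TransientResult:
    """Length-clamp transient tensions for one step size."""

    delta: float
    T0: float
    T1: float
    T2: float

    @property
    def T1_rel(self) -> float:
        return self.T1 / self.T0

    @property
    def T2_rel(self) -> float:
        return self.T2 / self.T0


@dataclass(frozen=True)
class SteadyStateResult:
    """Steady shortening observables at one load."""

    beta: float
    velocity: float  # nm/s per half-sarcomere, shortening > 0
    n_attached_mean: float
    n_stretched_mean: float
    mean_strain: float
    atp_rate: float

    def __post_init__(self) -> None:
        _require(self.atp_rate >= 0, "atp_rate", "must be >= 0")


@dataclass(frozen=True)
class EfficiencyResult:
    eta_direct: float
    eta_bound: float


# ---------------------------------------------------------------------------
# transient extraction
# ---------------------------------------------------------------------------

def _linear_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept (at t=0)."""
    A = np.vstack([t, np.ones_like(t)]).T
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(slope), float(intercept)


def extract_T1(
    trace: Trace,
    t_step: float,
    ramp_duration: float = 0.0,
    window: float = 2.5e-7,
    column: str = "tension_pN",
) -> float:
    """Tension immediately after the step, by the tangent method.

    A line is fitted to the tension over the early-recovery window
    [t_end, t_end + window] (t_end = end of the ramp) and extrapolated
    back to t_end; with recovery A - B exp(-t/tau) this recovers A - B to
    within ~(window/tau)^2/6 relative, so keep window <= tau/5.
    """
    t_end = t_step + ramp_duration
    sel = (trace.t >= t_end) & (trace.t <= t_end + window)
    if sel.sum() < 3:
        raise ValueError(
            f"extract_T1: window [{t_end:g}, {t_end + window:g}] s holds "
            f"{int(sel.sum())} samples; need >= 3"
        )
    slope, intercept = _linear_fit(trace.t[sel] - t_end, trace[column][sel])
    return intercept


def extract_T2(
    trace: Trace,
    t_step: float,
    ramp_duration: float = 0.0,
    search_start: float | None = None,
    search_end: float | None = None,
    n_segments: int = 12,
    slope_nsigma: float = 3.0,
    flat_fraction: float = 0.05,
    column: str = "tension_pN",
) -> float:
    """Tension at the fast-recovery plateau.

    The search window (default: from 4 T1-windows after the ramp to the
    end of the trace) is split into segments; a segment is flat when its
    fitted slope is within ``slope_nsigma`` standard errors of zero or
    its drift over the whole window is below ``flat_fraction`` of the
    tension range.  T2 is the mean over the first contiguous flat run;
    no flat segment raises with diagnostics.
    """
    t_end = t_step + ramp_duration
    lo = t_end + (search_start if search_start is not None else 1e-6)
    hi = search_end if search_end is not None else trace.t[-1]
    sel = (trace.t >= lo) & (trace.t <= hi)
    if sel.sum() < 4 * n_segments:
        raise ValueError("extract_T2: search window too short for plateau detection")
    t = trace.t[sel]
    y = trace[column][sel]
    span = hi - lo
    # flatness is judged against the full transient amplitude (including
    # the fast-recovery phase), not the plateau window's own tiny range
    full = trace[column][trace.t >= t_end]
    y_range = max(np.ptp(full), 1e-300)
    edges = np.linspace(lo, hi, n_segments + 1)
    flat = np.zeros(n_segments, dtype=bool)
    means = np.empty(n_segments)
    slopes = np.empty(n_segments)
    for k in range(n_segments):
        m = (t >= edges[k]) & (t < edges[k + 1])
        tk, yk = t[m], y[m]
        slope, intercept = _linear_fit(tk - tk[0], yk)
        resid = yk - (slope * (tk - tk[0]) + intercept)
        # effective sample count: successive tension samples are correlated
        n_eff = max(len(tk) / 4.0, 2.0)
        se = resid.std(ddof=2) / (tk.std() + 1e-300) / np.sqrt(n_eff)
        slopes[k] = slope
        means[k] = yk.mean()
        flat[k] = (abs(slope) < slope_nsigma * se) or (
            abs(slope) * span < flat_fraction * y_range
        )
    if not flat.any():
        raise ValueError(
            "extract_T2: no plateau detected; segment slopes (pN/s): "
            + np.array2string(slopes, precision=3)
        )
    first = int(np.argmax(flat))
    run = first
    while run + 1 < n_segments and flat[run + 1]:
        run += 1
    m = (t >= edges[first]) & (t < edges[run + 1])
    return float(y[m].mean())


def transient_result(
    trace: Trace,
    T0: float,
    delta: float,
    t_step: float,
    ramp_duration: float,
    **kw,
) -> TransientResult:
    """Bundle T0/T1/T2 for one length-clamp trace."""
    return TransientResult(
        delta=delta,
        T0=T0,
        T1=extract_T1(trace, t_step, ramp_duration,
                      **{k: v for k, v in kw.items() if k == "window"}),
        T2=extract_T2(trace, t_step, ramp_duration,
                      **{k: v for k, v in kw.items() if k != "window"}),
    )


# ---------------------------------------------------------------------------
# steady-state extraction
# ---------------------------------------------------------------------------

def extract_velocity(
    trace: Trace,
    r2_min: float = 0.99,
    column: str = "Z_nm",
    n_grid: int = 10,
) -> float:
    """Shortening velocity from the linear portion of the backbone trace.

    The maximal trailing window with linear-fit R^2 >= ``r2_min`` is
    selected on a grid of window starts; Z increases during shortening,
    so the slope is already shortening-positive.  A trace with no linear
    window but negligible net drift (a stalled clamp) returns the
    full-window slope; otherwise an error is raised.
    """
    t, z = trace.t, trace[column]
    best = None
    for k in range(n_grid):
        lo = int(len(t) * k / n_grid)
        tk, zk = t[lo:], z[lo:]
        slope, intercept = _linear_fit(tk, zk)
        resid = zk - (slope * tk + intercept)
        ss_tot = np.sum((zk - zk.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
        if r2 >= r2_min:
            best = slope
            break
    if best is not None:
        return best
    slope, intercept = _linear_fit(t, z)
    resid_sd = np.std(z - (slope * t + intercept))
    if abs(slope) * (t[-1] - t[0]) < 3.0 * resid_sd:  # flat within noise: stall
        return slope
    raise ValueError(
        "extract_velocity: no linear window at R^2 >= "
        f"{r2_min} and the trace is not flat (slope {slope:g} nm/s)"
    )


def count_motors(state: SarcomereState) -> tuple[int, int]:
    """(attached, stretched) counts: psi_i = 1, and strain > 0 among those."""
    att = state.psi == 1
    return int(att.sum()), int((att & (state.strains > 0)).sum())


def mean_strain(state: SarcomereState) -> float:
    """Mean elastic strain over attached motors (nan if none attached)."""
    att = state.psi == 1
    if not att.any():
        return float("nan")
    return float(state.strains[att].mean())


def steady_window(trace: Trace, fraction: float = 0.5) -> np.ndarray:
    """Boolean mask selecting the trailing ``fraction`` of the trace."""
    return trace.t >= trace.t[0] + (1 - fraction) * (trace.t[-1] - trace.t[0])


def occupancy_histogram(
    trace: Trace, window: np.ndarray | None = None
) -> np.ndarray:
    """Fractions of attached heads in the binding minima over a window.

    Attached heads were assigned to the circularly nearest minimum at
    record time; fractions are normalized over the window.
    """
    cols = sorted(c for c in trace.data if c.startswith("occupancy_m"))
    _require(len(cols) > 0, "trace", "carries no occupancy columns")
    w = window if window is not None else np.ones(len(trace), dtype=bool)
    counts = np.array([trace[c][w].sum() for c in cols], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("occupancy_histogram: no attached motors in window")
    return counts / total


def attachment_fraction(trace: Trace, window: np.ndarray | None = None) -> float:
    w = window if window is not None else np.ones(len(trace), dtype=bool)
    return float(trace["n_attached"][w].mean() / trace.meta.get("N", np.nan))


def atp_rate(trace: Trace, window: np.ndarray | None = None) -> float:
    """Detachment (= ATP consumption) rate over a window, 1/s."""
    w = window if window is not None else np.ones(len(trace), dtype=bool)
    t, a = trace.t[w], trace["atp_cum"][w]
    span = t[-1] - t[0]
    return float((a[-1] - a[0]) / span) if span > 0 else 0.0


def steady_state_result(
    trace: Trace, beta: float, T0: float, fraction: float = 0.5,
    r2_min: float = 0.0,
) -> SteadyStateResult:
    """Steady-phase observables of one force-clamp trace.

    The steady window is the trailing ``fraction`` of the trace; within
    it the backbone motion is taken as the linear portion, so the default
    velocity estimate is the plain least-squares slope (``r2_min = 0``).
    """
    w = steady_window(trace, fraction)
    sub = Trace(t=trace.t[w], data={k: v[w] for k, v in trace.data.items()},
                events=trace.events, meta=trace.meta)
    n_att = sub["n_attached"]
    tot_att = n_att.sum()
    return SteadyStateResult(
        beta=beta,
        velocity=extract_velocity(sub, r2_min=r2_min),
        n_attached_mean=float(n_att.mean()),
        n_stretched_mean=float(sub["n_stretched"].mean()),
        mean_strain=float(sub["strain_sum_nm"].sum() / tot_att)
        if tot_att > 0 else float("nan"),
        atp_rate=atp_rate(sub),
    )


# ---------------------------------------------------------------------------
# thermodynamics
# ---------------------------------------------------------------------------

def efficiency_direct(
    tension: float,
    velocity: float,
    atp_rate: float,
    deltaG_ATP: float = DELTA_G_ATP,
) -> float:
    """Contraction efficiency: force times velocity over ATP energy flux."""
    work_rate = tension * velocity
    if atp_rate <= 0:
        if abs(work_rate) > 0:
            raise ValueError("efficiency_direct: nonzero work at zero ATP rate")
        return 0.0
    return work_rate / (atp_rate * deltaG_ATP)


def switching_energy_rate(
    events: pd.DataFrame,
    t_lo: float,
    t_hi: float,
    variant: str = "positive",
) -> float:
    """Energy injected by the flashing per unit time over [t_lo, t_hi].

    Each attach/detach flip changes the total motor energy by
    E_before - E_after; the ``positive`` variant sums only injections
    (positive part), the ``net`` variant sums all signed changes.
    """
    _require(variant in ("positive", "net"), "variant", "positive or net")
    sel = (events["t_s"] >= t_lo) & (events["t_s"] <= t_hi)
    de = (events.loc[sel, "E_before_pNnm"] - events.loc[sel, "E_after_pNnm"]).to_numpy()
    if variant == "positive":
        de = np.clip(de, 0.0, None)
    span = t_hi - t_lo
    _require(span > 0, "window", "needs positive duration")
    return float(de.sum() / span)


def efficiency_bound(
    events: pd.DataFrame,
    tension: float,
    velocity: float,
    t_lo: float,
    t_hi: float,
    variant: str = "positive",
) -> float:
    """Upper bound on the ratchet efficiency from switching energetics.

    eta_max = T V / sum_j (E_before,j - E_after,j)^+ per unit time, over
    every jump in the steady-shortening window.
    """
    denom = switching_energy_rate(events, t_lo, t_hi, variant)
    if denom <= 0:
        raise ValueError(
            "efficiency_bound: no net energy injected by jumps in the window"
        )
    return tension * velocity / denom


def efficiency_from_trace(
    trace: Trace,
    beta: float,
    T0: float,
    fraction: float = 0.5,
    deltaG_ATP: float = DELTA_G_ATP,
    variant: str = "positive",
) -> EfficiencyResult:
    """Direct and bound efficiencies over the steady window of a clamp trace."""
    w = steady_window(trace, fraction)
    t_lo, t_hi = float(trace.t[w][0]), float(trace.t[w][-1])
    sub = Trace(t=trace.t[w], data={k: v[w] for k, v in trace.data.items()},
                events=trace.events, meta=trace.meta)
    v = extract_velocity(sub, r2_min=0.0)
    r = atp_rate(sub)
    load = beta * T0
    return EfficiencyResult(
        eta_direct=efficiency_direct(load, v, r, deltaG_ATP),
        eta_bound=efficiency_bound(trace.events, load, v, t_lo, t_hi, variant),
    )


def pooled_efficiency(
    traces,
    beta: float,
    T0s,
    fraction: float = 0.5,
    deltaG_ATP: float = DELTA_G_ATP,
    variant: str = "positive",
) -> EfficiencyResult:
    """Efficiencies pooled over replicate clamp traces.

    Work, ATP consumption and switching-energy injection are summed over
    the steady windows of all trials before dividing — the right
    estimator when single-trial windows hold only a handful of ATP
    events.
    """
    work = 0.0
    atp_energy = 0.0
    injected = 0.0
    for tr, T0 in zip(traces, np.atleast_1d(T0s)):
        w = steady_window(tr, fraction)
        t_lo, t_hi = float(tr.t[w][0]), float(tr.t[w][-1])
        span = t_hi - t_lo
        sub = Trace(t=tr.t[w], data={k: v[w] for k, v in tr.data.items()},
                    events=tr.events, meta=tr.meta)
        v = extract_velocity(sub, r2_min=0.0)
        work += beta * float(T0) * v * span
        atp_energy += float(sub["atp_cum"][-1] - sub["atp_cum"][0]) * deltaG_ATP
        injected += switching_energy_rate(tr.events, t_lo, t_hi, variant) * span
    if atp_energy <= 0:
        raise ValueError("pooled_efficiency: no ATP events in any window")
    if injected <= 0:
        raise ValueError("pooled_efficiency: no switching energy injected")
    return EfficiencyResult(eta_direct=work / atp_energy,
                            eta_bound=work / injected)


def power_curve(betas, velocities, T0: float) -> pd.DataFrame:
    """Power output beta*T0*V across the load grid, with its argmax."""
    betas = np.asarray(betas, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    power = betas * T0 * velocities
    df = pd.DataFrame({"beta": betas, "velocity_nm_s": velocities,
                       "power_pNnm_s": power})
    df.attrs["beta_max_power"] = float(betas[np.argmax(power)])
    return df
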