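"""Numba kernels: Euler-Maruyama integration of the flashing ratchet.

Everything hot lives here as nopython kernels over plain float64/int64
arrays; the public modules wrap them with validated dataclasses.  Each
kernel seeds numba's RNG once at entry, so a (seed, parameters) pair maps
to a bit-identical trajectory.

Conventions: the potential is passed as breakpoint arrays (bx, be) over
one period plus precomputed segment slopes bs; positions are reduced with
floor-division so negative coordinates wrap correctly; at an exact
breakpoint the forward-side segment supplies the force.
"""

import numpy as np
from numba import njit

RATE_SEARCH_CATCH = 0
RATE_DETAILED_BALANCE = 1

MODE_ISOMETRIC = 0
MODE_LENGTH_RAMP = 1
MODE_FORCE_CLAMP = 2


@njit(cache=True, inline="always")
def _seg(bx, xr):
    i = 0
    n = bx.shape[0] - 1
    while i < n - 1 and xr >= bx[i + 1]:
        i += 1
    return i


@njit(cache=True, inline="always")
def _reduce(x, L):
    return x - L * np.floor(x / L)


@njit(cache=True, inline="always")
def _pot_energy(bx, be, bs, L, x):
    xr = _reduce(x, L)
    i = _seg(bx, xr)
    return be[i] + bs[i] * (xr - bx[i])


@njit(cache=True, inline="always")
def _pot_force(bx, bs, L, x):
    xr = _reduce(x, L)
    i = _seg(bx, xr)
    return -bs[i]


@njit(cache=True, inline="always")
def _elastic_force(kp, km, s):
    return kp * s if s > 0.0 else km * s


@njit(cache=True, inline="always")
def _elastic_energy(kp, km, s):
    return 0.5 * kp * s * s if s > 0.0 else 0.5 * km * s * s


@njit(cache=True, inline="always")
def _attach_rate(f1, aw, rscale, s, xr, allow_hi):
    if 0.0 < s <= aw and (allow_hi <= 0.0 or xr < allow_hi):
        return f1 * rscale
    return 0.0


@njit(cache=True, inline="always")
def _detach_rate(g1, g2, aw, rscale, s):
    if s <= 0.0:
        return g2 * rscale
    r = s / aw
    if r > 1.0:
        r = 1.0
    return g1 * rscale * r


@njit(cache=True)
def motor_kernel(
    seed,
    n_steps,
    dt,
    gamma,
    kBT,
    bx,
    be,
    bs,
    L,
    allow_hi,
    x0,
    psi0,
    has_elastic,
    anchor,
    kp,
    km,
    jumps_on,
    rate_mode,
    f1,
    aw,
    g1,
    g2,
    rscale,
    F_ext,
    reflect,
    dom_lo,
    dom_hi,
    rec_steps,
    ev_cap,
):
    """Single head in the (flashing) potential; returns trace + events.

    Events: kind +1 attach, -1 detach; energies are the total motor energy
    (elastic + psi * potential) immediately before/after the flip.
    """
    np.random.seed(seed)
    sig = np.sqrt(2.0 * kBT * dt / gamma)
    x = x0
    psi = psi0
    atp = 0
    nrec = rec_steps.shape[0]
    rt = np.empty(nrec)
    rx = np.empty(nrec)
    rpsi = np.empty(nrec, np.int8)
    ev_t = np.empty(ev_cap)
    ev_kind = np.empty(ev_cap, np.int8)
    ev_x = np.empty(ev_cap)
    ev_eb = np.empty(ev_cap)
    ev_ea = np.empty(ev_cap)
    nev = 0
    ri = 0
    for step in range(n_steps):
        f = F_ext
        s = x - anchor
        if has_elastic:
            f -= _elastic_force(kp, km, s)
        if psi == 1:
            f += _pot_force(bx, bs, L, x)
        x = x + f * dt / gamma + sig * np.random.normal()
        if reflect:
            if x < dom_lo:
                x = 2.0 * dom_lo - x
            elif x > dom_hi:
                x = 2.0 * dom_hi - x
        if jumps_on:
            s = x - anchor
            xr = _reduce(x, L)
            if rate_mode == RATE_DETAILED_BALANCE:
                g = _pot_energy(bx, be, bs, L, x)
                if psi == 0:
                    r = f1 * rscale * np.exp(-g / (2.0 * kBT))
                else:
                    r = f1 * rscale * np.exp(g / (2.0 * kBT))
            else:
                if psi == 0:
                    r = _attach_rate(f1, aw, rscale, s, xr, allow_hi)
                else:
                    r = _detach_rate(g1, g2, aw, rscale, s)
            if r > 0.0 and np.random.random() < r * dt:
                eel = _elastic_energy(kp, km, s) if has_elastic else 0.0
                g = _pot_energy(bx, be, bs, L, x)
                if psi == 0:
                    eb = eel
                    ea = eel + g
                    psi = 1
                    kind = 1
                else:
                    eb = eel + g
                    ea = eel
                    psi = 0
                    atp += 1
                    kind = -1
                if nev < ev_cap:
                    ev_t[nev] = (step + 1) * dt
                    ev_kind[nev] = kind
                    ev_x[nev] = x
                    ev_eb[nev] = eb
                    ev_ea[nev] = ea
                    nev += 1
        if ri < nrec and step == rec_steps[ri]:
            rt[ri] = (step + 1) * dt
            rx[ri] = x
            rpsi[ri] = psi
            ri += 1
    return (
        rt,
        rx,
        rpsi,
        atp,
        x,
        psi,
        ev_t[:nev].copy(),
        ev_kind[:nev].copy(),
        ev_x[:nev].copy(),
        ev_eb[:nev].copy(),
        ev_ea[:nev].copy(),
    )


@njit(cache=True)
def fpt_constant_force_kernel(seed, n, ell, F_opposing, gamma, kBT, dt, max_steps):
    """First passage 0 -> ell against a constant opposing force.

    Reflecting boundary at the origin, absorbing at ell (matches the
    closed-form mean first-passage expression).  Discrete-time sampling
    alone misses excursions that touch the boundary inside a step, so a
    Brownian-bridge crossing test supplements the endpoint check (the
    bridge between consecutive positions crosses ell with probability
    exp(-(ell-a)(ell-b)/(D dt))), removing the leading O(sqrt(dt))
    first-passage bias.  Returns one passage time per walker; NaN where
    max_steps was exhausted.
    """
    np.random.seed(seed)
    D = kBT / gamma
    sig = np.sqrt(2.0 * D * dt)
    drift = -F_opposing * dt / gamma
    out = np.empty(n)
    for k in range(n):
        x = 0.0
        step = 0
        while step < max_steps:
            x_old = x
            x += drift + sig * np.random.normal()
            step += 1
            if x >= ell:
                break
            p_cross = np.exp(-(ell - x_old) * (ell - x) / (D * dt))
            if np.random.random() < p_cross:
                break
            if x < 0.0:
                x = -x
        out[k] = step * dt if step < max_steps else np.nan
    return out


@njit(cache=True)
def dwell_kernel(
    seed, n_escapes, bx, be, bs, L, x_start, x_left, x_right, gamma, kBT, dt, max_steps
):
    """Residence times of a free attached particle in one minimum.

    Escape = first crossing of an adjacent minimum's position (either
    direction).  Each escape restarts at x_start with fresh noise.
    """
    np.random.seed(seed)
    sig = np.sqrt(2.0 * kBT * dt / gamma)
    out = np.empty(n_escapes)
    for k in range(n_escapes):
        x = x_start
        step = 0
        while step < max_steps:
            x += _pot_force(bx, bs, L, x) * dt / gamma + sig * np.random.normal()
            step += 1
            if x <= x_left or x >= x_right:
                break
        out[k] = step * dt if step < max_steps else np.nan
    return out


@njit(cache=True)
def sme_kernel(
    seed,
    bx,
    be,
    bs,
    L,
    d,
    n_sites,
    gamma,
    kBT,
    Gamma_n,
    k_link,
    k_trap,
    X0,
    F_ext,
    dt,
    max_steps,
    capture,
    rec_stride,
    terminate,
    count_from_step,
):
    """Head + micro-needle coupled SDEs; jump counting; boundary rule.

    The head (always attached) diffuses in the periodic potential coupled
    by a symmetric spring to the high-drag needle; the needle is held by
    the trap stiffness and loaded by a constant external force.  Jumps
    between adjacent minima are counted online (capture radius =
    ``capture``); with ``terminate`` set, the run stops when the lowest
    minimum of the current or previous period is first captured,
    otherwise it runs for the full max_steps (stationary counting).
    Transitions before ``count_from_step`` update the tracked minimum but
    not the counters (equilibration burn-in for stationary nulls: the
    relaxation from the starting well into the binding region carries a
    deterministic net displacement that is not an equilibrium current).
    """
    np.random.seed(seed)
    sig_x = np.sqrt(2.0 * kBT * dt / gamma)
    sig_X = np.sqrt(2.0 * kBT * dt / Gamma_n)
    x = 0.0
    X = X0
    cur = 0  # global minima-ladder index; start at the highest minimum
    nf = 0
    nb = 0
    nrec = max_steps // rec_stride + 1 if rec_stride > 0 else 0
    rt = np.empty(nrec)
    rx = np.empty(nrec)
    rX = np.empty(nrec)
    ri = 0
    terminated = False
    step = 0
    low = n_sites - 1
    while step < max_steps:
        fx = _pot_force(bx, bs, L, x) - k_link * (x - X)
        fX = k_link * (x - X) - k_trap * (X - X0) - F_ext
        x += fx * dt / gamma + sig_x * np.random.normal()
        X += fX * dt / Gamma_n + sig_X * np.random.normal()
        step += 1
        if rec_stride > 0 and step % rec_stride == 0 and ri < nrec:
            rt[ri] = step * dt
            rx[ri] = x
            rX[ri] = X
            ri += 1
        # nearest-minimum capture
        p = np.floor(x / L)
        r = x - p * L
        k = int(np.floor(r / d + 0.5))
        if k >= n_sites:
            # inside the forbidden gap: nearest is this period's lowest
            # minimum or the next period's first one
            if (L - r) < (r - low * d):
                cand = (int(p) + 1) * n_sites
                pos = (p + 1.0) * L
            else:
                cand = int(p) * n_sites + low
                pos = p * L + low * d
        else:
            cand = int(p) * n_sites + k
            pos = p * L + k * d
        if cand != cur and abs(x - pos) <= capture:
            if step >= count_from_step:
                if cand > cur:
                    nf += cand - cur
                else:
                    nb += cur - cand
            cur = cand
            if terminate and cur % n_sites == low:
                terminated = True
                break
    return (
        nf,
        nb,
        step * dt,
        terminated,
        x,
        rt[:ri].copy(),
        rx[:ri].copy(),
        rX[:ri].copy(),
    )


@njit(cache=True)
def ensemble_kernel(
    seed,
    n_steps,
    dt,
    t_offset,
    x,
    psi,
    c,
    atp,
    Z_init,
    bx,
    be,
    bs,
    L,
    d,
    n_sites,
    allow_hi,
    gamma,
    kBT,
    kp,
    km,
    rate_mode,
    f1,
    aw,
    g1,
    g2,
    rscale,
    mode,
    ramp_t0,
    ramp_dur,
    ramp_dZ,
    Gamma_b,
    load,
    rec_steps,
    ev_cap,
):
    """Half-sarcomere ensemble: N parallel heads on a rigid backbone.

    Backbone driving by mode: isometric (Z fixed), length ramp (linear Z
    ramp of ramp_dZ over ramp_dur starting at ramp_t0, times relative to
    segment start) or force clamp (deterministic backbone,
    Gamma_b dZ/dt = total tension - load; Z increases during shortening).
    State arrays x/psi/atp are advanced in place.
    """
    np.random.seed(seed)
    N = x.shape[0]
    sig = np.sqrt(2.0 * kBT * dt / gamma)
    Z = Z_init
    Zbase = Z_init
    nrec = rec_steps.shape[0]
    rt = np.empty(nrec)
    rZ = np.empty(nrec)
    rT = np.empty(nrec)
    rnatt = np.empty(nrec, np.int32)
    rnstr = np.empty(nrec, np.int32)
    rocc = np.zeros((nrec, n_sites), np.int32)
    ratp = np.empty(nrec, np.int64)
    rssum = np.empty(nrec)  # sum of strains over attached heads
    ev_t = np.empty(ev_cap)
    ev_motor = np.empty(ev_cap, np.int64)
    ev_kind = np.empty(ev_cap, np.int8)
    ev_x = np.empty(ev_cap)
    ev_eb = np.empty(ev_cap)
    ev_ea = np.empty(ev_cap)
    nev = 0
    ev_overflow = False
    ri = 0
    low = n_sites - 1
    for step in range(n_steps):
        T = 0.0
        natt = 0
        nstr = 0
        for i in range(N):
            xi = x[i]
            s = xi - (Z + c[i])
            f = -_elastic_force(kp, km, s)
            if psi[i] == 1:
                f += _pot_force(bx, bs, L, xi)
            xi = xi + f * dt / gamma + sig * np.random.normal()
            s = xi - (Z + c[i])
            xr = _reduce(xi, L)
            if rate_mode == RATE_DETAILED_BALANCE:
                g = _pot_energy(bx, be, bs, L, xi)
                if psi[i] == 0:
                    r = f1 * rscale * np.exp(-g / (2.0 * kBT))
                else:
                    r = f1 * rscale * np.exp(g / (2.0 * kBT))
            else:
                if psi[i] == 0:
                    r = _attach_rate(f1, aw, rscale, s, xr, allow_hi)
                else:
                    r = _detach_rate(g1, g2, aw, rscale, s)
            if r > 0.0 and np.random.random() < r * dt:
                eel = _elastic_energy(kp, km, s)
                g = _pot_energy(bx, be, bs, L, xi)
                if psi[i] == 0:
                    eb = eel
                    ea = eel + g
                    psi[i] = 1
                    kind = 1
                else:
                    eb = eel + g
                    ea = eel
                    psi[i] = 0
                    atp[i] += 1
                    kind = -1
                if nev < ev_cap:
                    ev_t[nev] = t_offset + (step + 1) * dt
                    ev_motor[nev] = i
                    ev_kind[nev] = kind
                    ev_x[nev] = xi
                    ev_eb[nev] = eb
                    ev_ea[nev] = ea
                    nev += 1
                else:
                    ev_overflow = True
            x[i] = xi
            fel = _elastic_force(kp, km, s)
            T += fel
            if psi[i] == 1:
                natt += 1
                if s > 0.0:
                    nstr += 1
        if mode == MODE_FORCE_CLAMP:
            Z += (T - load) * dt / Gamma_b
        elif mode == MODE_LENGTH_RAMP:
            tau = (step + 1) * dt
            if tau <= ramp_t0:
                Z = Zbase
            elif tau < ramp_t0 + ramp_dur:
                Z = Zbase + ramp_dZ * (tau - ramp_t0) / ramp_dur
            else:
                Z = Zbase + ramp_dZ
        if ri < nrec and step == rec_steps[ri]:
            rt[ri] = t_offset + (step + 1) * dt
            rZ[ri] = Z
            rT[ri] = T
            rnatt[ri] = natt
            rnstr[ri] = nstr
            tot_atp = 0
            ssum = 0.0
            for i in range(N):
                tot_atp += atp[i]
                if psi[i] == 1:
                    ssum += x[i] - (Z + c[i])
                    # circular nearest minimum within the period
                    rr = _reduce(x[i], L)
                    kk = int(np.floor(rr / d + 0.5))
                    if kk >= n_sites:
                        if (L - rr) < (rr - low * d):
                            kk = 0
                        else:
                            kk = low
                    rocc[ri, kk] += 1
            ratp[ri] = tot_atp
            rssum[ri] = ssum
            ri += 1
    return (
        rt,
        rZ,
        rT,
        rnatt,
        rnstr,
        rocc,
        ratp,
        rssum,
        Z,
        ev_t[:nev].copy(),
        ev_motor[:nev].copy(),
        ev_kind[:nev].copy(),
        ev_x[:nev].copy(),
        ev_eb[:nev].copy(),
        ev_ea[:nev].copy(),
        ev_overflow,
    )
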