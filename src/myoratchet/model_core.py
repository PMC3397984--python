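"""Domain types and the periodic actomyosin energy landscape.

The half-sarcomere model describes each myosin head as an overdamped
Brownian particle.  While attached, the head moves in a piecewise-linear,
multistable periodic potential ``G_a`` representing the actomyosin
interaction: four stable binding minima per period (one period spans six
actin monomers), each minimum lower than the previous one by the bias
``deltaG``, with the landscape globally flat (it repeats exactly every
period).  The head is coupled to the thick-filament backbone through an
asymmetric elastic element that is stiffer when stretched than when
compressed.

Units throughout the package: length nm, force pN, energy pN*nm, time s,
drag pN*s/nm, stiffness pN/nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np


class ConfigurationError(ValueError):
    """A spec field violates its invariant; the message names the field."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class PhysicalEnv:
    """Thermal environment and drag coefficients.

    Parameters
    ----------
    kBT
        Thermal energy, pN*nm.  Default 4.1 (T ~ 297 K).
    gamma_head
        Drag coefficient of one myosin head, pN*s/nm.
    Gamma_needle
        Drag coefficient of the micro-needle used in the single-molecule
        set-up; three orders of magnitude above the head drag.
    Gamma_backbone
        Drag coefficient of the thick filament (scales with the number of
        heads; ensembles override it as ``100 * gamma_head * N``).
    """

    kBT: float = 4.1
    gamma_head: float = 1.9e-7
    Gamma_needle: float = 1.9e-4
    Gamma_backbone: float = 1.216e-3

    def __post_init__(self) -> None:
        for name in ("kBT", "gamma_head", "Gamma_needle", "Gamma_backbone"):
            _require(getattr(self, name) > 0, name, "must be strictly positive")
        _require(
            self.Gamma_needle >= 100.0 * self.gamma_head,
            "Gamma_needle",
            "needle drag must be >= 100 x gamma_head",
        )

    @property
    def D_head(self) -> float:
        """Head diffusion coefficient kBT/gamma, nm^2/s."""
        return self.kBT / self.gamma_head


@dataclass(frozen=True)
class PotentialSpec:
    """Geometry and energetics of the periodic actomyosin landscape.

    ``d`` is the minima spacing (compatible with the actin monomer
    diameter); one period of length ``monomers_per_period * d`` carries
    ``binding_sites`` minima, the remaining monomers forming a
    steric-exclusion span where attachment cannot occur.  ``barrier`` is
    the energy of each maximum above its departing minimum, and
    ``asymmetry_lambda`` places that maximum at a fraction lambda of ``d``
    from the departing minimum (short steep face climbed first).
    """

    d: float = 5.5
    monomers_per_period: int = 6
    binding_sites: int = 4
    deltaG: float = 8.2
    barrier: float = 41.0
    asymmetry_lambda: float = 0.1
    forward_sign: int = 1

    def __post_init__(self) -> None:
        _require(self.d > 0, "d", "minima spacing must be positive")
        _require(self.monomers_per_period >= 2, "monomers_per_period", "need >= 2")
        _require(
            0 < self.binding_sites < self.monomers_per_period,
            "binding_sites",
            "must satisfy 0 < binding_sites < monomers_per_period",
        )
        _require(self.deltaG >= 0, "deltaG", "bias must be >= 0")
        _require(self.barrier > self.deltaG, "barrier", "must exceed deltaG")
        _require(
            0.0 < self.asymmetry_lambda < 1.0,
            "asymmetry_lambda",
            "must lie strictly in (0, 1)",
        )
        _require(self.forward_sign in (1, -1), "forward_sign", "must be +1 or -1")

    @property
    def period(self) -> float:
        return self.monomers_per_period * self.d

    @property
    def allowed_span(self) -> float:
        """Length of the attachment-permitted region per period, nm."""
        return self.binding_sites * self.d

    def replace(self, **kw) -> "PotentialSpec":
        from dataclasses import replace

        return replace(self, **kw)


@dataclass(frozen=True)
class ElasticSpec:
    """Asymmetric elastic element between head and backbone.

    kappa_plus applies when the element is stretched (strain > 0),
    kappa_minus when compressed.  The compressed stiffness is a free
    parameter of the model; the default makes the element ten-fold softer
    in compression.

    The default stretched stiffness is the classical cross-bridge value
    (~0.3 pN/nm).  It is also the coherence condition of the reduced-
    barrier landscape: the shallow back face of each binding well exerts
    at most (B + dG)/((1-lambda) d) ~ 4 pN of holding force, so the
    element must not catch strains it cannot hold
    (kappa_plus * (attach_window + (1-lambda) d) below that bound),
    otherwise attached heads slip backwards and the isometric state
    collapses.  Stiffer (modern single-molecule) values can be configured
    together with a taller barrier.
    """

    kappa_plus: float = 0.3
    kappa_minus: float = 0.03

    def __post_init__(self) -> None:
        _require(self.kappa_plus > 0, "kappa_plus", "must be positive")
        _require(
            0 <= self.kappa_minus <= self.kappa_plus,
            "kappa_minus",
            "must satisfy 0 <= kappa_minus <= kappa_plus",
        )


@dataclass
class MotorState:
    """One myosin head: position, attachment flag, anchor offset, ATP used."""

    x: float
    psi: int = 0
    c: float = 0.0
    atp_used: int = 0

    def __post_init__(self) -> None:
        _require(self.psi in (0, 1), "psi", "attachment flag must be 0 or 1")


@dataclass(frozen=True)
class PiecewisePotential:
    """Realized periodic landscape: breakpoints over one period.

    breakpoints_x / breakpoints_e are ordered positions (nm) and energies
    (pN*nm) with the first point at x=0 and the last at x=period carrying
    the same energy (the landscape is flat on average and repeats each
    period).  Derived arrays (segment slopes, minima positions) are
    precomputed for the integrators.
    """

    breakpoints_x: np.ndarray
    breakpoints_e: np.ndarray
    period: float
    d: float
    binding_sites: int
    slopes: np.ndarray = field(init=False, repr=False)
    minima: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        bx = np.asarray(self.breakpoints_x, dtype=float)
        be = np.asarray(self.breakpoints_e, dtype=float)
        _require(bx.shape == be.shape, "breakpoints", "x/e length mismatch")
        _require(bool(np.all(np.diff(bx) > 0)), "breakpoints", "x must be increasing")
        _require(abs(bx[0]) < 1e-12, "breakpoints", "first breakpoint must sit at 0")
        _require(
            abs(bx[-1] - self.period) < 1e-9,
            "breakpoints",
            "last breakpoint must sit at the period",
        )
        _require(
            abs(be[-1] - be[0]) < 1e-9,
            "breakpoints",
            "energy must repeat every period (flat on average)",
        )
        object.__setattr__(self, "breakpoints_x", bx)
        object.__setattr__(self, "breakpoints_e", be)
        object.__setattr__(self, "slopes", np.diff(be) / np.diff(bx))
        interior = (be[1:-1] < be[:-2]) & (be[1:-1] < be[2:])
        mins = bx[1:-1][interior]
        if be[0] < be[1] and be[0] < be[-2]:  # x=0 is a (periodic) minimum
            mins = np.concatenate([[bx[0]], mins])
        object.__setattr__(self, "minima", np.sort(mins))
        _require(
            len(self.minima) == self.binding_sites,
            "breakpoints",
            f"expected exactly {self.binding_sites} minima per period, "
            f"found {len(self.minima)}",
        )

    # -- evaluation -------------------------------------------------------
    def energy(self, x) -> np.ndarray | float:
        return potential_energy(self, x)

    def force(self, x) -> np.ndarray | float:
        return potential_force(self, x)


def build_potential(spec: PotentialSpec) -> PiecewisePotential:
    """Construct the piecewise-linear multistable periodic potential.

    Per period of L = monomers_per_period * d: binding minima at
    0, d, ..., (n_sites-1) d with energies 0, -dG, ..., -(n_sites-1) dG;
    between consecutive minima a single maximum at (k + lambda) d with
    energy (departing minimum) + B.  Over the attachment-forbidden span
    the potential rises to a single return maximum at
    (n_sites + lambda) d of height B_return = B + (n_sites-1) dG above the
    lowest minimum, then falls linearly back to 0 at the period boundary,
    restoring exact periodicity with no second local minimum.
    """
    n = spec.binding_sites
    d, dG, B, lam = spec.d, spec.deltaG, spec.barrier, spec.asymmetry_lambda
    L = spec.period
    xs: list[float] = []
    es: list[float] = []
    for k in range(n - 1):
        xs += [k * d, (k + lam) * d]
        es += [-k * dG, -k * dG + B]
    xs.append((n - 1) * d)
    es.append(-(n - 1) * dG)
    # forbidden-span return: single maximum, landscape continuous and flat
    xs.append((n + lam) * d)
    es.append(B)  # = -(n-1) dG + (B + (n-1) dG)
    xs.append(L)
    es.append(0.0)
    bx = np.array(xs)
    be = np.array(es)
    if spec.forward_sign == -1:  # mirrored geometry (sensitivity switch)
        bx = L - bx[::-1]
        be = be[::-1]
        bx[0] = 0.0
    return PiecewisePotential(
        breakpoints_x=bx,
        breakpoints_e=be,
        period=L,
        d=d,
        binding_sites=n,
    )


def potential_energy(pot: PiecewisePotential, x):
    """Linear interpolation of the landscape at x (periodic, globally flat)."""
    xr = np.mod(x, pot.period)
    return np.interp(xr, pot.breakpoints_x, pot.breakpoints_e)


def potential_force(pot: PiecewisePotential, x):
    """-dG_a/dx at x; at a breakpoint the forward-side segment is used."""
    xr = np.atleast_1d(np.mod(x, pot.period))
    # side='right' => at an exact breakpoint pick the forward segment
    idx = np.searchsorted(pot.breakpoints_x, xr, side="right") - 1
    idx = np.clip(idx, 0, len(pot.slopes) - 1)
    out = -pot.slopes[idx]
    return out if np.ndim(x) else float(out[0])


def elastic_force(el: ElasticSpec, strain):
    """Force exerted on the backbone by the elastic element (pN).

    Positive force acts in the shortening direction; the element is
    piecewise linear and continuous at zero strain.
    """
    s = np.asarray(strain, dtype=float)
    out = np.where(s > 0, el.kappa_plus * s, el.kappa_minus * s)
    return out if np.ndim(strain) else float(out)


def elastic_energy(el: ElasticSpec, strain):
    s = np.asarray(strain, dtype=float)
    out = np.where(s > 0, 0.5 * el.kappa_plus * s**2, 0.5 * el.kappa_minus * s**2)
    return out if np.ndim(strain) else float(out)


def attachment_allowed(spec: PotentialSpec, x):
    """Steric constraint: attachment only over the binding-site span.

    True iff x reduced modulo the period lies in [0, binding_sites*d)
    (mirrored for forward_sign=-1), mimicking steric exclusion in the
    actin double helix.
    """
    L = spec.period
    xr = np.mod(x, L)
    if spec.forward_sign == -1:
        xr = np.mod(L - xr, L)
    out = xr < spec.allowed_span
    return out if np.ndim(x) else bool(out)


def boltzmann_density(
    pot: PiecewisePotential,
    kBT: float,
    domain: tuple[float, float],
    n: int = 4001,
) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium density exp(-U/kBT) on a grid over ``domain``.

    Normalized by trapezoidal quadrature so that it integrates to one
    (used as the equilibrium oracle for the Langevin integrator).
    """
    a, b = domain
    _require(b > a and np.isfinite(a) and np.isfinite(b), "domain", "need finite a < b")
    grid = np.linspace(a, b, n)
    u = potential_energy(pot, grid)
    w = np.exp(-(u - u.min()) / kBT)
    norm = np.trapezoid(w, grid)
    if norm <= 0 or not np.isfinite(norm):
        raise ConfigurationError("boltzmann_density: zero normalization on domain")
    return grid, w / norm
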