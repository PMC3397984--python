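# Methods

## Model

A myosin head is an overdamped Brownian particle with drag coefficient
γ = 1.9×10⁻⁷ pN·s/nm at kBT = 4.1 pN·nm.  Its attachment flag ψ ∈ {0, 1}
switches the actomyosin interaction on and off (a flashing potential).
While attached, the head moves in a piecewise-linear, multistable,
periodic landscape G_a(x): one period L = 6d spans six actin monomers
(d = 5.5 nm, the monomer spacing); four of them carry binding minima at
0, d, 2d, 3d whose energies descend by the bias ΔG per forward step; the
remaining two monomers form a steric-exclusion span where attachment is
forbidden and over which the landscape climbs back, so G_a is exactly
periodic ("flat on average") and sustained motion is impossible at
equilibrium.  Between consecutive minima a single maximum sits at a
fraction λ of d from the departing minimum, a height B above it.

Each head couples to the thick-filament backbone through an asymmetric
elastic element: stiffness κ₊ when stretched (strain s = x − Z − c > 0),
κ₋ when compressed.  The tension of a half-sarcomere with N parallel
heads is Σᵢ κ(sᵢ)·sᵢ over all heads.

The jump process breaks detailed balance.  Attachment follows Brownian
search-and-catch: rate f₁ only while the element is stretched forward by
0 < s ≤ δ_a and the head sits over a permitted monomer.  Detachment has
the classical 1957 shape: a fast constant rate g₂ at negative strain,
and a linear ramp g₁·min(s/δ_a, 1) at positive strain.  Each detachment
consumes one ATP.  A `detailed_balance` rate mode
(f = g = r₀·exp(∓G_a/2kBT)) restores equilibrium exactly and is the null
control: with it the mean velocity is statistically zero regardless of
landscape asymmetry.

## Parameters, units, defaults

All quantities are in pN, nm, s, pN·nm.  Every numeric parameter is
configuration with a default, because the calibrated values are study
conditions rather than constants of nature:

| parameter | default | why |
|---|---|---|
| kBT | 4.1 pN·nm | T ≈ 297 K |
| γ (head drag) | 1.9×10⁻⁷ pN·s/nm | accepted single-molecule value |
| Γ_needle | 1.9×10⁻⁴ | three orders of magnitude above γ |
| Γ_backbone | 100·γ·N | scale parameter; normalized results unchanged |
| d | 5.5 nm | actin monomer diameter ≈ observed step size |
| monomers/period | 6 (4 binding) | actin half-pitch steric geometry |
| ΔG | 8.2 pN·nm (2 kBT) | bias; the quantity the needle sweep estimates |
| B (single-molecule) | 41 pN·nm (10 kBT) | keeps the barrier transition below 1 ms |
| B (macroscopic) | calibrated, 12.78 pN·nm | see barrier reduction below |
| λ | 0.1 | transition state adjacent to the departing minimum |
| κ₊ / κ₋ | 0.3 / 0.03 pN/nm | classical cross-bridge stiffness; see below |
| f₁, δ_a | 6000 /s, d | sped-up search-and-catch (≈150× physiological) |
| g₁, g₂ | 150, 3000 /s | detachment ramp and fast negative-strain release |
| ΔG_ATP | 100 pN·nm (~25 kBT) | free energy routed through one cycle |
| dt | 7×10⁻¹¹ s | 1/100 of (λd)²/2D, the fastest timescale |

### Stiffness calibration

The stretched stiffness is a genuine calibration point.  The reduced
macroscopic barrier (below) bounds the holding force of a binding well
at (B_macro + ΔG)/((1−λ)d) ≈ 4.2 pN: an attached head pulled harder
than this simply slips backward well by well.  Search-and-catch at
window δ_a = d plus the in-well forward slide creates strains up to
≈ δ_a + (1−λ)d ≈ 10.5 nm, so coherence requires
κ₊ ≲ 4.2/10.5 ≈ 0.4 pN/nm.  We use κ₊ = 0.3 pN/nm — the classical
(lever-arm era) cross-bridge stiffness — with the 10:1 stretched/
compressed asymmetry of modern single-molecule measurements.  With the
stiffer modern κ₊ ≈ 2–3 pN/nm the same model requires a correspondingly
taller barrier (both are configurable); at the reduced barrier it
produces a collapsed isometric state, which is how the incoherence was
detected.  With 0.3 pN/nm the isometric ensemble holds a mean strain of
≈ +3.5 nm and the tension–length step response crosses zero near
−5 nm/half-sarcomere, both in the physiological range.

## Numerics

Euler–Maruyama with a single per-run RNG stream seeded from the master
seed (replicate seeds derive by counter through `SeedSequence`; every
output records its seed and resolved-config hash, and reruns are
bit-identical).  The step dt = 7×10⁻¹¹ s is 1/100 of the fastest
characteristic time, the diffusion time (λd)²/2D across the steep
barrier face; jump probabilities r·dt stay below 0.01 and flips are
per-step Bernoulli draws (rates depend on the continuously diffusing
position, so an exact-jump scheme would buy nothing).  At breakpoints of
the piecewise-linear landscape the forward-side segment supplies the
force (a measure-zero tie-break, fixed for determinism).

First-passage Monte Carlo against an absorbing boundary supplements the
endpoint test with a Brownian-bridge crossing probability
exp(−(ℓ−x₀)(ℓ−x₁)/(D·dt)), removing the leading O(√dt) bias from
crossings missed between samples; at dt = 1.4×10⁻¹¹ s the remaining
bias is below the Monte-Carlo resolution (~3%).  Dwell-time simulations
absorb at the adjacent minima positions, where the approach is steeply
downhill, and are unbiased at dt = 7×10⁻¹¹ within statistics.

The mean-exit-time quadrature oracle integrates
T′(x) = e^{U/kBT}(C − M(x)/D), M(x) = ∫ₐˣ e^{−U/kBT}, with C chosen for
a reflecting or absorbing left boundary — exact for any piecewise
landscape and entirely independent of the simulation path.

## Barrier reduction and time rescaling

Real-time protocols are unreachable at the single-molecule barrier, so
macroscopic runs reduce B until hopping is ≈150× faster, with the
attachment/detachment rates sped up in proportion.  The reduced barrier
is calibrated by root-solving the quadrature dwell time (escape from an
interior minimum to either neighbour): B_macro = 12.78 pN·nm (3.12 kBT)
gives a quadrature ratio of exactly 150, verified by direct Monte-Carlo
dwell simulation within statistics.  Observables reported "per unit
time" in this package are in simulation time; converting to real time
divides rates (and multiplies times) by the measured speed-up, the ratio
of simulated to physiological unloaded shortening velocity, as in the
rising-phase check.

## Protocols

Isometric: backbone held; tension rises to a plateau T0 (estimated as
the mean over the final third).  Length clamp: from the isometric state,
a step δ (negative = release) is applied as a linear backbone ramp.  The
ramp lasts 10⁻⁸ s — fast relative to the attached-state hopping time at
the reduced barrier (≈1.3×10⁻⁶ s), which is the property the
experimental "microsecond" step has relative to millisecond phase-2
recovery; a literal 100 µs ramp under the 150×-compressed kinetics
would complete after re-equilibration and erase the T1/T2 distinction.
T1 is the tangent-method extrapolation of the early recovery back to the
end of the ramp; T2 is the mean over the first rolling-slope-flat
plateau before the slow (attachment-driven) creep.  Force clamp: the
backbone obeys Γ_b·dZ/dt = T − β·T0.  Backbone thermal noise is omitted
(variance ∝ kBT/Γ_b, three orders below a head's; the stripped
backbone equation may or may not carry a noise term — this is our
documented choice).  Z increases during shortening; a length step δ
maps to ΔZ = −δ, which keeps the strain bookkeeping s = x − Z − c exact
and gives releases falling tension.

Anchors are stratified over one period, c_i = (i−½)L/N, honouring the
uniform coverage demanded by filament incommensurability without
O(1/√N) placement noise (uniform random placement is available by
flag).

## Single-molecule experiment

The head (permanently attached; rigor ignored) couples through a
symmetric spring κ_link = κ₊ to a needle with drag 10³γ held by
κ_trap = 0.1 pN/nm and loaded by a constant force.  Each run starts at
the highest minimum and stops when a lowest minimum is first captured —
the forward one three steps ahead, or the previous period's one step
behind; counting both exits keeps the ΔG = 0 null exact (zero net
crossing current at equilibrium).  Two step counts are kept: raw online
barrier crossings (which obey the exact bookkeeping identity
Nf − Nb = +3 or −1 per terminated run) and durable steps of the
median-filtered head record (window 2×10⁻⁵ s, between the fast
recrossing churn that occurs while the slow needle lags and the needle
relaxation time ≈5×10⁻⁴ s).  The durable counts are the reported
jump-ratio observable: the experimental analysis cannot see
sub-relaxation recrossings either.  The naive constant-force inversion
ΔG = kBT·ln(Nf/Nb) + F·d is kept for comparison; because the true
opposing force varies with the head position during a jump, it
systematically under-recovers the generating bias — the effect the
needle simulation exists to quantify.

## Efficiency bookkeeping

η_direct = βT0·V / (r·ΔG_ATP), with r the detachment (= ATP) rate over
the steady window.  The upper bound sums the energy injected by the
flashing at each ψ flip: η_max = βT0·V / Σⱼ(E_before − E_after)⁺ per
unit time, E the total motor energy (elastic + ψ·G_a) immediately
before/after the j-th jump.  The stripped formula's summand convention
is not recoverable, so both the positive-part and the net-sum variants
are implemented; positive-part is the default (it is the physical
injection and is never smaller, keeping the bound conservative).  The
energies are evaluated in the gauge with the first minimum at zero.

## Synthetic fixtures

The analysis layer is validated against closed-form traces before any
simulation output: staircases with known step times and directions
(step detector), single-exponential recoveries (T1 tangent method:
recovers the asymptote within (w/τ)²/6 for fit window w),
two-exponential transients with a known intermediate plateau (T2), and
linear shortening with known slope (velocity).  These fixtures emulate
shapes, not physics: passing them shows the extractors are correct, not
that the simulator is; the simulator-facing checks are the equilibrium
histogram, the first-passage oracles, the detailed-balance null and the
bookkeeping identities.

## Problem sizes

The test suite runs ensembles of N = 24 heads (12 for the
detailed-balance null), 3 replicates, 2 ms isometric rise and 0.5 ms
clamps per load — sizes at which the tested orderings resolve at three
standard errors; the normalized observables are N-independent (scale
invariance is itself tested at N = 12 vs 24).  The acceptance script
uses ≥250 dwell escapes per barrier.  Dwell and first-passage statistics
use hundreds of escapes; quoted tolerances are 3 standard errors of the
estimator unless a closed form allows 1–2%.

## Known limitations

One-dimensional geometry: no actin helix, no lever-arm azimuth, no
tendon or inter-sarcomere compliance, no activation latency.  Two
chemical states only — the weakly-bound, non-force-generating state is
absent, which depresses the direct efficiency relative to the bound.
The attachment/detachment rates remain phenomenological (the
diffusional treatment applies only to the attached landscape).
Isometric occupancy at λ = 0.1 concentrates in the two deepest minima
rather than the central ones, a consequence of the forward in-well
slide after attachment; the unloaded-shortening redistribution toward
the lowest minimum is reproduced.  Direct efficiencies at the default
parameters are of order a few per cent: the ordering
η_direct ≤ η_bound ≤ 1 and the power-curve shape are robust, but the
absolute scale is parameter-sensitive (it grows with the
ΔG_ATP-normalized work per cycle and shrinks with the g₂-driven futile
cycling this two-state reduction overproduces).  At the default free
rate parameters the force–velocity curve crosses zero velocity slightly
below β = 1: velocities at the isometric load are small and negative
within trial scatter, so the stall check is a statistical null rather
than an exact crossing.
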