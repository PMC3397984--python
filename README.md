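# myoratchet

A flashing Brownian-ratchet simulator of the actomyosin cross-bridge
cycle, for muscle biophysicists who want macroscopic fiber behaviour —
tension transients, force–velocity curves, motor strain statistics,
contraction efficiency — generated from single-molecule-level dynamics
rather than fitted rate functions.

## Model

Each myosin head is an overdamped Brownian particle (drag γ, thermal
energy kBT) coupled to the thick-filament backbone by an asymmetric
elastic element (stiffness κ₊ stretched, κ₋ compressed).  A two-valued
jump process ψ ∈ {0, 1} switches the actomyosin interaction on and off:

  γ ẋᵢ = −ψᵢ ∂ₓG_a(xᵢ) − κ(sᵢ)·sᵢ + ξᵢ(t),   sᵢ = xᵢ − (Z + cᵢ)

with ⟨ξ⟩ = 0, ⟨ξ(t)ξ(t′)⟩ = 2kBTγ·δ(t−t′).  The attached-state
landscape G_a is piecewise linear and periodic (period L = 6d): four
binding minima per period descending by the bias ΔG, two sterically
forbidden monomers over which the landscape returns, so G_a is flat on
average and directed motion requires the jump process to break detailed
balance — attachment by Brownian search-and-catch (rate f₁ only while
the element is stretched forward by 0 < s ≤ δ_a over a permitted
monomer), detachment with the classical 1957 strain dependence (g₂ at
negative strain, g₁·min(s/δ_a, 1) above).  Half-sarcomere tension is
T = Σᵢ κ(sᵢ)·sᵢ; the backbone is held (isometric), ramped (length
clamp) or force-balanced (force clamp, Γ_b Ż = T − βT₀).

A single-molecule mode reproduces the micro-needle experiment: one
permanently attached head coupled through a symmetric spring to a
needle with drag 10³γ, used to estimate ΔG from the ratio of forward to
backward jumps under load.  An exact mean-first-passage quadrature
calibrates the reduced barrier that makes macroscopic runs affordable
(dwell times ≈150× shorter than at the single-molecule barrier).
Efficiency is measured directly (βT₀V / ATP energy flux) and bounded
from the energy injected at every potential on/off switch.

See `docs/methods.md` for assumptions, parameter defaults, units and
numerical choices.

## Worked example

Calibrate the reduced barrier, rise to the isometric state, then clamp
at 60 % of the isometric tension:

```sh
$ myoratchet calibrate-barrier --seed 1 --out results/
B_macro = 12.7759 pN nm (3.116 kBT)

$ myoratchet isometric --seed 7 --duration 2e-3 --out results/ \
    --barrier 12.7759
trial 0: T0 = 13.24 pN

$ myoratchet force-clamp --beta 0.6 --seed 7 --pre 2e-3 \
    --duration 5e-4 --barrier 12.7759 --out results/
trial 0: v = 3367 nm/s, attached = 22.3, atp = 2e+04/s
```

The first command root-solves the barrier height whose quadrature dwell
time is 150-fold shorter than at the 10 kBT single-molecule barrier.
The second rises a 64-head half-sarcomere from fully detached to its
isometric plateau and reports T0, the mean tension over the final third.
The third continues into an isotonic clamp: `v` is the per-half-
sarcomere shortening velocity from the linear portion of the backbone
trace (positive = shortening — at β = 1 it is statistically zero, above
it negative), `attached` the mean bound-head count and `atp` the
detachment rate, one ATP per cycle.  Traces land in `results/*.tsv`
(with event logs carrying per-jump energies) and every run appends its
seed, resolved parameters and config hash to `results/run.log.jsonl`;
reruns with the same seed are byte-identical.  Values above are from
`--seed 7` on the defaults; velocities are in simulation time (the
methods note describes the real-time rescaling).

Single-molecule bias sweep (the ratio of forward to backward jumps vs
load, per candidate ΔG, with exponential fits):

```sh
myoratchet sme-sweep --seed 3 --runs 20 --out results/
```

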