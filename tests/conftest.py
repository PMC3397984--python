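"""Shared fixtures.

The expensive ensemble and single-molecule simulations are session-scoped
and shared across test modules; problem sizes (N, durations, trial and
run counts) are chosen so the full suite exercises every protocol at
statistically useful size.
"""

from __future__ import annotations

import numpy as np
import pytest

import myoratchet as mr
from myoratchet.sme_experiment import _run_batch

# reference single-molecule potential (the geometry the bias calibration
# and the dwell-time machinery are defined on)
REF = dict(d=5.5, deltaG=8.2, barrier=41.0, asymmetry_lambda=0.1)

# ensemble problem sizes used throughout the suite; the moderate loads
# carry the efficiency measurements and get longer steady windows
N_ENSEMBLE = 24
T_ISO = 2.0e-3
T_CLAMP = {0.0: 4.0e-4, 0.3: 1.2e-3, 0.6: 1.2e-3, 1.0: 4.0e-4, 2.5: 4.0e-4}
N_TRIALS = 3
BETAS = (0.0, 0.3, 0.6, 1.0, 2.5)


@pytest.fixture(scope="session")
def env() -> mr.PhysicalEnv:
    return mr.PhysicalEnv()


@pytest.fixture(scope="session")
def ref_spec() -> mr.PotentialSpec:
    return mr.PotentialSpec(**REF)


@pytest.fixture(scope="session")
def ref_pot(ref_spec) -> mr.PiecewisePotential:
    return mr.build_potential(ref_spec)


@pytest.fixture(scope="session")
def elastic() -> mr.ElasticSpec:
    return mr.ElasticSpec()


@pytest.fixture(scope="session")
def rates() -> mr.RateSpec:
    return mr.RateSpec()


@pytest.fixture(scope="session")
def macro_barrier(env, ref_spec) -> float:
    """Reduced barrier calibrated to the 150x dwell-time target."""
    return mr.calibrate_reduced_barrier(env, ref_spec, 150.0)


@pytest.fixture(scope="session")
def macro_spec(ref_spec, macro_barrier) -> mr.PotentialSpec:
    return ref_spec.replace(barrier=macro_barrier)


@pytest.fixture(scope="session")
def macro_pot(macro_spec) -> mr.PiecewisePotential:
    return mr.build_potential(macro_spec)


@pytest.fixture(scope="session")
def macro_runs(env, macro_spec, macro_pot, elastic, rates):
    """Isometric pre-equilibrations plus force clamps over the load grid.

    N_TRIALS independent half-sarcomeres are risen to the isometric
    steady state; each is then clamped at every beta in BETAS starting
    from its isometric end state.  Returns a dict with per-trial
    isometric traces, T0 estimates, and {beta: [traces]}.
    """
    integ = mr.IntegratorSpec(dt=7e-11, seed=0, record_stride=500)
    iso_traces, T0s, end_states = [], [], []
    for trial in range(N_TRIALS):
        state = mr.init_ensemble(N_ENSEMBLE, macro_spec.period, seed=trial)
        tr = mr.run_isometric(
            state, env, macro_pot, macro_spec, elastic, rates, integ,
            duration=T_ISO, seed=1000 + trial,
        )
        iso_traces.append(tr)
        T0s.append(mr.estimate_T0(tr))
        end_states.append(state)
    clamps: dict[float, list] = {}
    for beta in BETAS:
        clamps[beta] = []
        for trial in range(N_TRIALS):
            st = end_states[trial].copy()
            tr = mr.run_force_clamp(
                st, env, macro_pot, macro_spec, elastic, rates, integ,
                beta=beta, T0=T0s[trial], duration=T_CLAMP[beta],
                seed=int(2000 + 100 * beta + trial),
            )
            clamps[beta].append(tr)
    return {
        "isometric": iso_traces,
        "T0": T0s,
        "states": end_states,
        "clamps": clamps,
        "N": N_ENSEMBLE,
    }


@pytest.fixture(scope="session")
def length_clamp_runs(env, macro_spec, macro_pot, elastic, rates, macro_runs):
    """Release steps applied to copies of the isometric end states."""
    integ = mr.IntegratorSpec(dt=7e-11, seed=0, record_stride=500)
    out = {}
    for delta in (-1.0, -2.0):
        traces = []
        for trial, state in enumerate(macro_runs["states"]):
            st = state.copy()
            tr = mr.run_length_clamp(
                st, env, macro_pot, macro_spec, elastic, rates, integ,
                delta=delta, t_step=2e-6, duration=4e-5,
                seed=int(3000 + 10 * abs(delta) + trial),
            )
            traces.append(tr)
        out[delta] = traces
    return out


@pytest.fixture(scope="session")
def stationary_null_runs(env):
    """Fixed-duration equilibrium runs on the unbiased symmetric landscape.

    deltaG = 0, lambda = 0.5: the landscape (including the inter-region
    span) is mirror-symmetric, so over stationary non-terminated runs
    forward and backward crossings balance exactly in expectation.  The
    barrier is low so crossings are plentiful.
    """
    pot = mr.build_potential(mr.PotentialSpec(
        deltaG=0.0, barrier=3 * mr.PhysicalEnv().kBT, asymmetry_lambda=0.5))
    seeds = np.random.SeedSequence(55).generate_state(40) % (2**31)
    return _run_batch(env, pot, mr.NeedleSpec(), 7e-11, 0.0, 40, seeds,
                      1.2e-3, terminate_at_lowest=False, count_burn_in=2e-4)


@pytest.fixture(scope="session")
def sme_sweep_runs(env, ref_spec):
    """Raw SME run batches over the (deltaG, F) grid, plus a synthetic
    'experimental' batch generated at a known bias for the recovery test."""
    needle = mr.NeedleSpec()
    grid_dG = (4.1, 8.2, 12.3)
    grid_F = (0.0, 1.0)
    n_runs = 15
    max_dur = 5e-3
    out: dict = {"grid_dG": grid_dG, "grid_F": grid_F, "runs": {}}
    ss = np.random.SeedSequence(77)
    seeds = ss.generate_state(len(grid_dG) * len(grid_F) * n_runs) % (2**31)
    seeds = seeds.reshape(len(grid_dG), len(grid_F), n_runs)
    for i, dG in enumerate(grid_dG):
        pot = mr.build_potential(ref_spec.replace(deltaG=dG))
        for j, F in enumerate(grid_F):
            out["runs"][(dG, F)] = _run_batch(
                env, pot, needle, 7e-11, F, n_runs, seeds[i, j], max_dur
            )
    # synthetic observation at the true bias 8.2, fresh seeds
    obs_seeds = np.random.SeedSequence(991).generate_state(
        len(grid_F) * n_runs) % (2**31)
    obs_seeds = obs_seeds.reshape(len(grid_F), n_runs)
    pot = mr.build_potential(ref_spec.replace(deltaG=8.2))
    out["observed"] = {
        F: _run_batch(env, pot, needle, 7e-11, F, n_runs, obs_seeds[j], max_dur)
        for j, F in enumerate(grid_F)
    }
    return out
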