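"""Langevin integrator, jump process, first-passage machinery."""

import numpy as np
import pytest
from scipy import stats

import myoratchet as mr
from myoratchet.model_core import ConfigurationError, MotorState


class TestLangevinStep:
    def test_zero_force_zero_noise_is_identity(self, env):
        assert mr.langevin_step(1.23, 0.0, env, 1e-10, 0.0) == pytest.approx(1.23)

    def test_deterministic_drift(self, env):
        x1 = mr.langevin_step(0.0, 10.0, env, 2e-10, 0.0)
        assert x1 == pytest.approx(10.0 * 2e-10 / env.gamma_head)

    def test_free_diffusion_msd(self, env):
        # ensemble MSD after k steps: 2 D t within 3 standard errors
        rng = np.random.default_rng(3)
        n, k, dt = 10_000, 50, 1e-10
        x = np.zeros(n)
        for _ in range(k):
            x = mr.langevin_step(x, 0.0, env, dt, rng.standard_normal(n))
        msd = np.mean(x**2)
        expected = 2 * env.D_head * k * dt
        se = np.std(x**2) / np.sqrt(n)
        assert abs(msd - expected) < 3 * se


class TestRates:
    def test_attach_needs_forward_stretch_and_allowed_site(self, ref_spec):
        rs = mr.RateSpec()
        assert mr.attach_rate(rs, -1.0, 2 * 5.5, ref_spec) == 0.0
        assert mr.attach_rate(rs, rs.attach_window / 2, 2 * 5.5, ref_spec) == rs.f1
        # forbidden monomer: no catch even when stretched
        assert mr.attach_rate(rs, rs.attach_window / 2, 5 * 5.5, ref_spec) == 0.0
        # beyond the search window: no catch
        assert mr.attach_rate(rs, rs.attach_window * 1.01, 2 * 5.5, ref_spec) == 0.0

    def test_detach_huxley_shape(self):
        rs = mr.RateSpec(g1=150.0, g2=3000.0, attach_window=5.5)
        assert mr.detach_rate(rs, -0.5) == 3000.0
        assert mr.detach_rate(rs, 1e-9) == pytest.approx(0.0, abs=1e-3)
        assert mr.detach_rate(rs, 5.5) == 150.0
        assert mr.detach_rate(rs, 11.0) == 150.0  # capped
        assert mr.detach_rate(rs, 2.75) == pytest.approx(75.0)

    def test_rate_spec_invariants(self):
        with pytest.raises(ConfigurationError):
            mr.RateSpec(g1=100.0, g2=50.0)


class TestJumpUpdate:
    def test_zero_rate_no_event(self):
        s = MotorState(x=1.0, psi=0)
        s2, ev = mr.jump_update(s, (0.0, 0.0), 1e-10, 0.5)
        assert s2 is s and ev is None

    def test_detach_consumes_one_atp(self, ref_pot):
        el = mr.ElasticSpec()
        s = MotorState(x=5.5, psi=1)
        s2, ev = mr.jump_update(
            s, (0.0, 100.0), 1e-4, 0.0, pot=ref_pot, el=el, anchor=3.0
        )
        assert s2.psi == 0 and s2.atp_used == 1
        assert ev.kind == "detach"
        # detaching switches the potential off: E_after = elastic only
        assert ev.E_before - ev.E_after == pytest.approx(
            mr.potential_energy(ref_pot, 5.5)
        )

    def test_flip_fraction_matches_bernoulli_probability(self):
        rng = np.random.default_rng(11)
        r, dt, n = 50.0, 1e-4, 100_000
        flips = sum(
            mr.jump_update(MotorState(x=0.0, psi=0), (r, 0.0), dt, u)[1] is not None
            for u in rng.random(n)
        )
        p = r * dt
        se = np.sqrt(p * (1 - p) / n)
        assert abs(flips / n - p) < 3 * se

    def test_rate_dt_contract_enforced(self):
        with pytest.raises(ConfigurationError):
            mr.jump_update(MotorState(x=0.0, psi=0), (1e9, 0.0), 1e-10, 0.5)


class TestIntegratorSpec:
    def test_dt_limit_from_steep_face(self, env, ref_spec, elastic):
        with pytest.raises(ConfigurationError):
            mr.IntegratorSpec(dt=1e-9).validate_against(env, ref_spec, elastic)
        mr.IntegratorSpec(dt=7e-11).validate_against(env, ref_spec, elastic)

    def test_rate_dt_limit(self, env, ref_spec, elastic):
        with pytest.raises(ConfigurationError):
            mr.IntegratorSpec(dt=7e-11).validate_against(
                env, ref_spec, elastic, mr.RateSpec(f1=5e8)
            )


class TestMfptClosedForm:
    def test_diffusive_limit(self, env):
        ell = 1.0
        tau0 = mr.mfpt_closed_form(ell, 0.0, env.D_head, env.kBT)
        assert tau0 == pytest.approx(ell**2 / (2 * env.D_head), rel=1e-9)

    def test_monotone_in_force(self, env):
        taus = [
            mr.mfpt_closed_form(0.55, F, env.D_head, env.kBT)
            for F in np.linspace(0.0, 80.0, 9)
        ]
        assert np.all(np.diff(taus) > 0)

    def test_matches_quadrature_on_linear_ramp(self, env):
        # the reference single-molecule climb: 0.55 nm against 74.5 pN
        ell, F = 0.55, 41.0 / 0.55
        cf = mr.mfpt_closed_form(ell, F, env.D_head, env.kBT)
        qd = mr.mfpt_quadrature(
            lambda x: F * x, 0.0, ell, 0.0, env.D_head, env.kBT, left="reflecting"
        )
        assert qd == pytest.approx(cf, rel=1e-3)

    def test_quadrature_two_absorbing_symmetric(self, env):
        # flat potential, absorbing at both ends, start in the middle:
        # T = (b-a)^2/8D... classical result T(x0) = (x0-a)(b-x0)/(2D)
        a, b = 0.0, 2.0
        tau = mr.mfpt_quadrature(
            lambda x: np.zeros_like(x), a, b, 1.0, env.D_head, env.kBT,
            left="absorbing",
        )
        assert tau == pytest.approx(1.0 * 1.0 / (2 * env.D_head), rel=1e-4)


class TestSimulateMotor:
    def test_duration_zero_empty_trace(self, env, ref_pot):
        integ = mr.IntegratorSpec(dt=7e-11, seed=1)
        tr = mr.simulate_motor(env, ref_pot, None, None, integ, duration=0.0)
        assert len(tr) == 0

    def test_identical_seeds_bitwise_identical(self, env, ref_pot):
        integ = mr.IntegratorSpec(dt=7e-11, seed=123, record_stride=50)
        t1 = mr.simulate_motor(env, ref_pot, None, None, integ, duration=2e-7)
        t2 = mr.simulate_motor(env, ref_pot, None, None, integ, duration=2e-7)
        np.testing.assert_array_equal(t1["x_nm"], t2["x_nm"])

    def test_single_well_histogram_matches_boltzmann(self, env, ref_pot):
        # reflecting walls at the maxima flanking the second minimum;
        # stationary histogram vs the Boltzmann density oracle (KS < 0.02)
        integ = mr.IntegratorSpec(dt=7e-11, seed=42, record_stride=100)
        dom = (0.55, 6.05)
        tr = mr.simulate_motor(
            env, ref_pot, None, None, integ, duration=1.2e-3,
            x0=5.5, psi0=1, domain=dom,
        )
        xs = tr["x_nm"][2000:]
        g, rho = mr.boltzmann_density(ref_pot, env.kBT, dom, 20001)
        cdf = np.concatenate(
            [[0.0], np.cumsum((rho[1:] + rho[:-1]) / 2 * np.diff(g))]
        )
        cdf /= cdf[-1]
        ks = stats.kstest(xs, lambda v: np.interp(v, g, cdf)).statistic
        assert len(xs) >= 1e4
        assert ks < 0.02

    def test_atp_count_equals_detach_events(self, env, macro_pot, macro_spec,
                                            elastic):
        rates = mr.RateSpec()
        integ = mr.IntegratorSpec(dt=7e-11, seed=5, record_stride=1000)
        tr = mr.simulate_motor(
            env, macro_pot, elastic, rates, integ, duration=2e-4,
            x0=2.0, psi0=0, anchor=0.0, pspec=macro_spec,
        )
        n_detach = int((tr.events["kind"] == "detach").sum())
        assert tr.meta["atp_used"] == n_detach


class TestDwellTimes:
    def test_mean_dwell_positive_and_matches_quadrature(self, env, macro_pot):
        tau_q = mr.dwell_time_quadrature(env, macro_pot)
        m, se = mr.mean_dwell_time(
            env, macro_pot, mr.IntegratorSpec(dt=7e-11, seed=9), n_escapes=400
        )
        assert m > 0
        assert abs(m - tau_q) < 3 * se

    def test_dwell_scales_with_drag(self, env, macro_pot):
        # doubling gamma doubles the mean dwell time (time rescaling)
        m1, se1 = mr.mean_dwell_time(
            env, macro_pot, mr.IntegratorSpec(dt=7e-11, seed=21), n_escapes=300
        )
        env2 = mr.PhysicalEnv(gamma_head=2 * env.gamma_head)
        m2, se2 = mr.mean_dwell_time(
            env2, macro_pot, mr.IntegratorSpec(dt=1.4e-10, seed=22), n_escapes=300
        )
        se = np.sqrt((2 * se1) ** 2 + se2**2)
        assert abs(m2 - 2 * m1) < 3 * se


class TestBarrierCalibration:
    def test_identity_at_ratio_one(self, env, ref_spec):
        assert mr.calibrate_reduced_barrier(env, ref_spec, 1.0) == ref_spec.barrier

    def test_reduced_barrier_below_reference(self, env, ref_spec, macro_barrier):
        assert ref_spec.deltaG < macro_barrier < ref_spec.barrier

    def test_quadrature_ratio_hits_target(self, env, ref_spec, macro_barrier):
        tau_ref = mr.dwell_time_quadrature(env, mr.build_potential(ref_spec))
        tau_mac = mr.dwell_time_quadrature(
            env, mr.build_potential(ref_spec.replace(barrier=macro_barrier))
        )
        assert tau_ref / tau_mac == pytest.approx(150.0, rel=0.01)
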