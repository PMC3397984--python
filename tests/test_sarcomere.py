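"""Half-sarcomere ensemble: initialization, protocols, bookkeeping."""

import numpy as np
import pytest

import myoratchet as mr
from myoratchet.observables import steady_window
from myoratchet.sarcomere_ensemble import ProtocolSpec, summarize_trials


class TestInitEnsemble:
    def test_stratified_offsets(self):
        st = mr.init_ensemble(4, 33.0, seed=0)
        np.testing.assert_allclose(st.c, [4.125, 12.375, 20.625, 28.875])

    def test_initially_detached_zero_tension(self, elastic):
        st = mr.init_ensemble(8, 33.0, seed=0)
        assert st.psi.sum() == 0
        assert st.tension(elastic) == 0.0
        np.testing.assert_allclose(st.strains, 0.0)

    def test_random_placement_covers_period(self):
        st = mr.init_ensemble(256, 33.0, seed=3, random_placement=True)
        assert st.c.min() >= 0.0 and st.c.max() < 33.0
        # roughly uniform: each third holds a third of anchors
        hist, _ = np.histogram(st.c, bins=3, range=(0, 33.0))
        assert hist.min() > 256 / 3 - 4 * np.sqrt(256 / 3)

    def test_protocol_spec_validation(self):
        with pytest.raises(Exception):
            ProtocolSpec(kind="force_clamp", duration=1e-3, beta=3.0)
        with pytest.raises(Exception):
            ProtocolSpec(kind="bogus", duration=1e-3)


class TestIsometric:
    def test_all_rates_zero_tension_stays_zero(self, env, macro_pot, macro_spec,
                                               elastic):
        st = mr.init_ensemble(8, macro_spec.period, seed=0)
        rates = mr.RateSpec(f1=0.0, g1=0.0, g2=0.0)
        integ = mr.IntegratorSpec(dt=7e-11, seed=2, record_stride=500)
        tr = mr.run_isometric(st, env, macro_pot, macro_spec, elastic, rates,
                              integ, duration=5e-6)
        assert int(tr["n_attached"].max()) == 0
        # detached heads fluctuate around their anchors: tension noise only
        assert abs(tr["tension_pN"].mean()) < 3 * tr["tension_pN"].std()

    def test_rising_phase_reaches_plateau(self, macro_runs):
        # smoothed tension rises from ~0 to a plateau; the final-third
        # slope is consistent with zero across trials
        late_slopes = []
        for tr in macro_runs["isometric"]:
            n = len(tr)
            early = tr["tension_pN"][: n // 10].mean()
            late = tr["tension_pN"][-n // 3:].mean()
            assert late > early  # rose
            t_late = tr.t[-n // 3:]
            y_late = tr["tension_pN"][-n // 3:]
            late_slopes.append(np.polyfit(t_late, y_late, 1)[0] * (t_late[-1] - t_late[0]))
        m, sd = summarize_trials(late_slopes)
        se = sd / np.sqrt(len(late_slopes))
        assert abs(m) < max(3 * se, 0.5 * np.mean(macro_runs["T0"]))

    def test_T0_consistent_across_seeds(self, macro_runs):
        T0s = macro_runs["T0"]
        m, sd = summarize_trials(T0s)
        assert m > 0
        # trials are replicates of the same steady state
        assert sd < m  # scatter below the mean: a real plateau, not noise

    def test_tension_additivity_at_end_state(self, macro_runs, elastic):
        # the recorded tension at the final sample equals the sum of
        # elastic forces recomputed from the final state
        for tr, state in zip(macro_runs["isometric"], macro_runs["states"]):
            assert tr["tension_pN"][-1] == pytest.approx(
                state.tension(elastic), rel=1e-9, abs=1e-9
            )

    def test_atp_bookkeeping_exact(self, macro_runs):
        for tr, state in zip(macro_runs["isometric"], macro_runs["states"]):
            n_detach = int((tr.events["kind"] == "detach").sum())
            assert int(tr["atp_cum"][-1]) == n_detach
            assert int(state.atp.sum()) == n_detach

    def test_no_attachment_in_forbidden_region(self, macro_runs, macro_spec):
        # run-time check of the steric constraint on every attach event
        for traces in ([*macro_runs["isometric"]]
                       + [t for v in macro_runs["clamps"].values() for t in v]):
            ev = traces.events
            att = ev[ev["kind"] == "attach"]
            if len(att):
                assert mr.attachment_allowed(
                    macro_spec, att["x_nm"].to_numpy()
                ).all()


class TestLengthClamp:
    def test_release_drops_tension_then_recovers(self, length_clamp_runs,
                                                 macro_runs):
        T0s = macro_runs["T0"]
        for delta in (-1.0, -2.0):
            t1s, t2s = [], []
            for tr in length_clamp_runs[delta]:
                ramp = tr.meta["ramp_duration_s"]
                t1s.append(mr.extract_T1(tr, tr.meta["t_step_s"], ramp))
                t2s.append(mr.extract_T2(tr, tr.meta["t_step_s"], ramp,
                                         search_start=4e-6, search_end=3.5e-5))
            T0, T1, T2 = np.mean(T0s), np.mean(t1s), np.mean(t2s)
            se = np.std(t1s, ddof=1) / np.sqrt(len(t1s)) + \
                np.std(t2s, ddof=1) / np.sqrt(len(t2s))
            assert T1 < T2 + 3 * se  # elastic drop below re-equilibrated
            assert T1 < T0  # instantaneous drop for a release
            assert T2 < T0 + 3 * se + 0.3 * T0  # plateau at/below isometric

    def test_T1_steeper_than_T2_in_delta(self, length_clamp_runs):
        # the elastic T1(delta) falls faster with release size than the
        # re-equilibrated T2(delta)
        t1, t2 = {}, {}
        for delta in (-1.0, -2.0):
            t1[delta] = np.mean([
                mr.extract_T1(tr, tr.meta["t_step_s"], tr.meta["ramp_duration_s"])
                for tr in length_clamp_runs[delta]
            ])
            t2[delta] = np.mean([
                mr.extract_T2(tr, tr.meta["t_step_s"], tr.meta["ramp_duration_s"],
                              search_start=4e-6, search_end=3.5e-5)
                for tr in length_clamp_runs[delta]
            ])
        assert (t1[-1.0] - t1[-2.0]) > (t2[-1.0] - t2[-2.0])

    def test_elastic_prediction_on_frozen_state(self, elastic):
        # with kinetics and hopping frozen, a step changes tension by
        # delta x sum of attached stiffnesses (strains keep their sign)
        strains = np.array([1.0, 2.0, 3.0, 1.5])
        st = mr.init_ensemble(4, 33.0, seed=0)
        st.x = st.c + strains
        st.psi[:] = 1
        T_before = st.tension(elastic)
        delta = -0.2
        st.Z -= delta  # a release shifts the backbone forward
        predicted = T_before + delta * 4 * elastic.kappa_plus
        assert st.tension(elastic) == pytest.approx(predicted, rel=1e-12)


class TestForceClamp:
    def test_unloaded_shortens_forward(self, macro_runs):
        vels = [mr.extract_velocity(
            _sub(tr, steady_window(tr, 0.6)), r2_min=0.0)
            for tr in macro_runs["clamps"][0.0]]
        m = np.mean(vels)
        se = np.std(vels, ddof=1) / np.sqrt(len(vels))
        assert m > 3 * se  # forward shortening at zero load

    def test_stall_at_isometric_load(self, macro_runs):
        vels = [mr.extract_velocity(
            _sub(tr, steady_window(tr, 0.6)), r2_min=0.0)
            for tr in macro_runs["clamps"][1.0]]
        v0 = np.mean([mr.extract_velocity(
            _sub(tr, steady_window(tr, 0.6)), r2_min=0.0)
            for tr in macro_runs["clamps"][0.0]])
        m = np.mean(vels)
        se = max(np.std(vels, ddof=1) / np.sqrt(len(vels)), 0.02 * abs(v0))
        assert abs(m) < 3 * se

    def test_eccentric_load_lengthens(self, macro_runs):
        vels = [mr.extract_velocity(
            _sub(tr, steady_window(tr, 0.6)), r2_min=0.0)
            for tr in macro_runs["clamps"][2.5]]
        se = np.std(vels, ddof=1) / np.sqrt(len(vels))
        assert np.mean(vels) < 3 * se  # non-positive velocity

    def test_scale_invariance_attached_fraction(self, env, macro_spec,
                                                macro_pot, elastic, rates,
                                                macro_runs):
        # normalized observables are unchanged when N changes (N is a
        # scale parameter): compare attached fraction at N=12 vs N=24
        integ = mr.IntegratorSpec(dt=7e-11, seed=31, record_stride=500)
        fracs_small = []
        for trial in range(2):
            st = mr.init_ensemble(12, macro_spec.period, seed=50 + trial)
            tr = mr.run_isometric(st, env, macro_pot, macro_spec, elastic,
                                  rates, integ, duration=1.5e-3,
                                  seed=60 + trial)
            n = len(tr)
            fracs_small.append(tr["n_attached"][-n // 3:].mean() / 12)
        big = [tr["n_attached"][-len(tr) // 3:].mean() / macro_runs["N"]
               for tr in macro_runs["isometric"]]
        m1, m2 = np.mean(fracs_small), np.mean(big)
        se = np.sqrt(np.std(fracs_small, ddof=1) ** 2 / 2
                     + np.std(big, ddof=1) ** 2 / len(big)) + 1e-3
        assert abs(m1 - m2) < 3 * se


class TestMicroObservables:
    def test_occupancy_redistribution_under_load(self, macro_runs):
        # isometric: attached heads spread over all four binding minima;
        # early unloaded shortening: the lowest minimum is the most
        # populated as heads pile forward before detaching at the gap
        iso_occ = np.zeros(4)
        for tr in macro_runs["isometric"]:
            w = steady_window(tr, 0.3)
            iso_occ += [tr[f"occupancy_m{k + 1}"][w].sum() for k in range(4)]
        iso_occ /= iso_occ.sum()
        assert (iso_occ > 0.01).all()
        un_occ = np.zeros(4)
        for tr in macro_runs["clamps"][0.0]:
            w = (tr.t > 2e-6) & (tr.t < 3e-5)
            un_occ += [tr[f"occupancy_m{k + 1}"][w].sum() for k in range(4)]
        un_occ /= un_occ.sum()
        assert np.argmax(un_occ) == 3

    def test_mean_strain_drops_from_isometric_to_unloaded(self, macro_runs):
        # the ratchet lags the backbone during rapid shortening, so the
        # mean strain of attached heads falls below its isometric value
        def strain(traces, frac):
            s = n = 0.0
            for tr in traces:
                w = steady_window(tr, frac)
                s += tr["strain_sum_nm"][w].sum()
                n += tr["n_attached"][w].sum()
            return s / n

        iso = strain(macro_runs["isometric"], 0.3)
        un = strain(macro_runs["clamps"][0.0], 0.5)
        assert un < iso


class TestRunProtocol:
    def test_single_trial_and_determinism(self, env, macro_spec, macro_pot,
                                          elastic, rates):
        integ = mr.IntegratorSpec(dt=7e-11, seed=0, record_stride=2000)
        proto = ProtocolSpec(kind="isometric", duration=2e-5, n_trials=1)
        a = mr.run_protocol(proto, env, macro_spec, macro_pot, elastic, rates,
                            integ, master_seed=42, N=6)
        b = mr.run_protocol(proto, env, macro_spec, macro_pot, elastic, rates,
                            integ, master_seed=42, N=6)
        assert len(a) == 1
        np.testing.assert_array_equal(a[0]["tension_pN"], b[0]["tension_pN"])

    def test_replicates_differ_and_summarize(self, env, macro_spec, macro_pot,
                                             elastic, rates):
        integ = mr.IntegratorSpec(dt=7e-11, seed=0, record_stride=2000)
        proto = ProtocolSpec(kind="isometric", duration=2e-5, n_trials=3)
        traces = mr.run_protocol(proto, env, macro_spec, macro_pot, elastic,
                                 rates, integ, master_seed=7, N=6)
        assert len(traces) == 3
        finals = [tr["tension_pN"][-1] for tr in traces]
        assert len(set(np.round(finals, 12))) > 1
        m, sd = summarize_trials(finals)
        assert sd >= 0.0


def _sub(tr, mask):
    from myoratchet.trace import Trace

    return Trace(t=tr.t[mask], data={k: v[mask] for k, v in tr.data.items()},
                 events=tr.events, meta=tr.meta)
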