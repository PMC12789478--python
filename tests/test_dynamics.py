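"""Integration of the community ODEs: RHS terms, schedules, steady states."""

import numpy as np
import pytest

import gutswitch as gs
from gutswitch.community import (CommunityModel, Environment, Metabolite,
                                 PHModel, Subpopulation, default_config)
from gutswitch.dynamics import MixEvent, Segment, compile_model, resolve_env


def single_consumer_model(mu_max=0.3, vmax=1e-4, km=0.5, dilution=0.05):
    """One species growing on one substrate; no transitions."""
    return CommunityModel(
        metabolites=[Metabolite("S", feed_conc=5.0, init_conc=5.0)],
        subpopulations=[Subpopulation(id="x", species="sp", mu_max=mu_max,
                                      uptake={"S": (vmax, km)},
                                      ph_opt=0.0, ph_steep=1.0)],
        transitions=[],
        ph_model=PHModel(mode="fixed", fixed_value=6.4, acid_coeffs={}),
        environment=Environment(dilution=dilution, feed={"S": 5.0}),
    )


class TestRhs:
    def test_abiotic_chemostat(self, default_model):
        """With zero biomass, metabolites relax toward feed at rate D and
        cell derivatives vanish."""
        m = default_model.copy()
        m.environment.dilution = 0.1
        state = gs.CommunityState(cells={s: 0.0 for s in m.sub_ids},
                                  mets={n: 1.0 for n in m.met_names})
        dy = gs.rhs(state, model=m)
        feed = m.feed_vector()
        np.testing.assert_allclose(dy[:m.n_met], 0.1 * (feed - 1.0), atol=1e-14)
        np.testing.assert_allclose(dy[m.n_met:], 0.0, atol=1e-14)

    def test_closed_abiotic_system_is_static(self, default_model):
        m = default_model.copy()
        m.environment.dilution = 0.0
        state = gs.CommunityState(cells={s: 0.0 for s in m.sub_ids},
                                  mets={n: 2.0 for n in m.met_names})
        np.testing.assert_allclose(gs.rhs(state, model=m), 0.0, atol=1e-14)

    def test_hand_computed_monod_terms(self):
        m = single_consumer_model()
        state = gs.CommunityState(cells={"x": 1000.0}, mets={"S": 2.0})
        dy = gs.rhs(state, model=m)
        phf = 1.0 / (1.0 + np.exp(-6.4))           # ph_opt=0, steep=1, pH 6.4
        mu = 0.3 * phf * (2.0 / 2.5)
        dS = 0.05 * (5.0 - 2.0) - 1e-4 * (2.0 / 2.5) * 1000.0
        dX = (mu - 0.05) * 1000.0
        assert dy[0] == pytest.approx(dS, abs=1e-12)
        assert dy[1] == pytest.approx(dX, abs=1e-9)

    def test_rejects_non_finite_state(self, default_model):
        state = default_model.default_init()
        state.mets["glucose"] = float("nan")
        with pytest.raises(ValueError):
            gs.rhs(state, model=default_model)


class TestSimulate:
    def test_baseline_schedule_is_identity(self, default_model):
        times = np.linspace(0.0, 24.0, 49)
        plain = gs.simulate(default_model, times=times)
        sched = gs.PerturbationSchedule(segments=[Segment(0.0, 24.0)])
        wrapped = gs.simulate(default_model, schedule=sched, times=times)
        np.testing.assert_allclose(plain.ys, wrapped.ys, rtol=1e-6, atol=1e-8)

    def test_states_stay_nonnegative(self, default_model):
        traj = gs.simulate(default_model, times=np.linspace(0.0, 120.0, 121))
        assert np.all(traj.ys >= 0.0)

    def test_glucose_monotone_in_batch_single_consumer(self):
        m = single_consumer_model(dilution=0.0)
        traj = gs.simulate(m, times=np.linspace(0.0, 200.0, 201))
        s = traj.variable("S")
        assert np.all(np.diff(s) <= 1e-9)
        assert s[-1] < 0.05  # substrate-limited growth exhausts S

    def test_adaptive_matches_euler_oracle(self):
        m = single_consumer_model(dilution=0.0)
        euler = gs.simulate_euler(m, m.default_init(), 48.0, dt=1e-3,
                                  record_every=1000)
        adaptive = gs.simulate(m, m.default_init(), times=euler.times)
        scale = np.maximum(np.abs(adaptive.ys).max(axis=0), 1e-6)
        err = np.max(np.abs(adaptive.ys - euler.ys) / scale)
        assert err < 1e-3

    def test_mix_event_replaces_half_the_volume(self, default_model):
        times = np.linspace(0.0, 20.0, 41)
        sched = gs.PerturbationSchedule(
            segments=[Segment(0.0, 10.0, dilution=0.0),
                      Segment(10.0, 20.0, dilution=0.0)],
            events=[MixEvent(time=10.0, fraction=0.5)])
        traj = gs.simulate(default_model, schedule=sched, times=times)
        i = list(times).index(10.0)
        before = gs.simulate(default_model, schedule=None,
                             times=np.linspace(0.0, 10.0, 21)).ys[-1]
        feed = default_model.feed_vector()
        n_met = default_model.n_met
        np.testing.assert_allclose(traj.ys[i][:n_met],
                                   0.5 * before[:n_met] + 0.5 * feed, rtol=1e-5)
        np.testing.assert_allclose(traj.ys[i][n_met:], 0.5 * before[n_met:],
                                   rtol=1e-5)

    def test_schedule_gap_rejected(self, default_model):
        sched = gs.PerturbationSchedule(segments=[Segment(0.0, 5.0),
                                                  Segment(6.0, 10.0)])
        with pytest.raises(ValueError):
            gs.simulate(default_model, schedule=sched,
                        times=np.linspace(0.0, 10.0, 11))

    def test_cell_count_conserved_under_pure_switching(self):
        """mu=0, death=0, D=0: switching only redistributes cells."""
        cfg = default_config()
        for sub in cfg["subpopulations"]:
            sub["mu_max"] = 0.0
        cfg["environment"]["dilution"] = 0.0
        m = gs.build_default_community(cfg)
        traj = gs.simulate(m, m.default_init(), times=np.linspace(0.0, 100.0, 51))
        for sp, series in traj.species_totals(live_only=False).items():
            assert np.max(np.abs(series - series[0])) / series[0] < 1e-9


class TestSteadyState:
    def test_abiotic_steady_state_equals_feed(self, default_model):
        m = default_model.copy()
        init = gs.CommunityState(cells={s: 0.0 for s in m.sub_ids},
                                 mets={n: 0.0 for n in m.met_names})
        state, ok = gs.find_steady_state(m, init, env=Segment(0, 1e9, dilution=0.05),
                                         polish=True)
        assert ok
        feed = {met.name: met.feed_conc for met in m.metabolites}
        for name, conc in state.mets.items():
            assert conc == pytest.approx(feed[name], abs=1e-9)

    def test_washout_above_max_growth_rate(self, default_model):
        d = 2.0 * max(s.mu_max for s in default_model.subpopulations)
        state, ok = gs.find_steady_state(default_model,
                                         env=Segment(0, 1e9, dilution=d),
                                         t_max=3000)
        assert ok
        live = sum(v for k, v in state.cells.items() if "inactive" not in k)
        assert live < 1e-6
        feed = {met.name: met.feed_conc for met in default_model.metabolites}
        for name, conc in state.mets.items():
            assert conc == pytest.approx(feed[name], abs=0.01 * max(feed[name], 1.0))

    def test_matches_plain_long_integration(self, default_model):
        env = Segment(0, 1e9, dilution=0.1)
        state, ok = gs.find_steady_state(default_model, env=env, tol=1e-6)
        assert ok
        envp = resolve_env(default_model, env)
        cm = compile_model(default_model)
        traj = gs.simulate(default_model,
                           schedule=gs.PerturbationSchedule(
                               segments=[Segment(0.0, 3000.0, dilution=0.1)]),
                           times=np.array([0.0, 1500.0, 3000.0]))
        long_run = traj.ys[-1]
        short = state.to_vector(default_model)
        denom = np.maximum(np.maximum(np.abs(long_run), np.abs(short)), 1e-3)
        assert np.max(np.abs(long_run - short) / denom) < 1e-3

    def test_basin_consistency_near_one_attractor(self, bistable_model):
        """Inits within +-10% of each other inside one basin settle on
        the same fixed point."""
        states = []
        for f in (0.9, 1.0, 1.1):
            init = gs.CommunityState(cells={"thrifty": 3000.0 * f, "greedy": 1.0 * f},
                                     mets={"substrate": 10.0})
            st, ok = gs.find_steady_state(bistable_model, init, t_max=3000)
            assert ok
            states.append(st.to_vector(bistable_model))
        for other in states[1:]:
            denom = np.maximum(np.abs(states[0]), 1e-3)
            assert np.max(np.abs(states[0] - other) / denom) < 1e-4

    def test_rejects_nonpositive_tol(self, default_model):
        with pytest.raises(ValueError):
            gs.find_steady_state(default_model, tol=0.0)
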