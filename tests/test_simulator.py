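"""Integration, initializations, vitality, serialization."""

import numpy as np
import pytest

from coralsym.deb_core import (
    Environment,
    HolobiontState,
    ParameterSet,
    compute_fluxes,
    default_params,
)
from coralsym.simulator import (
    SimConfig,
    classify_vitality,
    euler_step,
    init_bleached,
    init_healthy,
    run,
    trajectory_from_csv,
    trajectory_to_csv,
)


class TestEulerStep:
    def test_zero_net_growth_leaves_state_unchanged(self, healthy_pair):
        state, flux = healthy_pair
        f = flux.copy()
        f.j_HG = np.asarray(f.j_HT).copy()
        f.j_SG = np.asarray(f.j_ST).copy()
        out = euler_step(state, f, 0.1)
        assert np.asarray(out.host_biomass) == pytest.approx(
            np.asarray(state.host_biomass))
        assert np.asarray(out.symbiont_biomass) == pytest.approx(
            np.asarray(state.symbiont_biomass))

    def test_one_step_arithmetic(self, healthy_pair):
        state, flux = healthy_pair
        f = flux.copy()
        f.j_HG = np.asarray(0.13)
        f.j_HT = np.asarray(0.03)
        out = euler_step(HolobiontState(1.0, state.symbiont_biomass), f, 0.1)
        assert float(out.host_biomass) == pytest.approx(1.01)

    def test_first_order_consistency(self, params, benign_env, healthy_pair):
        """Richardson check: halving dt changes the one-interval result
        by O(dt^2)."""
        state, flux = healthy_pair

        def advance(dt, steps):
            s, f = state, flux
            for _ in range(steps):
                s = euler_step(s, f, dt)
                f = compute_fluxes(s, benign_env, params, f)
            return np.asarray(s.host_biomass)

        h = 0.2
        errs = []
        for dt in (h, h / 2):
            coarse = advance(dt, 1 if dt == h else 2)
            fine = advance(dt / 8, 8 if dt == h else 16)
            errs.append(abs(float(coarse - fine)))
        # first-order method: error roughly halves with dt
        assert errs[1] < 0.75 * errs[0]


class TestRun:
    def test_zero_duration_returns_initial_condition(self, params, benign_env,
                                                     healthy_pair):
        state, flux = healthy_pair
        traj = run(state, flux, benign_env, params, SimConfig(duration=0.0))
        assert len(traj) == 1
        assert traj.times[0] == 0.0
        assert np.asarray(traj.states[0].symbiont_biomass) == pytest.approx(
            np.asarray(state.symbiont_biomass))

    def test_deterministic(self, params, benign_env, healthy_pair):
        state, flux = healthy_pair
        cfg = SimConfig(duration=30.0)
        a = run(state, flux, benign_env, params, cfg).to_frame()
        b = run(state, flux, benign_env, params, cfg).to_frame()
        assert a.equals(b)

    def test_biomass_stays_nonnegative(self, params):
        env = Environment(light=60.0, din=1e-5, prey=0.0)  # lethal conditions
        state, flux = init_healthy(params, env)
        traj = run(state, flux, env, params, SimConfig(duration=200.0))
        for s in traj.states:
            assert np.all(np.asarray(s.symbiont_biomass) >= 0)
            assert np.all(np.asarray(s.host_biomass) > 0)

    def test_population_split_invariance(self, benign_env):
        """Two identical-parameter symbionts at s each match one at 2s."""
        p = default_params()
        sens = p.symbionts[0]
        p1 = ParameterSet(host=p.host, symbionts=(sens,))
        p2 = ParameterSet(host=p.host, symbionts=(sens, type(sens)(label="copy")))
        s1, f1 = init_healthy(p1, benign_env, symbiont0=1.0)
        s2, f2 = init_healthy(p2, benign_env, symbiont0=0.5)
        cfg = SimConfig(duration=100.0)
        t1 = run(s1, f1, benign_env, p1, cfg)
        t2 = run(s2, f2, benign_env, p2, cfg)
        H1 = [float(s.host_biomass) for s in t1.states]
        H2 = [float(s.host_biomass) for s in t2.states]
        assert H2 == pytest.approx(H1, rel=1e-9)
        tot1 = [float(s.total_symbiont) for s in t1.states]
        tot2 = [float(s.total_symbiont) for s in t2.states]
        assert tot2 == pytest.approx(tot1, rel=1e-9)

    def test_reduction_parity_with_independent_single_symbiont_code(
            self, single_sensitive, benign_env):
        """A two-symbiont run with one biomass at 0 equals a separately coded
        scalar one-symbiont stepper."""
        p2 = default_params()
        state2, flux2 = init_healthy(p2, benign_env, symbiont0=(0.8, 0.0))
        traj2 = run(state2, flux2, benign_env, p2, SimConfig(duration=50.0))

        hp = p2.host
        sp = p2.symbionts[0]
        env = benign_env

        def su1(m, x):
            return 0.0 if x == 0 else 1.0 / (1.0 / m + 1.0 / x)

        def su2(m, x, y):
            if x == 0 or y == 0:
                return 0.0
            return 1.0 / (1.0 / m + 1.0 / x + 1.0 / y - 1.0 / (x + y))

        def fluxes(H, S, lag):
            j_X = hp.j_Xm * env.prey / (env.prey + hp.K_X)
            j_N = hp.j_Nm * env.din / (env.din + hp.K_N)
            A = 1.26 + 1.39 * np.exp(-6.48 * S / H)
            j_L = A * env.light * sp.a_star
            j_HT = hp.j_HT0
            r_NH = hp.sigma_NH * hp.n_NH * j_HT
            j_HG = su2(hp.j_HGm, hp.y_C * (lag["rho_C"] * S / H + j_X),
                       (j_N + hp.n_NX * j_X + r_NH) / hp.n_NH)
            rho_N = max(j_N + hp.n_NX * j_X + r_NH - hp.n_NH * j_HG, 0.0)
            j_eC = max(j_X + lag["rho_C"] * S / H - j_HG / hp.y_C, 0.0)
            j_CO2 = hp.k_CO2 * j_eC
            r_CH = hp.sigma_CH * (j_HT + (1 - hp.y_C) * j_HG / hp.y_C)
            r_CS = sp.sigma_CS * (sp.j_ST0 + (1 - hp.y_C) * lag["j_SG"] / hp.y_C)
            j_CP = su2(sp.j_CPm, sp.y_CL * j_L,
                       (j_CO2 + r_CH) * H / S + r_CS) / lag["c_ROS"]
            j_eL = max(j_L - j_CP / sp.y_CL, 0.0)
            j_NPQ = su1(sp.k_NPQ, j_eL)
            c_ROS = 1.0 + max(j_eL - j_NPQ, 0.0) / sp.k_ROS
            r_NS = sp.sigma_NS * sp.n_NS * sp.j_ST0
            j_SG = su2(sp.j_SGm, hp.y_C * j_CP,
                       (rho_N * H / S + r_NS) / sp.n_NS)
            rho_C = max(j_CP - j_SG / hp.y_C, 0.0)
            j_ST = sp.j_ST0 * (1 + sp.b * (c_ROS - 1))
            return dict(j_HG=j_HG, j_HT=j_HT, j_SG=j_SG, j_ST=j_ST,
                        rho_C=rho_C, c_ROS=c_ROS)

        H, S = 1.0, 0.8
        lag = {"rho_C": float(np.asarray(flux2.rho_C)[0]),
               "j_SG": float(np.asarray(flux2.j_SG)[0]),
               "c_ROS": float(np.asarray(flux2.c_ROS)[0]),
               "j_HG": float(np.asarray(flux2.j_HG)),
               "j_HT": float(np.asarray(flux2.j_HT)),
               "j_ST": float(np.asarray(flux2.j_ST)[0])}
        dt = 0.1
        Hs = {0.0: H}
        for i in range(1, 501):
            H = H * (1 + (lag["j_HG"] - lag["j_HT"]) * dt)
            S = max(S * (1 + (lag["j_SG"] - lag["j_ST"]) * dt), 0.0)
            lag.update(fluxes(H, S, lag))
            t = i * dt
            if abs(t - round(t)) < 1e-9:
                Hs[round(t)] = H

        for t, s2 in zip(traj2.times, traj2.states):
            assert float(s2.host_biomass) == pytest.approx(Hs[round(t)], rel=1e-10)
            assert float(np.asarray(s2.symbiont_biomass)[1]) == 0.0


class TestInitHealthy:
    def test_default_biomasses(self, params, benign_env):
        state, _ = init_healthy(params, benign_env)
        assert float(state.host_biomass) == 1.0
        assert np.asarray(state.symbiont_biomass) == pytest.approx([0.5, 0.5])

    def test_fluxes_are_a_fixed_point(self, params, benign_env, healthy_pair):
        state, flux = healthy_pair
        again = compute_fluxes(state, benign_env, params, flux)
        assert again.max_relative_difference(flux) < 1e-9

    def test_positive_initial_growth_in_mild_conditions(self, params):
        env = Environment(light=20.0, din=1e-7, prey=1e-7)
        state, flux = init_healthy(params, env)
        traj = run(state, flux, env, params, SimConfig(duration=1.0))
        f0 = traj.fluxes[0]
        assert float(np.asarray(f0.j_HG)) - float(np.asarray(f0.j_HT)) > 0


class TestInitBleached:
    def test_anchored_fluxes(self, params, benign_env):
        state, flux = init_bleached(params, benign_env)
        assert np.asarray(flux.j_HG) == 0.0
        assert np.all(np.asarray(flux.j_CP) == 0.0)

    def test_equal_split_totals(self, params, benign_env):
        state, _ = init_bleached(params, benign_env, total_symbiont0=1e-4)
        assert np.asarray(state.symbiont_biomass) == pytest.approx([5e-5, 5e-5])
        assert float(state.total_symbiont) == pytest.approx(1e-4)

    def test_derived_fluxes_follow_dependency_order(self, params):
        env = Environment(light=30.0, din=1e-7, prey=2e-7)
        _, flux = init_bleached(params, env)
        hp = params.host
        j_X = hp.j_Xm * env.prey / (env.prey + hp.K_X)
        assert np.all(np.asarray(flux.rho_C) == 0.0)
        assert float(np.asarray(flux.j_eC)) == pytest.approx(j_X)
        assert float(np.asarray(flux.j_CO2)) == pytest.approx(hp.k_CO2 * j_X)
        # all light is excess light at zero photosynthesis
        assert np.asarray(flux.j_eL) == pytest.approx(np.asarray(flux.j_L))


class TestVitality:
    def _traj_with_growth(self, params, benign_env, healthy_pair, growth):
        state, flux = healthy_pair
        traj = run(state, flux, benign_env, params,
                   SimConfig(duration=100.0, record_every=10.0))
        f = traj.fluxes[-1]
        f.j_HG = np.asarray(f.j_HT) + growth
        return traj

    @pytest.mark.parametrize("growth, expected", [
        (0.0, "dead"), (0.01, "alive"), (-0.01, "dead"),
    ])
    def test_growth_sign_rules(self, params, benign_env, healthy_pair,
                               growth, expected):
        traj = self._traj_with_growth(params, benign_env, healthy_pair, growth)
        assert classify_vitality(traj, 100.0) == expected

    def test_out_of_range_check_time(self, params, benign_env, healthy_pair):
        state, flux = healthy_pair
        traj = run(state, flux, benign_env, params, SimConfig(duration=10.0))
        with pytest.raises(Exception):
            classify_vitality(traj, 100.0)


class TestBistability:
    def test_healthy_survives_where_bleached_collapses(self, params):
        env = Environment(light=30.0, din=1e-7, prey=1e-7)
        cfg = SimConfig(duration=100.0)
        sh, fh = init_healthy(params, env)
        sb, fb = init_bleached(params, env)
        th = run(sh, fh, env, params, cfg)
        tb = run(sb, fb, env, params, cfg)
        assert classify_vitality(th, 100.0) == "alive"
        assert classify_vitality(tb, 100.0) == "dead"


class TestSerialization:
    def test_csv_round_trip_to_15_significant_digits(self, params, benign_env,
                                                     healthy_pair, tmp_path):
        state, flux = healthy_pair
        traj = run(state, flux, benign_env, params, SimConfig(duration=20.0))
        path = tmp_path / "traj.csv"
        trajectory_to_csv(traj, path)
        back = trajectory_from_csv(path)
        orig = traj.to_frame()
        assert list(back.columns) == list(orig.columns)
        np.testing.assert_allclose(back.to_numpy(), orig.to_numpy(), rtol=1e-15)

    def test_json_round_trip(self, params, benign_env, healthy_pair):
        from coralsym.simulator import Trajectory
        state, flux = healthy_pair
        traj = run(state, flux, benign_env, params, SimConfig(duration=5.0))
        back = Trajectory.from_json(traj.to_json())
        np.testing.assert_allclose(back.to_numpy(), traj.to_frame().to_numpy(),
                                   rtol=1e-15)
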