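"""Simulator unit and property tests: neuron families, OU noise, integration."""

import numpy as np
import pytest

from finitenet import sim_core as sc


def zero_noise(m=0.0):
    return sc.NoiseParameters(tau_I=1.0, m_I=m, s_I=0.0)


class TestNeuronPopulation:
    def test_family_parameter_laws(self):
        pop = sc.make_neuron_population(200, 0.25, rng_seed=7)
        assert sum(p.is_inhibitory for p in pop) == 50
        for p in pop:
            assert 0.0 <= p.r <= 1.0
            if p.is_inhibitory:
                assert p.a == pytest.approx(0.02 + 0.08 * p.r)
                assert p.b == pytest.approx(0.25 - 0.05 * p.r)
                assert p.c == -65.0 and p.d == 2.0
            else:
                assert p.a == 0.02 and p.b == 0.2
                assert p.c == pytest.approx(-65.0 + 15.0 * p.r**2)
                assert p.d == pytest.approx(8.0 - 6.0 * p.r**2)

    @pytest.mark.parametrize(
        "is_inh,r,expected",
        [
            (False, 0.0, (0.02, 0.2, -65.0, 8.0)),  # classic regular spiking
            (False, 1.0, (0.02, 0.2, -50.0, 2.0)),  # bursting end of the family
            (True, 0.5, (0.06, 0.225, -65.0, 2.0)),
        ],
    )
    def test_family_anchor_points(self, is_inh, r, expected):
        if is_inh:
            p = sc.NeuronParameters(0.02 + 0.08 * r, 0.25 - 0.05 * r, -65.0, 2.0, True, r)
        else:
            p = sc.NeuronParameters(0.02, 0.2, -65.0 + 15 * r**2, 8 - 6 * r**2, False, r)
        assert (p.a, p.b, p.c, p.d) == pytest.approx(expected)

    def test_rounding_of_inhibitory_count(self):
        pop = sc.make_neuron_population(90, 0.25, rng_seed=1)
        assert sum(p.is_inhibitory for p in pop) == 22  # round(22.5) -> 22

    def test_seed_reproducibility(self):
        a = sc.make_neuron_population(50, 0.25, rng_seed=3)
        b = sc.make_neuron_population(50, 0.25, rng_seed=3)
        assert a == b

    def test_invalid_population(self):
        with pytest.raises(ValueError):
            sc.make_neuron_population(0, 0.25, rng_seed=0)


class TestOUNoise:
    def test_deterministic_fixed_point(self):
        params = sc.NoiseParameters(tau_I=1.0, m_I=25.0, s_I=0.0)
        assert sc.ou_noise_step(25.0, params, dt=0.1, xi=0.7) == pytest.approx(25.0)

    def test_single_step_formula(self):
        params = sc.NoiseParameters(tau_I=2.0, m_I=10.0, s_I=3.0)
        out = sc.ou_noise_step(4.0, params, dt=0.5, xi=-1.25)
        expected = 4.0 - (4.0 / 2.0) * 0.5 + (10.0 / 2.0) * 0.5 + 3.0 * np.sqrt(
            2 * 0.5 / 2.0
        ) * (-1.25)
        assert out == pytest.approx(expected, rel=1e-15)

    def test_stationary_moments_match_recursion(self):
        # The Euler-Maruyama recursion is an AR(1): I' = rho I + (1-rho) m + amp xi
        # with rho = 1 - dt/tau and amp = s sqrt(2 dt / tau). Its exact
        # stationary SD is amp / sqrt(1 - rho^2), slightly above s at finite dt.
        params = sc.NoiseParameters()
        dt = 0.1
        rho = 1 - dt / params.tau_I
        amp = params.s_I * np.sqrt(2 * dt / params.tau_I)
        sd_exact = amp / np.sqrt(1 - rho**2)

        rng = np.random.default_rng(42)
        n = 1_000_000
        xs = np.empty(n)
        I = params.m_I
        xi = rng.standard_normal(n)
        for i in range(n):
            I = I - (I / params.tau_I) * dt + (params.m_I / params.tau_I) * dt + amp * xi[i]
            xs[i] = I
        n_eff = n * (1 - rho) / (1 + rho)
        se_mean = sd_exact / np.sqrt(n_eff)
        se_sd = sd_exact / np.sqrt(2 * n_eff)
        assert abs(xs.mean() - params.m_I) < 3 * se_mean
        assert abs(xs.std() - sd_exact) < 3 * se_sd
        # the discretisation bias at dt = 0.1, tau = 1 keeps the SD within ~3%
        # of the nominal stationary value
        assert abs(xs.std() - params.s_I) / params.s_I < 0.03

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            sc.NoiseParameters(tau_I=0.0)


def single_neuron_config(**kw):
    defaults = dict(n_neurons=1, duration=1000.0, seed=0, noise=zero_noise(), noise_gain=1.0)
    defaults.update(kw)
    return sc.SimulationConfig(**defaults)


class TestStepNetwork:
    def test_subthreshold_fixed_point(self):
        # 0.04 v^2 + 5 v + 140 - u = 0 and b v = u at (v, u) = (-70, -14)
        p = sc.NeuronParameters(0.02, 0.2, -65.0, 8.0, False, 0.0)
        cfg = single_neuron_config()
        state = sc.NetworkState(
            v=np.array([-70.0]), u=np.array([-14.0]), I_noise=np.array([0.0]), t=0.0
        )
        state2, fired = sc.step_network(state, [p], np.zeros((1, 1)), cfg, np.random.default_rng(0))
        assert not fired
        assert state2.v[0] == pytest.approx(-70.0)
        assert state2.u[0] == pytest.approx(-14.0)

    @pytest.mark.parametrize("b", [0.2, 0.25])
    def test_fixed_point_family(self, b):
        disc = (5 + -b) ** 2 - 4 * 0.04 * 140  # 0.04 v^2 + (5 - b) v + 140 = 0
        v_star = (-(5 - b) - np.sqrt(disc)) / (2 * 0.04)
        p = sc.NeuronParameters(0.02, b, -65.0, 8.0, False, 0.0)
        state = sc.NetworkState(
            v=np.array([v_star]), u=np.array([b * v_star]), I_noise=np.array([0.0]), t=0.0
        )
        state2, fired = sc.step_network(
            state, [p], np.zeros((1, 1)), single_neuron_config(), np.random.default_rng(0)
        )
        assert not fired
        assert state2.v[0] == pytest.approx(v_star, abs=1e-9)

    def test_reset_rule(self):
        p = sc.NeuronParameters(0.02, 0.2, -65.0, 8.0, False, 0.0)
        state = sc.NetworkState(
            v=np.array([40.0]), u=np.array([0.0]), I_noise=np.array([0.0]), t=0.0
        )
        state2, fired = sc.step_network(
            state, [p], np.zeros((1, 1)), single_neuron_config(), np.random.default_rng(0)
        )
        assert fired == {0}
        assert state2.v[0] == -65.0
        # u gains its Euler increment dt*a*(b*v - u) before the +d reset
        assert state2.u[0] == pytest.approx(8.0 + 0.1 * 0.02 * (0.2 * 40.0), abs=1e-12)

    def test_pulse_delivered_next_step(self):
        p = sc.NeuronParameters(0.02, 0.2, -65.0, 8.0, False, 0.0)
        w = np.array([[0.0, 12.0], [0.0, 0.0]])  # 1 -> 0 with weight 12
        cfg = sc.SimulationConfig(n_neurons=2, duration=10.0, seed=0, noise=zero_noise(), noise_gain=1.0)
        state = sc.NetworkState(
            v=np.array([-70.0, 40.0]), u=np.array([-14.0, 0.0]),
            I_noise=np.zeros(2), t=0.0,
        )
        state2, fired = sc.step_network(state, [p, p], w, cfg, np.random.default_rng(0))
        assert fired == {1}
        assert state2.pending[0] == 12.0
        state3, _ = sc.step_network(state2, [p, p], w, cfg, np.random.default_rng(0))
        # neuron 0 left its fixed point only because of the pulse
        assert state3.v[0] > -70.0 + 11.0

    def test_dimension_mismatch(self):
        p = sc.NeuronParameters(0.02, 0.2, -65.0, 8.0, False, 0.0)
        state = sc.NetworkState(
            v=np.zeros(2), u=np.zeros(2), I_noise=np.zeros(2), t=0.0
        )
        with pytest.raises(ValueError):
            sc.step_network(state, [p], np.zeros((2, 2)), single_neuron_config(), np.random.default_rng(0))


def rs_neuron():
    return sc.NeuronParameters(0.02, 0.2, -65.0, 8.0, False, 0.0)


class TestRunSimulation:
    def test_tonic_rate_matches_bruteforce_reference(self):
        # Independent plain-Python Euler integration of the same equations.
        p = rs_neuron()
        dt, T, I = 0.1, 5000.0, 10.0
        v, u = -65.0, -13.0
        ref_spikes = []
        t = 0.0
        for k in range(int(T / dt)):
            vv = v
            v = vv + dt * (0.04 * vv * vv + 5.0 * vv + 140.0 - u + I)
            u = u + dt * (0.02 * (0.2 * vv - u))
            if v >= 40.0:
                ref_spikes.append((k + 1) * dt)
                v, u = -65.0, u + 8.0
            t += dt

        cfg = sc.SimulationConfig(
            n_neurons=1, duration=T, seed=0, noise=zero_noise(m=I), noise_gain=1.0
        )
        raster = sc.run_simulation(cfg, [p], np.zeros((1, 1)))
        # identical dynamics apart from the randomised initial condition:
        # compare steady-state rates
        assert raster.n_spikes == pytest.approx(len(ref_spikes), abs=2)
        isi_ref = np.diff(ref_spikes)[5:]
        isi_sim = np.diff(raster.times)[5:]
        assert np.median(isi_sim) == pytest.approx(np.median(isi_ref), rel=1e-6)

    def test_seed_determinism(self):
        cfg = sc.SimulationConfig(n_neurons=5, duration=2000.0, seed=11)
        pop = sc.make_neuron_population(5, 0.2, rng_seed=11)
        w = np.zeros((5, 5))
        r1 = sc.run_simulation(cfg, pop, w)
        r2 = sc.run_simulation(cfg, pop, w)
        assert np.array_equal(r1.times, r2.times)
        assert np.array_equal(r1.neuron_ids, r2.neuron_ids)

    def test_engines_agree_exactly(self):
        n = 4
        pop = sc.make_neuron_population(n, 0.25, rng_seed=5)
        rng = np.random.default_rng(5)
        w = rng.normal(8, 2, (n, n))
        np.fill_diagonal(w, 0.0)
        cfg = sc.SimulationConfig(n_neurons=n, duration=3000.0, seed=5, noise_gain=0.3)
        ra = sc.run_simulation(cfg, pop, w, engine="numba")
        rb = sc.run_simulation(cfg, pop, w, engine="numpy")
        assert np.array_equal(ra.times, rb.times)
        assert np.array_equal(ra.neuron_ids, rb.neuron_ids)

    def test_zero_weights_decouple_into_single_neuron_runs(self):
        n = 3
        pop = sc.make_neuron_population(n, 0.0, rng_seed=9)
        cfg = sc.SimulationConfig(n_neurons=n, duration=2000.0, seed=9, noise_gain=0.3)
        full = sc.run_simulation(cfg, pop, np.zeros((n, n)))
        for i in range(n):
            cfg_i = sc.SimulationConfig(
                n_neurons=1, duration=2000.0, seed=9, noise_gain=0.3,
                noise_stream_ids=(i,),
            )
            sub = sc.run_simulation(cfg_i, [pop[i]], np.zeros((1, 1)))
            a = full.spikes_of(i)
            b = sub.spikes_of(0)
            assert a.size and np.array_equal(a, b)

    def test_rate_monotone_in_noise_mean(self):
        rates = []
        for mI in (15.0, 25.0, 35.0):
            cfg = sc.SimulationConfig(
                n_neurons=10, duration=20_000.0, seed=2,
                noise=sc.NoiseParameters(1.0, mI, 9.0),
            )
            pop = sc.make_neuron_population(10, 0.25, rng_seed=2)
            raster = sc.run_simulation(cfg, pop, np.zeros((10, 10)))
            rates.append(raster.n_spikes)
        assert rates[0] <= rates[1] <= rates[2]

    def test_divergence_guard(self):
        pop = [rs_neuron(), rs_neuron()]
        w = np.array([[0.0, -5000.0], [0.0, 0.0]])  # absurd inhibitory kick
        cfg = sc.SimulationConfig(
            n_neurons=2, duration=5000.0, seed=1,
            noise=sc.NoiseParameters(1.0, 25.0, 9.0), noise_gain=1.0,
        )
        with pytest.raises(sc.NumericalDivergenceError) as exc:
            sc.run_simulation(cfg, pop, w)
        assert exc.value.neuron == 0
        assert exc.value.time_ms > 0

    def test_raster_invariants(self):
        cfg = sc.SimulationConfig(n_neurons=5, duration=2000.0, seed=4)
        pop = sc.make_neuron_population(5, 0.25, rng_seed=4)
        r = sc.run_simulation(cfg, pop, np.zeros((5, 5)))
        assert np.all(np.diff(r.times) >= 0)
        assert r.times.min() > 0 and r.times.max() <= cfg.duration
        for i in range(5):
            assert np.all(np.diff(r.spikes_of(i)) > 0)
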