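"""Model core: gate, environmental input, design, AGL fit, nonlinear stage."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fieldfit import fitcore as fc
from fieldfit import synthdata as sd
from fieldfit.data import EnvSeries, EnvStack, SampleSet


def _nl(**kw):
    base = dict(T=6.0, D=0.0, phi=6.0, gamma=1.0, w=2.0,
                theta_lo=-100.0, theta_hi=100.0)
    base.update(kw)
    return fc.NonlinearParams(**base)


class TestGate:
    def test_flat_when_ungated(self):
        ct = np.linspace(0, 24, 97)
        assert np.allclose(fc.gate(ct, _nl(gamma=0.0)), 1.0)

    def test_cosine_extremes(self):
        nl = _nl(gamma=1.0, phi=7.0, w=1.0)
        assert fc.gate(7.0, nl) == pytest.approx(1.0)
        assert fc.gate(19.0, nl) == pytest.approx(0.0, abs=1e-12)

    def test_handworked_quarter_period(self):
        # ((1 + cos(pi/2)) / 2) ** 2 = 0.25
        nl = _nl(gamma=1.0, phi=6.0, w=2.0)
        assert fc.gate(12.0, nl) == pytest.approx(0.25)

    @settings(max_examples=50, deadline=None)
    @given(ct=st.floats(0, 48), phi=st.floats(0, 24),
           gamma=st.floats(0, 1), w=st.floats(0.2, 8))
    def test_bounded_by_gate_depth(self, ct, phi, gamma, w):
        g = float(fc.gate(ct, _nl(phi=phi, gamma=gamma, w=w)))
        assert (1 - gamma) - 1e-12 <= g <= 1 + 1e-12

    def test_gate_mass_decreases_with_sharpness(self):
        ct = np.linspace(0, 24, 2000)
        masses = [fc.gate(ct, _nl(gamma=1.0, w=w)).mean() for w in (0.5, 1, 2, 4, 8)]
        assert all(a > b for a, b in zip(masses, masses[1:]))


def _const_env(c, days=5, dt=0.5):
    t = np.arange(0, days * 24, dt)
    return EnvSeries(t, np.full_like(t, float(c)), np.zeros_like(t))


class TestEnvInput:
    def test_constant_ungated_returns_the_constant(self):
        env = _const_env(3.7)
        x = fc.env_input(env, 96.0, _nl(gamma=0.0), "temperature")
        assert x == pytest.approx(3.7)

    def test_clipping_saturation(self):
        env = _const_env(50.0)
        nl = _nl(gamma=1.0, theta_hi=10.0, theta_lo=0.0)
        x = fc.env_input(env, 96.0, nl, "temperature")
        # theta_hi times the mean gate weight over the window
        h1, h0 = int((nl.D + nl.T) / 0.5), int(nl.D / 0.5)
        ks = 96.0 - np.arange(h0, h1)[::-1] * 0.5 - 0.5
        expected = 10.0 * fc.gate(ks % 24, nl).mean()
        assert x == pytest.approx(expected)

    def test_matches_bruteforce_sum_on_square_wave(self):
        cond = sd.ConditionSpec("c", 12, 35, 15)
        env = sd.gc_env_series(cond, days=6)
        nl = _nl(T=7.0, D=2.5, phi=13.0, gamma=1.0, w=3.0,
                 theta_lo=18.0, theta_hi=33.0)
        t = 110.5
        # brute force: iterate the half-open window [t-D-T, t-D) on the grid
        acc, cnt = 0.0, 0
        for k in range(len(env.t)):
            s = env.t[k]
            if t - nl.D - nl.T <= s < t - nl.D:
                e = min(max(env.temperature[k], nl.theta_lo), nl.theta_hi)
                acc += float(fc.gate(env.clock_time[k], nl)) * e
                cnt += 1
        assert fc.env_input(env, t, nl, "temperature") == pytest.approx(acc / cnt)

    def test_invariant_to_earlier_history(self):
        cond = sd.ConditionSpec("c", 8, 20, 30)
        short = sd.gc_env_series(cond, days=5)
        long = sd.gc_env_series(cond, days=9)
        nl = _nl(T=24.0, D=6.0)
        a = fc.env_input(short, 100.0, nl, "temperature")
        b = fc.env_input(long, 196.0, nl, "temperature")  # same clock alignment
        assert a == pytest.approx(b)

    def test_insufficient_history_rejected(self):
        env = _const_env(5.0, days=4)
        with pytest.raises(ValueError, match="history"):
            fc.env_input(env, 4.0, _nl(T=24.0), "temperature")


class TestDesignRow:
    def test_origin(self):
        row = fc.design_row(0.0, 0.0, 0.0)
        np.testing.assert_allclose(row, [1, 0, 1, 0, 0, 0, 0, 0], atol=1e-12)

    def test_quarter_period(self):
        row = fc.design_row(6.0, 0.0, 0.0)
        assert row[2] == pytest.approx(0.0, abs=1e-12)
        assert row[3] == pytest.approx(1.0)

    def test_direct_evaluation(self):
        c, s = np.cos(3 * np.pi / 2), np.sin(3 * np.pi / 2)
        row = fc.design_row(18.0, 2.0, 3.0)
        np.testing.assert_allclose(row, [1, 2, c, s, 3, 6, 3 * c, 3 * s], atol=1e-12)


def _random_design(n, seed):
    rng = np.random.default_rng(seed)
    clock = rng.uniform(0, 24, n)
    age = rng.uniform(10, 100, n)
    x = rng.normal(2, 1.5, n)
    return fc.design_matrix(clock, age, x)


class TestFitLinearAgl:
    def test_zero_lambda_equals_ols(self):
        X = _random_design(300, 1)
        rng = np.random.default_rng(2)
        y = X @ np.array([1.0, 0.02, 0.5, -0.3, 0.8, 0.01, 0.1, -0.2])
        y += rng.normal(0, 0.3, len(y))
        coefs, _ = fc.fit_linear_agl(X, y, lambda_grid=[0.0])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(coefs.as_array(), ols, atol=1e-6)

    def test_single_group_support_recovery(self):
        X = _random_design(600, 3)
        beta = np.zeros(8)
        beta[0], beta[2], beta[3] = 2.0, 1.5, -0.8  # intercept + clock pair only
        y = X @ beta
        coefs, _ = fc.fit_linear_agl(X, y)
        arr = coefs.as_array()
        assert arr[1] == 0.0
        assert np.all(arr[4:] == 0.0)
        # oracle: exact least squares on the true support
        sup = np.linalg.lstsq(X[:, [0, 2, 3]], y, rcond=None)[0]
        np.testing.assert_allclose(arr[[0, 2, 3]], sup, atol=1e-3)

    def test_constant_response_intercept_only(self):
        X = _random_design(100, 4)
        with pytest.warns(UserWarning, match="zero variance"):
            coefs, _ = fc.fit_linear_agl(X, np.full(100, 3.0))
        assert coefs.b0 == pytest.approx(3.0)
        assert np.all(coefs.as_array()[1:] == 0.0)

    def test_huge_lambda_shrinks_to_intercept(self):
        X = _random_design(200, 5)
        rng = np.random.default_rng(6)
        y = X @ np.array([1, 0.01, 0.4, 0.2, 0.3, 0, 0, 0]) + rng.normal(0, 0.2, 200)
        coefs, _ = fc.fit_linear_agl(X, y, lambda_grid=[1e9])
        assert np.all(coefs.as_array()[1:] == 0.0)
        assert coefs.b0 == pytest.approx(float(np.mean(y)))


class TestOptimizeNonlinear:
    def test_criterion_not_worse_than_any_grid_point(self, gc_probe):
        truth = sd.make_truth_genes(1, 0, 0, reference=gc_probe.samples,
                                    seed=11, noise_sd=0.0)[0]
        bundle = sd.simulate_gc_study(sd.enumerate_conditions()[:10], [truth],
                                      seed=12, batch_effect_sd=0)
        y = bundle.expr.loc[truth.gene_id].to_numpy()
        E = bundle.samples.stack.temperature
        grid = fc.default_nl_grid(float(E.min()), float(E.max()))
        nl, coefs, crit = fc.optimize_nonlinear(y, bundle.samples, "temperature",
                                                grid=grid, nm_maxiter=0)
        for g in grid[::7]:
            x = fc.sample_env_inputs(bundle.samples, g, "temperature")
            _, bic = fc.fit_linear_agl(
                fc.design_matrix(bundle.samples.clock, bundle.samples.age, x), y
            )
            assert crit <= bic + 1e-6

    def test_empty_grid_rejected(self, gc_probe):
        with pytest.raises(ValueError, match="empty"):
            fc.optimize_nonlinear(np.zeros(len(gc_probe.samples)),
                                  gc_probe.samples, "temperature", grid=[])

    def test_gate_phase_recovery(self, gc_probe, conditions):
        """A strongly gated gene's peak-responsiveness time is recovered to 2 h."""
        nl_true = _nl(T=6.0, D=0.0, phi=6.0, gamma=1.0, w=2.0)
        tg = sd.TruthGene("g", "temperature", nl_true,
                          fc.LinearCoefs(5.0, 0.0, 0.3, -0.2, 0.2, 0, 0, 0), 0.05)
        bundle = sd.simulate_gc_study(conditions, [tg], seed=13, batch_effect_sd=0)
        y = bundle.expr.loc["g"].to_numpy()
        nl, _, _ = fc.optimize_nonlinear(y, bundle.samples, "temperature")
        dphi = min(abs(nl.phi - 6.0), 24 - abs(nl.phi - 6.0))
        assert dphi <= 2.0


class TestPredictAndChoice:
    def test_neither_model_ignores_environment(self, conditions):
        fit = fc.GeneModelFit("g", "neither", _nl(),
                              fc.LinearCoefs(2.0, 0.1, 0.5, 0.2, 0, 0, 0, 0),
                              0.0, 10)
        samples = [(1.5, 20.0, 80.0), (13.5, 20.0, 92.0)]
        p1 = fc.predict(fit, sd.gc_env_series(conditions[10], days=5), samples)
        p2 = fc.predict(fit, sd.gc_env_series(conditions[60], days=5), samples)
        np.testing.assert_allclose(p1, p2)

    def test_handworked_prediction(self):
        env = _const_env(1.5)
        fit = fc.GeneModelFit("g", "temperature", _nl(gamma=0.0),
                              fc.LinearCoefs(1, 0, 0, 0, 2, 0, 0, 0), 0.0, 10)
        # x_env = 1.5 (constant trace), so y = 1 + 2 * 1.5 = 4
        pred = fc.predict(fit, env, [(0.0, 10.0, 96.0)])
        assert pred[0] == pytest.approx(4.0)

    def test_noiseless_selfconsistency(self, gc_probe):
        tg = sd.make_truth_genes(0, 1, 0, reference=gc_probe.samples,
                                 seed=21, noise_sd=0.0)[0]
        bundle = sd.simulate_gc_study(sd.enumerate_conditions()[:6], [tg],
                                      seed=22, batch_effect_sd=0)
        pred = fc.predict(tg.as_fit(), bundle.samples.stack, bundle.samples)
        obs = bundle.expr.loc[tg.gene_id].to_numpy()
        assert np.max(np.abs(np.maximum(pred, 0) - obs)) < 1e-9

    def test_tie_between_env_free_models_is_neither(self):
        nl = _nl()
        c_free = fc.LinearCoefs(1.0, 0.0, 0.5, 0.1, 0, 0, 0, 0)
        fits = {"temperature": (nl, c_free, 10.0), "radiation": (nl, c_free, 10.0)}
        assert fc.choose_predictor(fits) == "neither"

    def test_winner_with_zero_env_group_reported_neither(self):
        nl = _nl()
        zero = fc.LinearCoefs(1.0, 0.0, 0.5, 0.1, 0, 0, 0, 0)
        envy = fc.LinearCoefs(1.0, 0.0, 0.5, 0.1, 0.4, 0, 0, 0)
        fits = {"temperature": (nl, zero, 5.0), "radiation": (nl, envy, 9.0)}
        assert fc.choose_predictor(fits) == "neither"
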