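"""Generator correctness: condition grid, environmental traces, forward model."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fieldfit import synthdata as sd
from fieldfit.data import EnvStack, SampleSet
from fieldfit import fitcore as fc


class TestEnumerateConditions:
    def test_count_and_uniqueness(self, conditions):
        assert len(conditions) == 73
        ids = [c.condition_id for c in conditions]
        assert len(set(ids)) == 73

    def test_matches_bruteforce_factorial_rule(self, conditions):
        brute = set()
        for lh in (8, 12, 16):
            for lt, dk in itertools.product((20, 25, 30, 35, 40), (15, 20, 25, 30, 35)):
                if lt != dk:
                    brute.add((lh, lt, dk))
        for dk in (15, 20, 25, 30, 35):
            brute.add((0, None, dk))
        for lt in (20, 25, 30, 35, 40):
            brute.add((24, lt, None))
        got = {(c.light_hours, c.light_temp, c.dark_temp) for c in conditions}
        assert got == brute
        assert sum(c.light_hours == 8 for c in conditions) == 21

    def test_equal_temperature_conditions_excluded(self, conditions):
        assert not any(
            c.light_temp is not None and c.light_temp == c.dark_temp
            for c in conditions
        )

    def test_deterministic_order(self, conditions):
        assert conditions == sd.enumerate_conditions()
        lhs = [c.light_hours for c in conditions]
        assert lhs == sorted(lhs)


class TestGcEnvSeries:
    def test_square_wave(self):
        cond = sd.ConditionSpec("c", 12, 30, 20)
        env = sd.gc_env_series(cond)
        day = env.clock_time < 12
        assert np.all(env.temperature[day] == 30)
        assert np.all(env.temperature[~day] == 20)
        assert set(np.unique(env.irradiance)) == {0.0, 1.0}

    def test_constant_conditions(self):
        dark = sd.gc_env_series(sd.ConditionSpec("d", 0, None, 25))
        assert np.all(dark.irradiance == 0) and np.all(dark.temperature == 25)
        light = sd.gc_env_series(sd.ConditionSpec("l", 24, 30, None))
        assert np.all(light.irradiance == 1.0) and np.all(light.temperature == 30)

    def test_negative_dif_condition_has_negative_correlation(self):
        env = sd.gc_env_series(sd.ConditionSpec("n", 8, 20, 35))
        one_day = slice(0, int(24 / env.dt))
        r = np.corrcoef(env.temperature[one_day], env.irradiance[one_day])[0, 1]
        assert r < 0

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            sd.gc_env_series(sd.ConditionSpec("c", 12, 30, 20), dt=0.7)


class TestFieldEnvSeries:
    def test_positive_diel_correlation(self):
        env = sd.field_env_series(30, seed=1)
        r = np.corrcoef(env.temperature, env.irradiance)[0, 1]
        assert r > 0.3

    def test_reproducible(self):
        a = sd.field_env_series(10, seed=7)
        b = sd.field_env_series(10, seed=7)
        np.testing.assert_array_equal(a.temperature, b.temperature)
        np.testing.assert_array_equal(a.irradiance, b.irradiance)

    def test_irradiance_zero_at_midnight_without_noise(self):
        p = sd.FieldEnvParams(ar_sd=0.0, weather_sigma=0.0)
        env = sd.field_env_series(6, seed=0, params=p)
        midnight = env.clock_time < 1e-9
        assert np.all(env.irradiance[midnight] == 0)

    def test_gc_grid_less_correlated_than_field(self, conditions):
        """Pooled over the GC grid the variables are far less correlated than
        in the field, and temperature spans its full range within both light
        phases (the conditional decorrelation the design is built for)."""
        temps, irrs = [], []
        for c in conditions:
            env = sd.gc_env_series(c)
            one_day = slice(0, int(24 / env.dt))
            temps.append(env.temperature[one_day])
            irrs.append(env.irradiance[one_day])
        t, i = np.concatenate(temps), np.concatenate(irrs)
        r_gc = np.corrcoef(t, i)[0, 1]
        field = sd.field_env_series(30, seed=1)
        r_field = np.corrcoef(field.temperature, field.irradiance)[0, 1]
        assert abs(r_gc) < r_field
        assert set(np.unique(t[i > 0])) == {20, 25, 30, 35, 40}
        assert set(np.unique(t[i == 0])) == {15, 20, 25, 30, 35}


class TestSimulateExpression:
    def test_noiseless_roundtrip_through_predict(self, gc_probe, small_truth):
        noiseless = [sd.TruthGene(t.gene_id, t.driver, t.true_params,
                                  t.true_coefs, 0.0) for t in small_truth]
        env = sd.gc_env_series(sd.enumerate_conditions()[30], days=5)
        times = [(96.0 + ck, 17.0) for ck in sd.SAMPLING_CLOCKS]
        study = sd.simulate_expression(noiseless, env, times, seed=0)
        stack = EnvStack([env])
        samples = SampleSet(stack, [0] * len(times),
                            [t for t, _ in times],
                            [t % 24 for t, _ in times], [a for _, a in times])
        for tg in noiseless:
            mu = fc.predict(tg.as_fit(), stack, samples)
            got = study.matrix.loc[tg.gene_id].to_numpy()
            assert np.max(np.abs(np.maximum(mu, 0) - got)) < 1e-9

    def test_constant_gene(self):
        tg = sd.TruthGene("g", "neither",
                          fc.NonlinearParams(3, 0, 0, 0, 2, -1, 1),
                          fc.LinearCoefs(b0=5.0), 0.0)
        env = sd.gc_env_series(sd.enumerate_conditions()[10], days=5)
        study = sd.simulate_expression([tg], env, [(80.0, 17.0), (90.0, 17.0)])
        assert np.all(study.matrix.to_numpy() == 5.0)

    def test_insufficient_history_names_earliest_time(self, small_truth):
        env = sd.gc_env_series(sd.enumerate_conditions()[10], days=5)
        with pytest.raises(ValueError, match="72.0 h"):
            sd.simulate_expression(small_truth, env, [(10.0, 17.0)])

    def test_temperature_gene_differs_between_temperature_conditions(self, gc_probe):
        tg = sd.make_truth_genes(1, 0, 0, reference=gc_probe.samples, seed=3,
                                 noise_sd=0.0)[0]
        conds = [c for c in sd.enumerate_conditions()
                 if c.light_hours == 12 and c.light_temp == 30]
        b1 = sd.simulate_gc_study([conds[0]], [tg], seed=0, batch_effect_sd=0)
        b2 = sd.simulate_gc_study([conds[1]], [tg], seed=0, batch_effect_sd=0)
        assert not np.allclose(b1.expr.to_numpy(), b2.expr.to_numpy())


class TestStudyPlanAndFixtures:
    @pytest.mark.parametrize("n_cond,tp,cv,expected", [
        (73, 8, 2, 1168), (1, 1, 1, 1), (5, 8, 2, 80),
    ])
    def test_make_study_samples_counts(self, conditions, n_cond, tp, cv, expected):
        plan = sd.make_study_samples(conditions[:n_cond], tp, cv)
        assert len(plan) == expected

    def test_plate_swap_involution_and_identity(self, small_gc):
        study = small_gc.study
        once = sd.inject_plate_swap(study, "P01", "P02")
        assert not once.meta.equals(study.meta)
        twice = sd.inject_plate_swap(once, "P01", "P02")
        pd.testing.assert_frame_equal(twice.meta, study.meta)
        pd.testing.assert_frame_equal(twice.matrix, study.matrix)
        same = sd.inject_plate_swap(study, "P03", "P03")
        pd.testing.assert_frame_equal(same.meta, study.meta)

    def test_plate_swap_breaks_nominal_temperature(self, small_gc):
        swapped = sd.inject_plate_swap(small_gc.study, "P01", "P02")
        p1 = swapped.meta[swapped.meta["plate_id"] == "P01"]
        true_t = swapped.truth.loc[p1.index, "true_temp_C"]
        assert not np.allclose(p1["nominal_temp_C"].to_numpy(), true_t.to_numpy())

    def test_plate_swap_unknown_plate(self, small_gc):
        with pytest.raises(ValueError, match="unknown plate"):
            sd.inject_plate_swap(small_gc.study, "P01", "nope")

    def test_snp_fixture_pure_and_degenerate(self):
        calls = sd.make_snp_fixture(200, 3, ["A", "B", "A"], 0.0, 0.0, seed=1)
        wide = calls.pivot(index="sample_id", columns="locus_id", values="call")
        assert (wide.loc["s000"] == "A").all()
        assert (wide.loc["s001"] == "B").all()
        none = sd.make_snp_fixture(50, 1, ["A"], 0.0, 1.0, seed=1)
        assert (none["call"] == "none").all()

    def test_snp_fixture_mixture_half_concordant(self):
        calls = sd.make_snp_fixture(4000, 1, ["mix"], 0.0, 0.0, seed=2)
        prop = (calls["call"] == "A").mean()
        assert abs(prop - 0.5) < 0.03  # binomial expectation

    def test_cluster_table_shape_and_selection(self):
        table = sd.make_cluster_table()
        sizes = table.groupby("exemplar_gene_id").size()
        assert len(sizes) == 466
        assert int(sizes.sum()) == 15907
        for target in (2929, 3208, 1167, 687, 526):
            chosen = sd.select_exemplars_for_count(table, target)
            assert int(sizes.loc[chosen].sum()) == target
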