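"""Diel statistics: filters, spline amplitude, DEGs, correlation screens."""

import numpy as np
import pandas as pd
import pytest

from fieldfit import dielstats as ds
from fieldfit.data import ExpressionStudy

CLOCKS = np.array([1.5, 4.5, 7.5, 10.5, 13.5, 16.5, 19.5, 22.5])


def _study(matrix: dict, meta_rows: list) -> ExpressionStudy:
    ids = [r["sample_id"] for r in meta_rows]
    m = pd.DataFrame(matrix, index=ids).T
    m.index.name = "gene_id"
    return ExpressionStudy(m, pd.DataFrame(meta_rows))


class TestFilterExpressed:
    def test_strict_inequality_and_bruteforce(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.uniform(0, 3, (40, 10)),
                           index=[f"g{i}" for i in range(40)])
        mat.loc["g0"] = 1.0    # mean exactly 1: excluded
        mat.loc["g1"] = 1.01   # included
        meta = pd.DataFrame({
            "sample_id": list(mat.columns), "cultivar": "A", "condition_id": "c",
            "plate_id": "P1", "clock_time_h": 0.0, "age_days": 17.0,
            "sampling_time_index": 0,
        })
        study = ExpressionStudy(mat, meta)
        kept = set(ds.filter_expressed(study))
        brute = {g for g in mat.index if mat.loc[g].mean() > 1.0}
        assert kept == brute
        assert "g0" not in kept and "g1" in kept


class TestDielAmplitude:
    def test_constant_series_zero_amplitude(self):
        res = ds.diel_amplitude(CLOCKS, np.full(8, 4.2))
        assert res.amplitude == pytest.approx(0.0, abs=1e-8)

    def test_cosine_amplitude_band(self):
        for A in (1.0, 3.0):
            y = A * np.cos(2 * np.pi * CLOCKS / 24.0) + 5.0
            res = ds.diel_amplitude(CLOCKS, y)
            assert 1.8 * A <= res.amplitude <= 2.0 * A

    def test_matches_r_smoothing_spline_oracle(self):
        # frozen from R: smooth.spline(x, y, spar=0.3, all.knots=TRUE),
        # evaluated on the 1.5-h grid; agreement is approximate because the
        # spar->penalty conversion is parameterization-level, not bit-level
        y = 3 * np.cos(2 * np.pi * CLOCKS / 24.0) + 5.0
        res = ds.diel_amplitude(CLOCKS, y)
        assert res.amplitude == pytest.approx(5.711222, rel=0.05)
        y2 = np.array([2.1, 0.5, 3.3, 4.0, 2.2, 1.1, 0.7, 2.5])
        res2 = ds.diel_amplitude(CLOCKS, y2)
        assert res2.amplitude == pytest.approx(2.812411, rel=0.15)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(0, 5, 8)
        a = ds.diel_amplitude(CLOCKS, y).amplitude
        b = ds.diel_amplitude(CLOCKS, y + 7.5).amplitude
        assert a == pytest.approx(b, abs=1e-6)

    def test_time_origin_shift_invariance(self):
        y = 2.0 * np.cos(2 * np.pi * CLOCKS / 24.0) + 3.0
        a = ds.diel_amplitude(CLOCKS, y).amplitude
        b = ds.diel_amplitude(CLOCKS + 36.0, y).amplitude
        assert a == pytest.approx(b, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="4 time points"):
            ds.diel_amplitude([0, 12, 24], [1, 2, 1])


class TestFilterOscillating:
    def _table(self, amp_a, amp_b):
        return pd.DataFrame({
            "gene_id": ["g"] * 2, "cultivar": ["A", "B"],
            "condition_id": ["c", "c"], "amplitude": [amp_a, amp_b],
        })

    @pytest.mark.parametrize("a,b,kept", [
        (2.5, 2.5, True), (2.5, 1.9, False), (2.0, 3.0, False),
    ])
    def test_both_cultivar_rule_strict(self, a, b, kept):
        out = ds.filter_oscillating(self._table(a, b))
        assert ("g" in out) == kept

    def test_missing_cultivar_rejected(self):
        solo = self._table(3.0, 3.0).iloc[:1]
        with pytest.raises(ValueError):
            ds.filter_oscillating(solo)


class TestCultivarSpecific:
    def _study(self, mean_a, mean_b):
        rows = []
        for i in range(4):
            rows.append({"sample_id": f"a{i}", "cultivar": "A", "condition_id": "c",
                         "plate_id": "P1", "clock_time_h": 0.0, "age_days": 17.0,
                         "sampling_time_index": i})
            rows.append({"sample_id": f"b{i}", "cultivar": "B", "condition_id": "c",
                         "plate_id": "P1", "clock_time_h": 0.0, "age_days": 17.0,
                         "sampling_time_index": i})
        vals = {f"a{i}": mean_a for i in range(4)} | {f"b{i}": mean_b for i in range(4)}
        return _study({"g": [vals[r["sample_id"]] for r in rows]}, rows)

    @pytest.mark.parametrize("ma,mb,specific", [
        (3.0, 0.4, True),    # both clauses satisfied
        (3.0, 0.9, False),   # low cultivar not low enough
        (2.3, 0.4, False),   # difference 1.9 <= 2
    ])
    def test_rules(self, ma, mb, specific):
        out = ds.cultivar_specific_genes(self._study(ma, mb))
        assert ("g" in out["A"]) == specific
        assert out["B"] == []

    def test_bruteforce_on_random_matrix(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(6):
            for cv in "AB":
                rows.append({"sample_id": f"{cv}{i}", "cultivar": cv,
                             "condition_id": "c", "plate_id": "P1",
                             "clock_time_h": 0.0, "age_days": 17.0,
                             "sampling_time_index": i})
        mat = {f"g{j}": rng.uniform(0, 4, len(rows)) for j in range(50)}
        study = _study(mat, rows)
        out = ds.cultivar_specific_genes(study)
        a_cols = [r["sample_id"] for r in rows if r["cultivar"] == "A"]
        b_cols = [r["sample_id"] for r in rows if r["cultivar"] == "B"]
        for g in mat:
            ma = study.matrix.loc[g, a_cols].mean()
            mb = study.matrix.loc[g, b_cols].mean()
            assert (g in out["A"]) == (ma - mb > 2 and mb < 0.5)
            assert (g in out["B"]) == (mb - ma > 2 and ma < 0.5)


def _paired_study(n_genes, delta, sigma, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for i, ck in enumerate(CLOCKS):
        for cv in "AB":
            rows.append({"sample_id": f"{cv}{i}", "cultivar": cv,
                         "condition_id": "c", "plate_id": "P1",
                         "clock_time_h": ck, "age_days": 17.0,
                         "sampling_time_index": i})
    mat = {}
    for j in range(n_genes):
        base = rng.uniform(2, 6) + rng.normal(0, 1, len(CLOCKS))
        vals = []
        for i in range(len(CLOCKS)):
            vals.append(base[i] + rng.normal(0, sigma))          # cultivar A
            vals.append(base[i] + delta + rng.normal(0, sigma))  # cultivar B
        mat[f"g{j}"] = vals
    return _study(mat, rows)


def brute_force_bh(p):
    """Textbook Benjamini-Hochberg step-up adjusted values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        val = min(prev, p[idx] * m / rank)
        q[idx] = val
        prev = val
    return q


class TestDegPairedT:
    def test_identical_cultivars_no_degs(self):
        study = _paired_study(30, 0.0, 0.0, seed=1)
        # zero sigma AND zero delta: columns identical within a pair
        degs, table = ds.deg_paired_t(study, "c")
        assert degs == []

    def test_strong_shift_detected_with_direction(self):
        study = _paired_study(1, 4.0, 0.1, seed=2)
        degs, _ = ds.deg_paired_t(study, "c")
        assert len(degs) == 1
        assert degs[0].direction == "higher_B"

    def test_q_values_match_bruteforce_bh(self):
        study = _paired_study(200, 0.3, 1.0, seed=3)
        _, table = ds.deg_paired_t(study, "c")
        np.testing.assert_allclose(table["q"].to_numpy(),
                                   brute_force_bh(table["p"].to_numpy()),
                                   atol=1e-12)

    def test_unequal_pairing_rejected(self):
        study = _paired_study(3, 0.0, 1.0, seed=4)
        dropped = study.matrix.drop(columns=["A0"])
        meta = study.meta.drop(index=["A0"])
        with pytest.raises(ValueError):
            ds.deg_paired_t(ExpressionStudy(dropped, meta.reset_index()), "c")


class TestTempCorrelationScreen:
    def _study_with_temps(self, mat, temps):
        rows = [{"sample_id": f"s{i}", "cultivar": "A", "condition_id": "c",
                 "plate_id": "P1", "clock_time_h": 0.0, "age_days": 17.0,
                 "sampling_time_index": i, "nominal_temp_C": temps[i]}
                for i in range(len(temps))]
        return _study(mat, rows)

    def test_affine_gene_r_one(self):
        temps = np.array([15.0, 20, 25, 30, 35, 40])
        study = self._study_with_temps({"g": 0.1 * temps + 1}, temps)
        pos, neg, r = ds.temp_correlation_screen(study)
        assert pos == ["g"] and neg == []
        assert r["g"] == pytest.approx(1.0)

    def test_independent_gene_excluded(self):
        rng = np.random.default_rng(11)
        temps = rng.uniform(15, 40, 200)
        study = self._study_with_temps({"g": rng.normal(3, 1, 200)}, temps)
        pos, neg, r = ds.temp_correlation_screen(study)
        assert pos == [] and neg == [] and abs(r["g"]) < 0.3

    def test_zero_variance_gene_excluded_with_warning(self):
        temps = np.array([15.0, 25, 35, 40])
        study = self._study_with_temps({"g": [2.0, 2.0, 2.0, 2.0]}, temps)
        with pytest.warns(UserWarning, match="zero variance"):
            pos, neg, r = ds.temp_correlation_screen(study)
        assert pos == [] and neg == [] and np.isnan(r["g"])

    def test_negative_set(self):
        temps = np.array([15.0, 20, 25, 30, 35, 40])
        study = self._study_with_temps({"g": -0.2 * temps + 9}, temps)
        pos, neg, _ = ds.temp_correlation_screen(study)
        assert neg == ["g"] and pos == []
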