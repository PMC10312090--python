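"""Regression model selection, FDR, repeatability, correlations, conversions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cswater as cw


def _table(age, sex, vol, y, roi="cortex", wf="csff"):
    d = dict(
        subject_id=[f"s{i}" for i in range(len(age))],
        age_years=age, sex=sex, roi=roi, normalized_volume=vol,
        mwf=0.05, iewf=0.9, csff=0.05,
    )
    t = pd.DataFrame(d)
    t[wf] = y
    return t


def _random_table(rng, n=40):
    age = rng.uniform(20, 80, n)
    sex = rng.integers(0, 2, n)
    vol = rng.normal(500, 40, n)
    y = 0.04 + 1e-4 * age + 0.002 * sex + 1e-5 * vol + rng.normal(0, 0.01, n)
    return _table(age, sex, vol, y)


class TestFitLmQm:
    def test_noiseless_linear_recovered_to_machine_precision(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(20, 80, 30)
        sex = rng.integers(0, 2, 30)
        vol = rng.normal(500, 40, 30)
        y = 2.0 + 0.1 * age
        lm, _ = cw.fit_lm_qm(_table(age, sex, vol, y), ("cortex", "csff"))
        assert lm.params["const"] == pytest.approx(2.0, abs=1e-9)
        assert lm.params["age"] == pytest.approx(0.1, abs=1e-12)
        assert lm.params["sex"] == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_quadratic_recovered(self):
        rng = np.random.default_rng(1)
        age = rng.uniform(20, 80, 30)
        y = 0.001 * age**2
        _, qm = cw.fit_lm_qm(
            _table(age, rng.integers(0, 2, 30), rng.normal(500, 40, 30), y),
            ("cortex", "csff"),
        )
        assert qm.params["age_sq"] == pytest.approx(0.001, abs=1e-10)

    def test_coefficients_match_normal_equations(self):
        rng = np.random.default_rng(2)
        t = _random_table(rng)
        lm, qm = cw.fit_lm_qm(t, ("cortex", "csff"))
        X = np.column_stack(
            [np.ones(len(t)), t["age_years"], t["sex"], t["normalized_volume"]]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ t["csff"])
        np.testing.assert_allclose(lm.params.to_numpy(), beta, rtol=1e-8)

    def test_single_sex_design_rejected(self):
        rng = np.random.default_rng(3)
        t = _random_table(rng)
        t["sex"] = 1
        with pytest.raises(ValueError, match="sex"):
            cw.fit_lm_qm(t, ("cortex", "csff"))


class TestSelectModel:
    def test_strong_quadratic_selects_qm(self):
        rng = np.random.default_rng(4)
        age = rng.uniform(20, 80, 60)
        y = 0.04 + 1e-4 * (age - 50) ** 2 + rng.normal(0, 1e-4, 60)
        lm, qm = cw.fit_lm_qm(
            _table(age, rng.integers(0, 2, 60), rng.normal(500, 40, 60), y),
            ("cortex", "csff"),
        )
        res = cw.select_model(lm, qm)
        assert res.model == "QM"
        assert res.age_p == res.anova_p
        assert res.age_p_quadratic is not None

    def test_exactly_linear_noiseless_keeps_lm(self):
        rng = np.random.default_rng(5)
        age = rng.uniform(20, 80, 30)
        y = 0.02 + 1e-3 * age
        lm, qm = cw.fit_lm_qm(
            _table(age, rng.integers(0, 2, 30), rng.normal(500, 40, 30), y),
            ("cortex", "csff"),
        )
        res = cw.select_model(lm, qm)
        assert res.model == "LM"
        assert res.age_p_quadratic is None

    def test_f_statistic_matches_manual_rss_formula(self):
        rng = np.random.default_rng(6)
        t = _random_table(rng, n=50)
        lm, qm = cw.fit_lm_qm(t, ("cortex", "csff"))
        res = cw.select_model(lm, qm)
        f_manual = (lm.ssr - qm.ssr) / (qm.ssr / (50 - 5))
        assert res.anova_f == pytest.approx(f_manual, rel=1e-10)

    def test_type_one_error_calibrated(self):
        # linear truth: QM selection rate should approximate alpha
        n_sel = 0
        n_rep = 400
        for r in range(n_rep):
            rng = np.random.default_rng(10_000 + r)
            t = _random_table(rng, n=60)
            lm, qm = cw.fit_lm_qm(t, ("cortex", "csff"))
            n_sel += cw.select_model(lm, qm).model == "QM"
        rate = n_sel / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 3 * se


class TestFdrAdjust:
    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.uniform(0, 1, 9)
            adj = cw.fdr_adjust(p)
            # independent brute-force BH: sort, p*(m/i), cumulative min
            order = np.argsort(p)
            m = len(p)
            stepped = p[order] * m / np.arange(1, m + 1)
            stepped = np.minimum.accumulate(stepped[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(stepped, 1.0)
            np.testing.assert_allclose(adj, expected, rtol=1e-12)

    def test_equal_and_singleton(self):
        np.testing.assert_allclose(cw.fdr_adjust([0.03] * 9), 0.03)
        assert cw.fdr_adjust([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cw.fdr_adjust([0.1, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_adjusted_dominates_raw_and_preserves_order(self, pvals):
        p = np.array(pvals)
        adj = cw.fdr_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestBlandAltman:
    def test_identical_and_offset_pairs(self):
        r = cw.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.bias == 0 and r.loa_lower == 0 and r.loa_upper == 0
        r = cw.bland_altman([1.1, 2.1, 3.1], [1.0, 2.0, 3.0])
        assert r.bias == pytest.approx(0.1)
        assert r.sd == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computation(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0.1, 0.01, 30), rng.normal(0.1, 0.01, 30)
        r = cw.bland_altman(a, b)
        d = a - b
        assert r.bias == pytest.approx(d.mean())
        assert r.sd == pytest.approx(d.std(ddof=1))
        assert r.loa_upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        assert r.loa_lower <= r.bias <= r.loa_upper

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            cw.bland_altman([1.0], [2.0])


class TestSpearman:
    def test_monotone_sequences(self):
        x = np.arange(10.0)
        assert cw.spearman_corr(x, x**3)[0] == pytest.approx(1.0)
        assert cw.spearman_corr(x, -np.exp(x))[0] == pytest.approx(-1.0)

    def test_ties_match_average_rank_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 5, 40).astype(float)   # heavy ties
        y = rng.integers(0, 5, 40).astype(float)
        rho, _ = cw.spearman_corr(x, y)
        # brute-force: average ranks then Pearson
        def avg_rank(v):
            order = np.argsort(v, kind="stable")
            r = np.empty(len(v))
            sv = v[order]
            i = 0
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                r[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return r
        rx, ry = avg_rank(x), avg_rank(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, rel=1e-12)

    def test_zero_rank_variance_undefined(self):
        rho, p = cw.spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho) and np.isnan(p)


class TestConversions:
    def test_vcsf_worked_values(self):
        assert round(100 * cw.csff_to_vcsf(0.040, 0.83), 1) == 3.3
        assert round(100 * cw.csff_to_vcsf(0.050, 0.70), 1) == 3.5
        assert cw.csff_to_vcsf(0.0, 0.8) == 0.0

    def test_vcsf_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            cw.csff_to_vcsf(1.2, 0.8)

    def test_compartment_shift_worked_values(self):
        d_iewf, d_csff = cw.compartment_shift((0.05, 0.90, 0.05), 0.76)
        assert round(d_iewf, 1) == -1.6
        assert round(d_csff, 1) == 0.8

    def test_no_change_gives_zero_deltas(self):
        assert cw.compartment_shift((0.05, 0.90, 0.05), 0.90) == (0.0, 0.0)

    def test_matches_scalar_recomputation(self):
        mw, iew, csf, new = 0.05, 0.90, 0.05, 0.80
        d_iewf, d_csff = cw.compartment_shift((mw, iew, csf), new)
        assert d_iewf == pytest.approx((new / (mw + new + csf) - iew / 1.0) * 100)
        assert d_csff == pytest.approx((csf / (mw + new + csf) - csf / 1.0) * 100)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            cw.compartment_shift((0.0, 0.0, 0.0), 0.0)


class TestAnalyzeCohort:
    def test_nine_outcomes_with_fdr(self):
        t = cw.simulate_cohort(cw.default_cohort_spec(n_subjects=60, seed=3))
        summary, results = cw.analyze_cohort(t)
        assert len(summary) == 9
        assert np.all(summary["age_p_fdr"] >= summary["age_p"] - 1e-15)
        assert set(summary["model"]) <= {"LM", "QM"}

    def test_regressions_recover_generator_coefficients(self):
        # noise-free generator, volume effect off: the LM fit on a
        # linear outcome recovers the (renormalization-adjusted) trend
        spec = cw.default_cohort_spec(n_subjects=60, seed=4)
        spec.trends[("cerebral_wm", "csff")] = cw.Trend(0.05, 2e-4)
        t = cw.simulate_cohort(spec)
        lm, qm = cw.fit_lm_qm(t, ("cerebral_wm", "csff"))
        slope_se = lm.bse["age"]
        assert abs(lm.params["age"] - 2e-4) < 2 * slope_se
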