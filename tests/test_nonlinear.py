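import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardiomr.nonlinear import (FP_POWERS, build_grs, exposure_homogeneity_tests,
                                fracpoly_fit, nonlinearity_tests,
                                residual_exposure, stratify, stratum_lace)
from cardiomr.simulate import SimulationConfig, simulate_cohort


def make_lace_table(mean_exposure, lace, lace_se=0.002, beta_exp=None, se_exp=0.02):
    n = len(mean_exposure)
    return pd.DataFrame(dict(
        stratum=np.arange(n), n=2000, mean_exposure=mean_exposure,
        grs_exposure_beta=beta_exp if beta_exp is not None else np.full(n, 5.0),
        grs_exposure_se=np.full(n, se_exp),
        grs_outcome_beta=np.asarray(lace) * 5.0, grs_outcome_se=np.full(n, lace_se) * 5.0,
        lace=lace, lace_se=np.full(n, lace_se), excluded=False, reason="",
    ))


class TestGRS:
    def test_zero_weights(self):
        d = pd.DataFrame(np.ones((5, 3)), columns=["a", "b", "c"])
        assert np.all(build_grs(d, {"a": 0.0, "b": 0.0, "c": 0.0}) == 0)

    def test_single_variant_unit_scaling(self):
        d = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        np.testing.assert_allclose(build_grs(d, {"a": 5.0}, scale_bpm=5.0), [0, 1, 2])

    def test_noise_free_regression_returns_scale(self, rng):
        cfg = SimulationConfig(n_variants=10, n_exposure_cohort=2000,
                               noise_sd=0.0, exposure_h2=0.3, seed=4)
        c = simulate_cohort(cfg, "exposure")
        grs = build_grs(c.dosages, dict(zip(c.variant_meta["SNP"],
                                            c.variant_meta["beta_true"])), scale_bpm=5.0)
        slope = np.polyfit(grs, c.exposure, 1)[0]
        assert slope == pytest.approx(5.0, rel=1e-8)

    def test_missing_weights_warn_but_proceed(self):
        d = pd.DataFrame({"a": [0.0, 1.0]})
        out = build_grs(d, {"a": 5.0, "zz": 2.0})
        assert len(out) == 2


class TestResidualAndStrata:
    def test_orthogonal_to_score(self, rng):
        x = rng.normal(70, 10, 500)
        g = rng.normal(0, 1, 500)
        r = residual_exposure(x, g)
        assert abs(np.corrcoef(r, g)[0, 1]) < 1e-10
        assert r.var() <= x.var()

    def test_no_covariates_null_score(self, rng):
        x = rng.normal(70, 10, 300)
        r = residual_exposure(x, np.zeros(300) + 1e-9 * rng.normal(size=300))
        assert r.mean() == pytest.approx(0.0, abs=1e-8)

    def test_equal_count_strata(self, rng):
        r = rng.normal(size=3000)
        s = stratify(r, 30)
        assert np.all(np.bincount(s) == 100)
        s2 = stratify(rng.normal(size=3001), 30)
        assert set(np.bincount(s2)) <= {100, 101}

    def test_labels_increase_with_residual(self, rng):
        r = rng.normal(size=600)
        s = stratify(r, 6)
        means = [r[s == i].mean() for i in range(6)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            stratify(np.arange(10), 30)


class TestLACE:
    def test_constructed_arithmetic(self):
        t = make_lace_table([60.0] * 6, [0.05] * 6)
        assert np.allclose(t["lace"], t["grs_outcome_beta"] / t["grs_exposure_beta"])

    def test_linear_truth_recovered_across_strata(self):
        cfg = SimulationConfig(n_variants=25, n_outcome_cohort=30_000,
                               exposure_h2=0.3, causal_effect=0.2, seed=9)
        c = simulate_cohort(cfg, "outcome")
        grs = build_grs(c.dosages, dict(zip(c.variant_meta["SNP"],
                                            c.variant_meta["beta_true"])))
        resid = residual_exposure(c.exposure, grs)
        strata = stratify(resid, 10)
        t = stratum_lace(c.exposure, grs, strata, c.outcome_continuous)
        ok = np.abs(t["lace"] - 0.2) <= 3 * t["lace_se"]
        assert ok.mean() >= 0.9

    def test_small_stratum_excluded_with_reason(self, rng):
        n = 300
        x = rng.normal(70, 10, n)
        g = rng.normal(0, 1, n)
        strata = np.zeros(n, int)
        strata[:20] = 1  # undersized stratum
        t = stratum_lace(x, g, strata, rng.normal(size=n), min_stratum=50)
        assert t.set_index("stratum").loc[1, "excluded"]


class TestFracPoly:
    def test_constant_lace_selects_linear_curve(self):
        x = np.linspace(55, 90, 10)
        fit = fracpoly_fit(make_lace_table(x, np.full(10, 0.02)))
        grid = np.linspace(56, 89, 20)
        np.testing.assert_allclose(fit.effect(grid), 0.02 * (grid - 70), atol=1e-6)

    def test_candidate_power_set(self):
        x = np.linspace(55, 90, 8)
        fit = fracpoly_fit(make_lace_table(x, 0.001 * x))
        assert fit.candidate_powers == (-2.0, -1.0, 0.0, 0.5, 1.0, 2.0, 3.0)
        assert FP_POWERS == (-2.0, -1.0, 0.0, 0.5, 1.0, 2.0, 3.0)

    def test_curve_anchored_at_reference(self, rng):
        x = np.linspace(55, 90, 12)
        lace = 0.01 + 0.0005 * x + rng.normal(0, 0.0005, 12)
        fit = fracpoly_fit(make_lace_table(x, lace))
        assert fit.effect(70.0) == pytest.approx(0.0, abs=1e-12)

    def test_reference_shift_moves_curve_vertically(self, rng):
        x = np.linspace(55, 90, 12)
        lace = 0.02 + 0.0004 * x + rng.normal(0, 0.0005, 12)
        t = make_lace_table(x, lace)
        fit70 = fracpoly_fit(t, reference=70.0)
        fit80 = fracpoly_fit(t, reference=80.0)
        grid = np.linspace(56, 89, 15)
        shift = fit70.effect(80.0)
        np.testing.assert_allclose(fit80.effect(grid), fit70.effect(grid) - shift,
                                   atol=1e-8)

    def test_degree1_power1_matches_ivw_of_lace(self, rng):
        x = np.linspace(55, 90, 20)
        lace = rng.normal(0.02, 0.0005, 20)
        se = rng.uniform(0.001, 0.004, 20)
        t = make_lace_table(x, lace, lace_se=0.002)
        t["lace_se"] = se
        fit = fracpoly_fit(t)
        w = 1 / se**2
        ivw_mean = (w * lace).sum() / w.sum()
        if fit.degree == 1 and fit.powers == (1.0,):
            assert fit.coefficients[0] == pytest.approx(ivw_mean, rel=1e-8)
        # regardless of selection, the power-1 degree-1 fit must equal it
        from cardiomr.nonlinear import _fp_terms, _wls_known_var
        D = np.column_stack([d(x - 45.0) for _, d in _fp_terms(1.0)])
        coef, _, _ = _wls_known_var(D, np.asarray(lace), w)
        assert coef[0] == pytest.approx(ivw_mean, rel=1e-8)

    def test_quadratic_truth_detected(self):
        x = np.linspace(55, 90, 30)
        lace = 0.001 * (x - 45)  # derivative proportional to exposure
        fit = fracpoly_fit(make_lace_table(x, lace, lace_se=0.0005))
        assert fit.p_fracpoly < 0.05
        # fitted derivative is non-constant
        eff = fit.effect(np.array([60.0, 75.0, 89.0]))
        d1 = (eff[1] - eff[0]) / 15
        d2 = (eff[2] - eff[1]) / 14
        assert abs(d2 - d1) > 1e-4

    def test_offset_violation_raises(self):
        x = np.linspace(30, 90, 10)  # values below the 45 offset
        with pytest.raises(ValueError, match="offset"):
            fracpoly_fit(make_lace_table(x, np.full(10, 0.02)))

    def test_end_to_end_linear_curve_recovery(self):
        # full pipeline at n=100k: effect(x) = 0.01 (x - 70) recovered within
        # 0.005 everywhere on 55..90
        from cardiomr.simulate import OutcomeModel

        cfg = SimulationConfig(n_variants=25, n_outcome_cohort=100_000,
                               exposure_h2=0.3, causal_effect=0.01,
                               outcome_model=OutcomeModel(noise_sd=0.15), seed=17)
        c = simulate_cohort(cfg, "outcome")
        grs = build_grs(c.dosages, dict(zip(c.variant_meta["SNP"],
                                            c.variant_meta["beta_true"])))
        resid = residual_exposure(c.exposure, grs)
        strata = stratify(resid, 30)
        t = stratum_lace(c.exposure, grs, strata, c.outcome_continuous)
        fit = fracpoly_fit(t)
        grid = np.linspace(55, 90, 36)
        err = np.abs(fit.effect(grid) - 0.01 * (grid - 70))
        assert err.max() < 0.005


class TestNonlinearityTests:
    def test_identical_lace_gives_q_zero(self):
        x = np.linspace(55, 90, 10)
        t = make_lace_table(x, np.full(10, 0.02))
        fit = fracpoly_fit(t)
        p_trend, p_q, p_fp = nonlinearity_tests(t, fit)
        assert p_q == pytest.approx(1.0)

    def test_exposure_homogeneity_on_equal_coefficients(self):
        x = np.linspace(55, 90, 10)
        t = make_lace_table(x, np.full(10, 0.02), beta_exp=np.full(10, 5.0))
        p_trend, p_q = exposure_homogeneity_tests(t)
        assert p_q == pytest.approx(1.0)

    def test_exposure_heterogeneity_detected(self):
        x = np.linspace(55, 90, 30)
        beta_exp = np.where(x > 72, 10.0, 5.0)  # doubled in the top half
        t = make_lace_table(x, np.full(30, 0.02), beta_exp=beta_exp, se_exp=0.05)
        p_trend, p_q = exposure_homogeneity_tests(t)
        assert p_trend < 0.05 and p_q < 0.05

    def test_grs_homogeneous_across_residual_strata(self):
        # residual stratification must not distort the score distribution
        rng = np.random.default_rng(31)
        nonsig = 0
        n_rep = 50
        for _ in range(n_rep):
            cfg = SimulationConfig(n_variants=5, n_exposure_cohort=2000,
                                   exposure_h2=0.2, seed=int(rng.integers(2**31)))
            c = simulate_cohort(cfg, "exposure")
            grs = build_grs(c.dosages, dict(zip(c.variant_meta["SNP"],
                                                c.variant_meta["beta_true"])))
            resid = residual_exposure(c.exposure, grs)
            strata = stratify(resid, 10)
            groups = [grs[strata == i] for i in range(10)]
            _, p = stats.f_oneway(*groups)
            nonsig += p >= 0.05
        assert nonsig / n_rep >= 0.92


@pytest.fixture
def rng():
    return np.random.default_rng(55)
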