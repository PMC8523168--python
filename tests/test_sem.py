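import numpy as np
import pandas as pd
import pytest

from conftest import make_latent_indicator_data
from invasim.sem import (SemModelSpec, build_mediation_models, compare_models,
                         fit_sem, mediation_decomposition)


def _standard_models(n_c=3, n_p=2, n_i=3):
    return build_mediation_models([f"c{j}" for j in range(n_c)],
                                  [f"p{j}" for j in range(n_p)],
                                  [f"i{j}" for j in range(n_i)])


class TestModelSpecs:
    def test_partial_has_one_fewer_df_than_complete(self):
        models = _standard_models()
        assert models["partial_mediation"].degrees_of_freedom() == \
            models["complete_mediation"].degrees_of_freedom() - 1

    def test_no_mediation_lacks_productivity_paths(self):
        spec = _standard_models()["no_mediation"]
        assert spec.paths == [("C", "I")]

    def test_single_indicator_latent_rejected(self):
        with pytest.raises(ValueError):
            build_mediation_models(["c0", "c1"], ["p0"], ["i0", "i1"])

    def test_cyclic_paths_rejected(self):
        with pytest.raises(ValueError):
            SemModelSpec("cyclic", {"C": ["c0", "c1"], "P": ["p0", "p1"]},
                         [("C", "P"), ("P", "C")])

    def test_indicator_on_two_latents_rejected(self):
        with pytest.raises(ValueError):
            SemModelSpec("bad", {"C": ["x", "c1"], "P": ["x", "p1"]},
                         [("C", "P")])


class TestFit:
    def test_perfect_fit_when_sample_cov_is_implied_cov(self):
        # build Sigma(theta0) by hand and hand it over as the sample cov
        lam = np.array([[1.0, 0.0], [0.8, 0.0], [0.0, 1.0], [0.0, 0.7]])
        B = np.array([[0.0, 0.0], [0.5, 0.0]])
        psi = np.diag([1.0, 0.75])
        theta = np.diag([0.3, 0.4, 0.35, 0.5])
        A = np.linalg.inv(np.eye(2) - B)
        sigma0 = lam @ A @ psi @ A.T @ lam.T + theta
        spec = SemModelSpec("two_factor", {"C": ["c0", "c1"], "P": ["p0", "p1"]},
                            [("C", "P")])
        fit = fit_sem(spec, sample_cov=sigma0, n=500)
        assert fit.fmin < 1e-8
        assert fit.chi2 < 1e-5
        np.testing.assert_allclose(fit.implied_cov, sigma0, atol=1e-6)

    def test_single_indicator_paths_match_ols_oracle(self):
        # three observed z-scored variables as error-free single-indicator
        # latents: standardised paths must equal the closed-form
        # standardised regression coefficients from the correlation matrix
        rng = np.random.default_rng(0)
        n = 400
        C = rng.standard_normal(n)
        P = 0.6 * C + 0.8 * rng.standard_normal(n)
        I = -0.5 * P - 0.2 * C + 0.7 * rng.standard_normal(n)
        data = pd.DataFrame({"C_obs": C, "P_obs": P, "I_obs": I})
        data = (data - data.mean()) / data.std()
        spec = SemModelSpec(
            "path_analysis",
            {"C": ["C_obs"], "P": ["P_obs"], "I": ["I_obs"]},
            [("C", "P"), ("P", "I"), ("C", "I")],
            fixed_residuals={"C_obs": 0.0, "P_obs": 0.0, "I_obs": 0.0})
        fit = fit_sem(spec, data)
        R = data.corr().to_numpy()
        a_hat = R[0, 1]
        coef = np.linalg.solve(R[:2, :2], R[:2, 2])
        assert fit.std_paths[("C", "P")] == pytest.approx(a_hat, abs=1e-6)
        assert fit.std_paths[("C", "I")] == pytest.approx(coef[0], abs=1e-6)
        assert fit.std_paths[("P", "I")] == pytest.approx(coef[1], abs=1e-6)

    def test_parameter_recovery_partial_model(self):
        errs = []
        for seed in range(20):
            data, cc, cp, ci = make_latent_indicator_data(
                0.5, -0.6, -0.15, n=680, seed=seed)
            models = build_mediation_models(cc, cp, ci)
            fit = fit_sem(models["partial_mediation"], data)
            errs.append([fit.std_paths[("C", "P")] - 0.5,
                         fit.std_paths[("P", "I")] + 0.6,
                         fit.std_paths[("C", "I")] + 0.15])
        assert np.abs(np.mean(errs, axis=0)).max() < 0.08

    def test_indicator_rescaling_leaves_standardised_solution(self):
        data, cc, cp, ci = make_latent_indicator_data(0.5, -0.5, -0.2,
                                                      n=500, seed=3)
        models = build_mediation_models(cc, cp, ci)
        fit1 = fit_sem(models["partial_mediation"], data)
        scaled = data.copy()
        scaled[cc[1]] *= 10.0
        scaled[ci[0]] *= 0.1
        fit2 = fit_sem(models["partial_mediation"], scaled)
        for key in fit1.std_paths:
            assert fit1.std_paths[key] == pytest.approx(fit2.std_paths[key],
                                                        abs=1e-6)

    def test_nesting_monotonicity_of_chi2(self):
        for seed in range(5):
            data, cc, cp, ci = make_latent_indicator_data(
                0.4, -0.4, -0.2, n=300, seed=100 + seed, n_i=3)
            models = build_mediation_models(cc, cp, ci)
            chi_p = fit_sem(models["partial_mediation"], data).chi2
            chi_c = fit_sem(models["complete_mediation"], data).chi2
            assert chi_c >= chi_p - 1e-6

    def test_saturated_three_indicator_model_recovers_cov(self):
        # a one-latent, three-indicator model is just-identified: chi2 ~ 0
        rng = np.random.default_rng(1)
        L = rng.standard_normal(200)
        data = pd.DataFrame({f"x{j}": 0.8 * L + 0.6 * rng.standard_normal(200)
                             for j in range(3)})
        spec = SemModelSpec("one_factor", {"F": ["x0", "x1", "x2"]}, [])
        fit = fit_sem(spec, data)
        assert fit.df == 0
        assert fit.chi2 < 1e-6
        np.testing.assert_allclose(fit.implied_cov, fit.sample_cov, atol=1e-5)

    def test_needs_more_samples_than_indicators(self):
        data, cc, cp, ci = make_latent_indicator_data(0.5, -0.5, 0.0, n=10,
                                                      seed=0)
        models = build_mediation_models(cc, cp, ci)
        with pytest.raises(ValueError):
            fit_sem(models["partial_mediation"], data)


class TestCompare:
    def test_identical_fits_have_zero_delta_aicc(self):
        data, cc, cp, ci = make_latent_indicator_data(0.5, -0.5, -0.2,
                                                      n=300, seed=5, n_i=3)
        models = _standard_models()
        f1 = fit_sem(models["partial_mediation"], data)
        f2 = fit_sem(models["partial_mediation"], data)
        out = compare_models({"a": f1, "b": f2})
        assert out["table"]["delta_aicc"].abs().max() < 1e-8

    def test_lrt_between_partial_and_complete(self):
        data, cc, cp, ci = make_latent_indicator_data(0.5, -0.5, -0.3,
                                                      n=680, seed=6)
        models = build_mediation_models(cc, cp, ci)
        fits = {k: fit_sem(m, data) for k, m in models.items()}
        out = compare_models(fits)
        lrt = out["lrt"]
        assert lrt["df"] == 1
        assert lrt["stat"] >= 0
        assert 0.0 <= lrt["p_value"] <= 1.0

    def test_non_nested_lrt_rejected(self):
        data, cc, cp, ci = make_latent_indicator_data(0.5, -0.5, -0.2,
                                                      n=300, seed=7, n_i=3)
        models = _standard_models()
        f_partial = fit_sem(models["partial_mediation"], data)
        fits = {"partial_mediation": f_partial, "complete_mediation": f_partial}
        with pytest.raises(ValueError):
            compare_models(fits)

    def test_different_data_rejected(self):
        d1, cc, cp, ci = make_latent_indicator_data(0.5, -0.5, -0.2, n=300,
                                                    seed=8, n_i=3)
        d2, *_ = make_latent_indicator_data(0.5, -0.5, -0.2, n=200, seed=9,
                                            n_i=3)
        models = _standard_models()
        fits = {"a": fit_sem(models["partial_mediation"], d1),
                "b": fit_sem(models["partial_mediation"], d2)}
        with pytest.raises(ValueError):
            compare_models(fits)


class TestMediationDecomposition:
    def test_printed_convention_from_published_coefficients(self):
        dec = mediation_decomposition(a=0.47, b=-0.63, direct_ci=-0.13,
                                      direct_pi=-0.33)
        assert round(dec.indirect, 2) == pytest.approx(-0.30)
        assert dec.proportion_mediated_printed == pytest.approx(0.48)
        assert dec.total_productivity_printed == pytest.approx(-0.63)
        assert dec.total_composition_printed == pytest.approx(-0.43)

    def test_zero_a_gives_zero_indirect(self):
        dec = mediation_decomposition(a=0.0, b=-0.5, direct_ci=-0.3)
        assert dec.indirect == 0.0
        assert dec.proportion_mediated == 0.0

    def test_zero_total_gives_nan_sentinel(self):
        dec = mediation_decomposition(a=0.5, b=-0.4, direct_ci=0.2)
        assert np.isnan(dec.proportion_mediated)

    def test_from_fit_uses_standardised_paths(self):
        data, cc, cp, ci = make_latent_indicator_data(0.5, -0.5, -0.2,
                                                      n=680, seed=10)
        models = build_mediation_models(cc, cp, ci)
        fit = fit_sem(models["partial_mediation"], data)
        dec = mediation_decomposition(fit)
        assert dec.a == pytest.approx(fit.std_paths[("C", "P")])
        assert dec.indirect == pytest.approx(dec.a * dec.b)
        truth = (0.5 * -0.5) / (-0.2 + 0.5 * -0.5)
        assert dec.proportion_mediated == pytest.approx(truth, abs=0.15)

    def test_wrong_structure_rejected(self):
        data, cc, cp, ci = make_latent_indicator_data(0.5, -0.5, -0.2,
                                                      n=300, seed=11, n_i=3)
        models = _standard_models()
        fit = fit_sem(models["complete_mediation"], data)
        with pytest.raises(ValueError):
            mediation_decomposition(fit)
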