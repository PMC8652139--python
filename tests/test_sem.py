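"""Maximum-likelihood fitting of the 3-node path model and its fit indices."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from perturbsem import (
    PathModel,
    PathModelSpec,
    SEMData,
    SEMTruth,
    baseline_model,
    fit_indices,
    fit_path_model,
    implied_covariance,
    render_model_figure,
    rmsea_ci,
    simulate_sem_dataset,
)
from perturbsem.sem import SATURATED, discrepancy


def _numeric_ml_oracle(S, spec, x0=None):
    """Independent route: minimise the discrepancy with a generic optimiser."""
    free_gamma = [spec.free_gamma11, spec.free_gamma21]

    def unpack(th):
        v1, v2 = np.exp(th[0]), np.exp(th[1])
        i = 2
        if spec.free_exo_covariance:
            c = th[i]; i += 1
        else:
            c = 0.0
        g = [0.0, 0.0]
        for j in range(2):
            if free_gamma[j]:
                g[j] = th[i]; i += 1
        psi = np.exp(th[i])
        return v1, v2, c, g[0], g[1], psi

    def obj(th):
        try:
            return discrepancy(S, implied_covariance(*unpack(th)))
        except Exception:
            return 1e6

    k = 3 + spec.free_exo_covariance + sum(free_gamma)
    x0 = np.zeros(k) if x0 is None else x0
    res = optimize.minimize(obj, x0, method="Nelder-Mead",
                            options=dict(xatol=1e-12, fatol=1e-15, maxiter=50000))
    return unpack(res.x), res.fun


def _random_data(rng, n=60):
    X = rng.normal(size=(n, 3)) @ rng.normal(size=(3, 3))
    return SEMData(X[:, 0], X[:, 1], X[:, 2])


class TestSaturatedModel:
    def test_gamma_equals_ols_coefficients(self, rng):
        """The saturated path model reproduces S, so the paths are the
        multiple-regression coefficients of endpoint on (fac1, fac2)."""
        for _ in range(5):
            data = _random_data(rng)
            fit = fit_path_model(data)
            X = np.column_stack([data.fac1, data.fac2])
            Xc = X - X.mean(0)
            yc = data.endpoint - data.endpoint.mean()
            beta = np.linalg.lstsq(Xc, yc, rcond=None)[0]
            assert fit.gamma11 == pytest.approx(beta[0], abs=1e-8)
            assert fit.gamma21 == pytest.approx(beta[1], abs=1e-8)
            resid = yc - Xc @ beta
            assert fit.resid_var == pytest.approx(resid @ resid / (data.n - 1), rel=1e-8)

    def test_perfect_fit_identities(self, rng):
        data = _random_data(rng)
        fit = fit_path_model(data)
        np.testing.assert_allclose(fit.implied_cov, fit.sample_cov, atol=1e-10)
        assert fit.chisq == pytest.approx(0.0, abs=1e-10)
        assert fit.df_model == 0
        assert fit.cfi == 1.0 and fit.tli == 1.0
        assert fit.rmsea == 0.0 and fit.rmsea_ci90 == (0.0, 0.0)
        assert fit.srmr == pytest.approx(0.0, abs=1e-10)

    def test_near_noiseless_regression_recovered(self, rng):
        """endpoint ~ 0.5*fac1 with (almost) no residual noise."""
        n = 200
        fac1 = rng.normal(size=n)
        fac2 = rng.normal(size=n)
        endpoint = 0.5 * fac1 + rng.normal(0.0, 1e-4, n)
        fit = fit_path_model(SEMData(fac1, fac2, endpoint))
        assert fit.gamma11 == pytest.approx(0.5, abs=1e-3)
        assert fit.gamma21 == pytest.approx(0.0, abs=1e-3)
        assert fit.resid_var == pytest.approx(0.0, abs=1e-6)

    def test_exactly_collinear_data_raises_rank_error(self, rng):
        fac1 = rng.normal(size=50)
        fac2 = rng.normal(size=50)
        with pytest.raises(np.linalg.LinAlgError):
            PathModel(SEMData(fac1, fac2, 0.5 * fac1))


class TestConstrainedModels:
    @pytest.mark.parametrize(
        "spec",
        [
            PathModelSpec(free_gamma21=False),
            PathModelSpec(free_gamma11=False),
            PathModelSpec(free_exo_covariance=False),
            PathModelSpec(free_gamma21=False, free_exo_covariance=False),
        ],
        ids=["fix_g21", "fix_g11", "fix_cov", "fix_g21_cov"],
    )
    def test_closed_form_matches_numeric_optimiser(self, rng, spec):
        data = _random_data(rng, n=80)
        model = PathModel(data, spec)
        fit = model.fit()
        (_, _, c, g1, g2, _), f_num = _numeric_ml_oracle(model.S, spec)
        f_closed = fit.chisq / (data.n - 1)
        assert f_closed == pytest.approx(f_num, abs=1e-8)
        assert fit.gamma11 == pytest.approx(g1, abs=1e-5)
        assert fit.gamma21 == pytest.approx(g2, abs=1e-5)
        assert fit.exo_cov == pytest.approx(c, abs=1e-5)
        assert fit.df_model == 6 - spec.n_free

    def test_parameter_recovery_large_n(self):
        truth = SEMTruth(gamma11=0.5, gamma21=0.3, exo_corr=0.4, resid_var=0.5,
                         n=10_000, seed=42)
        fit = fit_path_model(simulate_sem_dataset(truth))
        for name, true in (("gamma11", 0.5), ("gamma21", 0.3), ("exo_cov", 0.4),
                           ("resid_var", 0.5)):
            est, se = fit.params[name], fit.bse[name]
            assert abs(est - true) < 3 * se, f"{name}: {est} vs {true} (se {se})"

    def test_constrained_statistic_is_chi_square_1(self):
        """Data generated with gamma21 = 0, fitted with it fixed: the test
        statistic follows chi-square(1)."""
        spec = PathModelSpec(free_gamma21=False)
        stats_t = []
        for seed in range(500):
            truth = SEMTruth(gamma11=0.5, gamma21=0.0, exo_corr=0.4,
                             resid_var=0.5, n=200, seed=seed)
            stats_t.append(PathModel(simulate_sem_dataset(truth), spec).fit().chisq)
        ks = stats.kstest(stats_t, stats.chi2(1).cdf)
        assert ks.pvalue > 0.01

    def test_wald_pvalue_is_two_sided_normal(self, rng):
        data = _random_data(rng)
        fit = fit_path_model(data)
        for name in fit.free_names:
            z = fit.params[name] / fit.bse[name]
            assert fit.pvalues[name] == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)


class TestBaselineModel:
    def test_diagonal_s_gives_zero(self):
        chisq_b, df_b = baseline_model(np.diag([1.0, 2.0, 3.0]), n=100)
        assert chisq_b == pytest.approx(0.0, abs=1e-10)
        assert df_b == 3

    def test_matches_direct_discrepancy_evaluation(self, rng):
        for _ in range(5):
            A = rng.normal(size=(3, 3))
            S = A @ A.T + np.eye(3)
            n = int(rng.integers(20, 500))
            chisq_b, df_b = baseline_model(S, n)
            # independent re-evaluation of F at Sigma = diag(S)
            D = np.diag(np.diag(S))
            f = (np.log(np.linalg.det(D)) + np.trace(S @ np.linalg.inv(D))
                 - np.log(np.linalg.det(S)) - 3)
            assert chisq_b == pytest.approx((n - 1) * f, rel=1e-10)
            assert df_b == 3


class TestFitIndices:
    def test_closed_form_rmsea(self):
        rmsea, ci, cfi, tli, srmr = fit_indices(
            10.0, 4, 80.0, 3, 101, np.eye(3), np.eye(3)
        )
        assert rmsea == pytest.approx(np.sqrt(6.0 / 400.0), abs=1e-12)

    def test_truncation_when_statistic_below_df(self):
        rmsea, _, cfi, _, _ = fit_indices(2.0, 4, 80.0, 3, 101, np.eye(3), np.eye(3))
        assert rmsea == 0.0 and cfi == 1.0

    def test_saturated_degeneracy(self):
        rmsea, ci, cfi, tli, srmr = fit_indices(
            0.0, 0, 50.0, 3, 101, np.eye(3), np.eye(3)
        )
        assert (rmsea, ci, cfi, tli, srmr) == (0.0, (0.0, 0.0), 1.0, 1.0, 0.0)

    def test_indices_invariant_to_variable_rescaling(self, rng):
        data = _random_data(rng, n=120)
        spec = PathModelSpec(free_gamma21=False)
        fit1 = PathModel(data, spec).fit()
        scaled = SEMData(data.fac1 * 3.0, data.fac2 * 0.2, data.endpoint * 11.0)
        fit2 = PathModel(scaled, spec).fit()
        for attr in ("chisq", "rmsea", "cfi", "tli", "srmr"):
            assert getattr(fit1, attr) == pytest.approx(getattr(fit2, attr), abs=1e-6)
        np.testing.assert_allclose(fit1.rmsea_ci90, fit2.rmsea_ci90, atol=1e-6)


class TestRmseaCI:
    def test_saturated_convention(self):
        assert rmsea_ci(0.0, 0, 100) == (0.0, 0.0)

    def test_brackets_point_estimate(self, rng):
        for _ in range(20):
            T = float(rng.uniform(0.0, 30.0))
            df = int(rng.integers(1, 6))
            n = int(rng.integers(20, 1000))
            lo, hi = rmsea_ci(T, df, n)
            point = np.sqrt(max(T - df, 0) / (df * (n - 1)))
            assert lo - 1e-12 <= point <= hi + 1e-12

    def test_endpoints_round_trip_noncentral_cdf(self, rng):
        """Inverted noncentrality values reproduce the target CDF levels."""
        for _ in range(20):
            T = float(rng.uniform(2.0, 40.0))
            df = int(rng.integers(1, 6))
            n = int(rng.integers(20, 500))
            lo, hi = rmsea_ci(T, df, n)
            for r, target in ((lo, 0.95), (hi, 0.05)):
                lam = r**2 * df * (n - 1)
                if lam <= 0:
                    assert stats.chi2.cdf(T, df) <= target + 1e-6
                else:
                    assert stats.ncx2.cdf(T, df, lam) == pytest.approx(target, abs=1e-6)


class TestResultsInterface:
    def test_from_dataframe_and_summary(self, rng):
        df = pd.DataFrame(
            {"a": rng.normal(size=30), "b": rng.normal(size=30), "y": rng.normal(size=30)}
        )
        fit = PathModel.from_dataframe(df, "a", "b", "y").fit()
        text = fit.summary()
        for token in ("gamma11", "RMSEA", "CFI", "SRMR", "chi-square"):
            assert token in text
        d = fit.to_dict()
        for key in ("gamma11", "se_gamma11", "p_gamma11", "rmsea_ci90_lo", "srmr"):
            assert key in d

    def test_statistic_selector(self, rng):
        fit = fit_path_model(_random_data(rng))
        assert fit.statistic("gamma11") == fit.gamma11
        assert fit.statistic("cfi") == fit.cfi
        with pytest.raises(KeyError):
            fit.statistic("nonsense")


class TestModelFigure:
    def test_saturated_figure_has_two_paths_and_covariance_arc(self, rng, tmp_path):
        fit = fit_path_model(_random_data(rng))
        out = tmp_path / "model.svg"
        render_model_figure(fit, out)
        svg = out.read_text()
        assert 'id="path_gamma11"' in svg and 'id="path_gamma21"' in svg
        assert 'id="exo_covariance"' in svg

    def test_fixed_path_absent(self, rng, tmp_path):
        data = _random_data(rng)
        fit = PathModel(data, PathModelSpec(free_gamma21=False)).fit()
        out = tmp_path / "model.svg"
        render_model_figure(fit, out)
        svg = out.read_text()
        assert 'id="path_gamma21"' not in svg and 'id="path_gamma11"' in svg
        assert out.stat().st_size > 0
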