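"""Implied covariance, the ML discrepancy, and fitting against independent oracles."""

import math

import numpy as np
import pytest
from scipy import optimize

import semnet as sn


def _random_pd(rng, p):
    a = rng.standard_normal((p + 3, p))
    return np.cov(a, rowvar=False)


class TestImpliedCovariance:
    def test_pure_exogenous_model_is_diagonal(self):
        genes = tuple(f"g{i}" for i in range(7))
        m = sn.PathModel(genes, ())
        phis = {g: float(i + 1) for i, g in enumerate(genes)}
        theta = sn.ParameterSet({}, phis, {}, {})
        sigma = sn.implied_covariance(m, theta)
        assert np.allclose(sigma, np.diag([phis[g] for g in genes]))

    @pytest.mark.parametrize(
        "gamma,expected",
        [(0.0, [[4.0, 0.0], [0.0, 2.0]]), (0.5, [[4.0, 2.0], [2.0, 3.0]])],
    )
    def test_single_path_blocks(self, gamma, expected):
        # cov(x,y) = gamma*phi, var(y) = gamma^2*phi + psi
        m = sn.PathModel(("x", "y"), (("x", "y"),))
        theta = sn.ParameterSet({("x", "y"): gamma}, {"x": 4.0}, {}, {"y": 2.0})
        assert np.allclose(sn.implied_covariance(m, theta), expected)

    def test_symmetry_for_random_parameters(self, cegs_baseline):
        rng = np.random.default_rng(3)
        for _ in range(10):
            theta = sn.ParameterSet(
                {p: float(rng.normal(0, 1)) for p in cegs_baseline.paths},
                {g: float(rng.uniform(0.5, 3)) for g in cegs_baseline.exogenous},
                {},
                {g: float(rng.uniform(0.5, 3)) for g in cegs_baseline.endogenous},
            )
            sigma = sn.implied_covariance(cegs_baseline, theta)
            assert np.allclose(sigma, sigma.T)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            sn.ParameterSet({("x", "y"): 0.5}, {"x": -1.0}, {}, {"y": 1.0})


class TestMLDiscrepancy:
    def test_zero_iff_equal(self):
        rng = np.random.default_rng(0)
        for p in (2, 3, 6):
            s = _random_pd(rng, p)
            assert sn.ml_discrepancy(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_by_two(self):
        # tr(S Sigma^-1) = 2 exactly, so F = ln|Sigma| - ln|S| = ln(12/8)
        s = np.array([[4.0, 2.0], [2.0, 3.0]])
        sigma = np.diag([4.0, 3.0])
        assert sn.ml_discrepancy(s, sigma) == pytest.approx(math.log(1.5), abs=1e-12)

    def test_identity_pair(self):
        assert sn.ml_discrepancy(np.eye(3), np.eye(3)) == 0.0

    def test_nonnegative_on_random_pd_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = int(rng.integers(2, 7))
            assert sn.ml_discrepancy(_random_pd(rng, p), _random_pd(rng, p)) >= 0.0

    def test_singular_sigma_raises(self):
        with pytest.raises(sn.NotPositiveDefiniteError):
            sn.ml_discrepancy(np.eye(2), np.ones((2, 2)))


class TestFitModel:
    def test_saturated_two_variable_closed_form(self):
        # gamma-hat = s_xy/s_xx, psi-hat = s_yy - s_xy^2/s_xx
        m = sn.PathModel(("x", "y"), (("x", "y"),))
        s = np.array([[4.0, 2.0], [2.0, 3.0]])
        mom = sn.SampleMoments(s, np.zeros(2), 100, ("x", "y"))
        fit = sn.fit_model(m, mom)
        assert fit.theta.path_coefficients[("x", "y")] == pytest.approx(0.5)
        assert fit.theta.exo_variances["x"] == pytest.approx(4.0)
        assert fit.theta.residual_variances["y"] == pytest.approx(2.0)
        assert fit.stats.chi_square == pytest.approx(0.0, abs=1e-10)
        assert fit.stats.df == 0
        assert fit.stats.gfi == pytest.approx(1.0)
        assert fit.stats.pgfi == pytest.approx(0.0)
        assert math.isnan(fit.stats.agfi)

    def test_exact_fit_recovers_generating_parameters(self, chain_model):
        theta0 = sn.ParameterSet(
            {("x", "y"): 0.7, ("y", "z"): -0.4}, {"x": 2.0}, {}, {"y": 1.0, "z": 0.5}
        )
        sigma0 = sn.implied_covariance(chain_model, theta0)
        mom = sn.SampleMoments(sigma0, np.zeros(3), 500, ("x", "y", "z"))
        fit = sn.fit_model(chain_model, mom)
        assert fit.stats.f_ml == pytest.approx(0.0, abs=1e-12)
        for name, v in theta0.as_flat_dict().items():
            assert fit.theta.as_flat_dict()[name] == pytest.approx(v, abs=1e-9)

    def test_matches_brute_force_minimizer(self):
        """Two-parent regression with diagonal Phi on correlated regressors:
        the 5-parameter F_ML surface has a unique minimum the fit must hit."""
        m = sn.PathModel(("x1", "x2", "y"), (("x1", "y"), ("x2", "y")))
        s = np.array([[1.0, 0.8, 0.5], [0.8, 1.2, 0.4], [0.5, 0.4, 1.5]])
        mom = sn.SampleMoments(s, np.zeros(3), 200, ("x1", "x2", "y"))
        fit = sn.fit_model(m, mom)

        def objective(x):
            g1, g2, lp1, lp2, lps = x
            theta = sn.ParameterSet(
                {("x1", "y"): g1, ("x2", "y"): g2},
                {"x1": math.exp(lp1), "x2": math.exp(lp2)}, {},
                {"y": math.exp(lps)},
            )
            return sn.ml_discrepancy(s, sn.implied_covariance(m, theta))

        # independent route: coarse grid then local refinement
        best = None
        for g1 in np.linspace(-1, 1, 5):
            for g2 in np.linspace(-1, 1, 5):
                res = optimize.minimize(
                    objective, [g1, g2, 0.0, 0.0, 0.0], method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000},
                )
                if best is None or res.fun < best.fun:
                    best = res
        assert fit.stats.f_ml == pytest.approx(best.fun, abs=1e-8)
        assert fit.theta.path_coefficients[("x1", "y")] == pytest.approx(best.x[0], abs=1e-4)
        assert fit.theta.path_coefficients[("x2", "y")] == pytest.approx(best.x[1], abs=1e-4)
        assert fit.theta.exo_variances["x1"] == pytest.approx(math.exp(best.x[2]), abs=1e-4)
        assert fit.theta.residual_variances["y"] == pytest.approx(math.exp(best.x[4]), abs=1e-4)

    def test_full_covariance_coefficients_equal_ols(self):
        """Classical recursive-system result: with all exogenous covariances
        free, ML path coefficients equal per-equation least squares computed
        directly from the raw data."""
        m = sn.build_baseline(population="cegs", covariance_variant="full")
        theta = sn.default_parameters(m, exo_covariance=0.3)
        config = sn.SimulationConfig(model=m, parameters=theta, n=400, seed=9)
        data, _ = sn.generate_grn_dataset(config)
        fit = sn.fit_model(m, sn.SampleMoments.from_data(data))
        x = data.to_numpy()
        cols = {g: i for i, g in enumerate(data.columns)}
        for g in m.endogenous:
            parents = m.parents[g]
            design = np.column_stack(
                [np.ones(len(data))] + [x[:, cols[q]] for q in parents])
            beta = np.linalg.lstsq(design, x[:, cols[g]], rcond=None)[0]
            for q, b in zip(parents, beta[1:]):
                assert fit.theta.path_coefficients[(q, g)] == pytest.approx(b, abs=1e-6)

    def test_recovery_at_large_n_within_5pct(self, chain_model):
        theta0 = sn.ParameterSet(
            {("x", "y"): 0.6, ("y", "z"): 0.8}, {"x": 1.5}, {}, {"y": 1.0, "z": 2.0}
        )
        config = sn.SimulationConfig(model=chain_model, parameters=theta0,
                                     n=10_000, seed=77)
        data, _ = sn.generate_grn_dataset(config)
        fit = sn.fit_model(chain_model, sn.SampleMoments.from_data(data))
        report = sn.parameter_recovery_report(theta0, fit)
        assert (report["relative_error"] < 0.05).all()

    def test_missing_gene_raises(self, chain_model):
        mom = sn.SampleMoments(np.eye(2), np.zeros(2), 50, ("x", "y"))
        with pytest.raises(KeyError):
            sn.fit_model(chain_model, mom)

    def test_deterministic(self, cegs_baseline, cegs_moments):
        f1 = sn.fit_model(cegs_baseline, cegs_moments)
        f2 = sn.fit_model(cegs_baseline, cegs_moments)
        assert f1.theta.as_flat_dict() == f2.theta.as_flat_dict()
        assert f1.stats.bic == f2.stats.bic


class TestFitStatistics:
    def test_cegs_baseline_degrees_of_freedom(self, cegs_baseline, cegs_moments):
        # p=12 observed variables: 78 moments, 26 free parameters
        fit = sn.fit_model(cegs_baseline, cegs_moments)
        assert fit.stats.t == 26
        assert fit.stats.df == 52

    def test_chi_square_uses_n_minus_one(self, cegs_baseline, cegs_moments):
        fit = sn.fit_model(cegs_baseline, cegs_moments)
        assert fit.stats.chi_square == pytest.approx(
            (cegs_moments.n - 1) * fit.stats.f_ml)

    def test_delta_bic_invariant_to_penalty_convention(self, cegs_baseline, cegs_moments):
        """chi2 + t ln n and chi2 - df ln n give identical BIC differences for
        nested models on the same data (delta t = -delta df)."""
        base = sn.fit_model(cegs_baseline, cegs_moments)
        bigger = sn.fit_model(cegs_baseline.with_path("snf", "tra"), cegs_moments)
        ln_n = math.log(cegs_moments.n)
        delta_plus = base.stats.bic - bigger.stats.bic
        alt = lambda s: s.chi_square - s.df * ln_n
        delta_minus = alt(base.stats) - alt(bigger.stats)
        assert delta_plus == pytest.approx(delta_minus, abs=1e-8)

    def test_fit_report_serializes(self, cegs_baseline, cegs_moments):
        import json

        fit = sn.fit_model(cegs_baseline, cegs_moments)
        payload = json.loads(fit.to_json())
        assert len(payload["parameters"]) == 26
        assert payload["convergence"]["converged"] is True
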